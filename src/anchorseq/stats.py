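"""Assay-validation statistics: input accounting, binomial detection power,
titration linearity, slope comparison, reproducibility, and limit of
detection.

The sampling model is binomial throughout: a library interrogates ``n``
unique molecules (UMIs), an event present at frequency ``p`` is seen
``X ~ Binomial(n, p)`` times, and detection questions reduce to exact
binomial tails — no normal approximation anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

HAPLOME_PG = 3.5  # picograms of DNA per haploid human genome equivalent


class PowerOverflowError(RuntimeError):
    """min_trials would exceed the configured cap."""


def haplome_equivalents(mass_ng: float, pg_per_haplome: float = HAPLOME_PG) -> int:
    """Number of haploid genome equivalents in ``mass_ng`` of DNA.

    50 ng at 3.5 pg/haplome gives ~14,300 haplomes.
    """
    if pg_per_haplome <= 0:
        raise ValueError("pg_per_haplome must be positive")
    if mass_ng < 0:
        raise ValueError("mass must be >= 0")
    return int(round(mass_ng * 1000.0 / pg_per_haplome))


def expected_observations(n_haplomes: float, process_yield: float, frequency: float) -> float:
    """Expected molecule count: input haplomes x library yield x event frequency."""
    for name, v in (("process_yield", process_yield), ("frequency", frequency)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return n_haplomes * process_yield * frequency


def min_trials(k: int, p: float, confidence: float = 0.95, cap: int = 10**9) -> int:
    """Smallest n with P(X >= k | X ~ Binomial(n, p)) >= confidence.

    Exact binomial tail; doubling search bracketing then bisection, so the
    returned n is minimal (n-1 fails).
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")

    def ok(n):
        return sps.binom.sf(k - 1, n, p) >= confidence

    lo, hi = k, k
    while not ok(hi):
        hi *= 2
        if hi > cap:
            raise PowerOverflowError(f"required n exceeds cap {cap} for k={k}, p={p}")
    while lo < hi:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


def power_table(
    frequencies: Sequence[float],
    ks: Sequence[int] = (1, 2, 3),
    confidences: Sequence[float] = (0.95, 0.99),
    cap: int = 10**9,
) -> pd.DataFrame:
    """Required unique-molecule counts (trials) over a grid of event
    frequencies, observation thresholds and confidence levels."""
    rows = []
    for conf in confidences:
        for k in ks:
            for p in frequencies:
                rows.append(
                    {
                        "frequency": p,
                        "k_observations": k,
                        "confidence": conf,
                        "min_umis": min_trials(k, p, conf, cap=cap),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TitrationPoint:
    expected: float  # expected frequency (or input copies)
    measured: float  # measured frequency (or detected molecules)
    replicate_id: str = "rep1"

    @property
    def detected(self) -> bool:
        return self.measured > 0


@dataclass(frozen=True)
class LinearityFit:
    beta: float
    intercept: float
    r_squared: float
    beta_ci: tuple
    n_points: int
    log_scale: bool

    def __post_init__(self):
        if not self.beta_ci[0] <= self.beta <= self.beta_ci[1]:
            raise ValueError("confidence interval must contain the estimate")


def fit_linearity(points: Sequence[TitrationPoint], log_scale: bool = True) -> LinearityFit:
    """OLS of measured on expected signal (log10-log10 by default).

    The slope beta is the linearity parameter: beta = 1 means the measured
    signal is proportional to input.  Zero-measured points must be routed to
    detection analysis, not regression.
    """
    import statsmodels.api as sm

    pts = [p for p in points]
    if len(pts) < 3:
        raise ValueError("need at least 3 titration points")
    x = np.array([p.expected for p in pts], dtype=float)
    y = np.array([p.measured for p in pts], dtype=float)
    if log_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log-scale fit requires positive values; route zeros to detection analysis")
        x, y = np.log10(x), np.log10(y)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate titration: all expected values equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return LinearityFit(
        beta=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        beta_ci=(float(ci[1][0]), float(ci[1][1])),
        n_points=len(pts),
        log_scale=log_scale,
    )


def compare_slopes(points_a: Sequence[TitrationPoint], points_b: Sequence[TitrationPoint], log_scale: bool = True) -> float:
    """F-test p-value for a slope difference between two titrations.

    Pooled two-group linear model with a group x log10(expected) interaction;
    the returned p-value tests the interaction term.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    frames = []
    for grp, pts in (("a", points_a), ("b", points_b)):
        x = np.array([p.expected for p in pts], dtype=float)
        y = np.array([p.measured for p in pts], dtype=float)
        if log_scale:
            if (x <= 0).any() or (y <= 0).any():
                raise ValueError("log-scale comparison requires positive values")
            x, y = np.log10(x), np.log10(y)
        frames.append(pd.DataFrame({"x": x, "y": y, "group": grp}))
    df = pd.concat(frames, ignore_index=True)
    if df.groupby("group")["x"].nunique().min() < 2:
        raise ValueError("degenerate design: a group has a single expected level")
    model = smf.ols("y ~ x * group", data=df).fit()
    table = anova_lm(model, typ=2)
    return float(table.loc["x:group", "PR(>F)"])


def replicate_r_squared(measured_a: Sequence[float], measured_b: Sequence[float], log_scale: bool = True) -> float:
    """Squared Pearson correlation between paired replicate measurements.

    Pairs where either replicate is zero are excluded (zeros belong to
    detection analysis, not to the log-scale correlation).
    """
    a = np.asarray(measured_a, dtype=float)
    b = np.asarray(measured_b, dtype=float)
    keep = (a > 0) & (b > 0)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 jointly detected pairs")
    if log_scale:
        a, b = np.log10(a), np.log10(b)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def estimate_llod(
    points: Sequence[TitrationPoint],
    detection_rate: float = 0.9,
    max_fold_error: float = 2.0,
) -> float:
    """Lower limit of detection from a replicated titration.

    The LLoD is the lowest expected frequency at which (a) at least
    ``detection_rate`` of replicates detect one or more molecules and (b) the
    median measured frequency is within ``max_fold_error`` of truth.  Returns
    ``inf`` when no level qualifies.
    """
    by_level = {}
    for p in points:
        by_level.setdefault(p.expected, []).append(p)
    for level, pts in by_level.items():
        if len(pts) < 2:
            raise ValueError(f"level {level}: need >= 2 replicates")
    qualifying = []
    for level in sorted(by_level):
        pts = by_level[level]
        det = np.mean([p.detected for p in pts])
        if det < detection_rate:
            continue
        med = float(np.median([p.measured for p in pts]))
        if med <= 0:
            continue
        fold = med / level if med >= level else level / med
        if fold <= max_fold_error:
            qualifying.append(level)
    return min(qualifying) if qualifying else float("inf")
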