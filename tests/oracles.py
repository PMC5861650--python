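"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: alignment scores
come from exhaustive path enumeration, outcome enumeration from raw pairing
of end sequences with reverse-complement string deduplication, and binomial
thresholds from a linear scan of exact tails.
"""

from __future__ import annotations

import itertools

from scipy import stats as sps

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_alignment_score(
    read: str,
    ref: str,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -6,
    gap_extend: int = -1,
) -> int:
    """Best semiglobal affine-gap score by enumerating every monotone path
    (read consumed end-to-end, reference end gaps free), with an admissible
    branch-and-bound prune that cannot change the optimum."""
    m, n = len(read), len(ref)
    best = [-(10**9)]

    def go(i, j, score, state):
        if score + 2 * (m - i) <= best[0]:  # even all-matches cannot win
            return
        if i == m:
            best[0] = max(best[0], score)
            return
        if j < n:
            s = match if read[i] == ref[j] else mismatch
            go(i + 1, j + 1, score + s, 0)
            cost = gap_extend if state == 2 else gap_open + gap_extend
            go(i, j + 1, score + cost, 2)
        cost = gap_extend if state == 3 else gap_open + gap_extend
        go(i + 1, j, score + cost, 3)

    for j0 in range(n + 1):
        go(0, j0, 0, 0)
    return best[0]


def brute_force_outcome_count(end_seqs: dict) -> set:
    """Distinct junction sequences from joining any two free ends.

    ``end_seqs`` maps an end name to its sequence laid 5'->3' toward the
    junction (LEFT fragments as-is, RIGHT fragments reverse-complemented).
    Joining ends a and b produces a_toward + rc(b_toward); sequences equal up
    to reverse complement are one outcome.
    """
    canon = set()
    for a, b in itertools.combinations_with_replacement(sorted(end_seqs), 2):
        seq = end_seqs[a] + rc(end_seqs[b])
        canon.add(min(seq, rc(seq)))
    return canon


def brute_force_min_trials(k: int, p: float, confidence: float) -> int:
    """Linear scan over n of the exact binomial tail."""
    n = k
    while sps.binom.sf(k - 1, n, p) < confidence:
        n += 1
    return n
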