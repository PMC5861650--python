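"""Ready-made simulated experiments mirroring the assay's validation designs.

Three designs are provided:

* a dual-guide single-locus editing experiment (two cuts 1176 bp apart, one
  anchor primer downstream of the distal cut) with small indels at ~17%,
  the large deletion at ~40%, the inversion at ~18% and homolog/sister
  fusions at ~0.75% — the published bulk-editing outcome mix;
* a two-locus experiment (one cut per locus, one anchor primer per locus)
  with on-target indels at ~82% and ~91% and inter-chromosomal fusions
  totalling ~2.5% per locus;
* a titration series (edited molecules diluted into unedited background)
  for linearity / reproducibility / detection-limit studies.

These functions run the *full* pipeline on simulated FASTQ files and return
both the pipeline's frequency estimates and the simulator's ground truth.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pipeline import RunConfig, run_pipeline
from .preprocess import SampleRow, SampleSheet
from .reference import AnchorPrimer, CutSite, ReferenceModel
from .simulate import SimConfig, random_locus, simulate_library

I5_BARCODES = ["TAGATCGC", "CTCTCTAT", "TATCCTCT", "AGAGTAGA"]
I7_BARCODES = ["AGCGGAAT", "GATCATGC", "AAGACGGA", "CGAGTCCT"]

PRIMER_DISTANCE = 50  # bp from primer 3' terminus to the cut

DUAL_CUT_PROPORTIONS = {
    "SMALL_INDEL": 0.17,
    "DELETION": 0.40,
    "INVERSION": 0.18,
    "HOMOLOG_RR": 0.0075,
    "WILDTYPE": 0.2425,
}

TWO_LOCUS_PROPORTIONS = {
    # per-locus molecule mixes at the two anchor primers
    "locusA": {"SMALL_INDEL": 0.82, "FUSION_LR": 0.0125, "FUSION_LL": 0.0125, "WILDTYPE": 0.155},
    "locusB": {"SMALL_INDEL": 0.91, "FUSION_RL": 0.0125, "FUSION_LL": 0.0125, "WILDTYPE": 0.065},
}

CUT_SEPARATION = 1176


def dual_cut_model(seed: int = 0) -> ReferenceModel:
    """One synthetic locus, two cuts 1176 bp apart, primer downstream of the
    distal cut reading back across it."""
    locus = random_locus(4000, seed, name="locusA", chrom_label="chrA")
    cut1 = CutSite(locus, 1400, guide_name="g64")
    cut2 = CutSite(locus, 1400 + CUT_SEPARATION, guide_name="g323")
    primer = AnchorPrimer("P323", cut2.right_end, PRIMER_DISTANCE)
    model = ReferenceModel(loci={locus.name: locus}, cuts=[cut1, cut2], primers=[primer])
    return model


def two_locus_model(seed: int = 0) -> ReferenceModel:
    """Two synthetic loci on distinct chromosomes, one cut each, one anchor
    primer upstream of each cut."""
    locus_a = random_locus(3000, seed * 2 + 1, name="locusA", chrom_label="chrA")
    locus_b = random_locus(3000, seed * 2 + 2, name="locusB", chrom_label="chrB")
    cut_a = CutSite(locus_a, 1500, guide_name="gA")
    cut_b = CutSite(locus_b, 1500, guide_name="gB")
    primers = [
        AnchorPrimer("P_A", cut_a.left_end, PRIMER_DISTANCE),
        AnchorPrimer("P_B", cut_b.left_end, PRIMER_DISTANCE),
    ]
    return ReferenceModel(
        loci={locus_a.name: locus_a, locus_b.name: locus_b},
        cuts=[cut_a, cut_b],
        primers=primers,
    )


def _concat(paths, out_path):
    with open(out_path, "w") as out:
        for p in paths:
            with open(p) as fh:
                for chunk in iter(lambda: fh.read(1 << 20), ""):
                    out.write(chunk)


def run_simulated_experiment(
    model: ReferenceModel,
    sample_specs: Sequence[dict],
    out_dir,
    run_config: Optional[RunConfig] = None,
):
    """Simulate one library per sample spec, pool them, run the pipeline.

    Each spec is ``{"name", "primer", "config": SimConfig}``; barcodes are
    assigned from the preset lists in spec order.  Returns
    ``(summary, truths)`` where truths maps sample name to its truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, truths, r1s, r2s = [], {}, [], []
    for i, spec in enumerate(sample_specs):
        cfg: SimConfig = spec["config"]
        cfg.i5_barcode = I5_BARCODES[i % len(I5_BARCODES)]
        cfg.i7_barcode = I7_BARCODES[i % len(I7_BARCODES)]
        sim = simulate_library(cfg, model, spec["primer"], out_dir / "sim", prefix=spec["name"])
        truths[spec["name"]] = sim["truth"]
        r1s.append(sim["paths"]["r1"])
        r2s.append(sim["paths"]["r2"])
        rows.append(SampleRow(spec["name"], cfg.i5_barcode, cfg.i7_barcode, spec["primer"]))
    r1, r2 = out_dir / "pooled_R1.fastq", out_dir / "pooled_R2.fastq"
    _concat(r1s, r1)
    _concat(r2s, r2)
    sheet = SampleSheet(rows)
    sheet.to_csv(out_dir / "samples.csv")
    if run_config is None:
        run_config = RunConfig(model=model)
    else:
        run_config.model = model
    summary = run_pipeline(run_config, r1, r2, sheet, out_dir / "run")
    return summary, truths


def run_dual_cut_experiment(
    seed: int,
    n_molecules: int = 30_000,
    out_dir=None,
    proportions: Optional[dict] = None,
    duplicates=("geometric", 5.0),
    error_rate: float = 0.001,
):
    """The dual-guide editing experiment end to end; returns (summary, truth)."""
    import tempfile

    model = dual_cut_model(seed)
    cfg = SimConfig(
        n_molecules=n_molecules,
        outcome_proportions=dict(proportions or DUAL_CUT_PROPORTIONS),
        duplicates_per_umi=duplicates,
        substitution_error_rate=error_rate,
        seed=seed + 1,
    )
    spec = [{"name": "edited", "primer": "P323", "config": cfg}]
    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            summary, truths = run_simulated_experiment(model, spec, tmp)
    else:
        summary, truths = run_simulated_experiment(model, spec, out_dir)
    return summary["samples"]["edited"], truths["edited"]


def run_two_locus_experiment(
    seed: int,
    n_molecules_per_primer: int = 20_000,
    out_dir=None,
    error_rate: float = 0.001,
    duplicates=("geometric", 5.0),
):
    """The two-locus translocation experiment; returns (summary dict, truths)."""
    import tempfile

    model = two_locus_model(seed)
    specs = []
    for name, primer, props in (
        ("sampleA", "P_A", TWO_LOCUS_PROPORTIONS["locusA"]),
        ("sampleB", "P_B", TWO_LOCUS_PROPORTIONS["locusB"]),
    ):
        specs.append(
            {
                "name": name,
                "primer": primer,
                "config": SimConfig(
                    n_molecules=n_molecules_per_primer,
                    outcome_proportions=dict(props),
                    duplicates_per_umi=duplicates,
                    substitution_error_rate=error_rate,
                    seed=seed + len(specs) + 1,
                ),
            }
        )
    if out_dir is None:
        with tempfile.TemporaryDirectory() as tmp:
            summary, truths = run_simulated_experiment(model, specs, tmp)
    else:
        summary, truths = run_simulated_experiment(model, specs, out_dir)
    return summary["samples"], truths


def run_titration_replicate(
    seed: int,
    levels: Sequence[float],
    n_molecules: int = 2860,
    error_rate: float = 0.001,
):
    """One titration replicate: per level, an independent library in which a
    fraction ``level`` of molecules is edited (deletion:inversion = 2:1, as in
    an engineered clone carrying two deletions and one inversion per three
    locus copies).  Returns the measured edited frequency per level (0 when
    nothing was detected).
    """
    import tempfile

    model = dual_cut_model(seed=0)  # fixed reference; seed drives sampling only
    measured = []
    for j, level in enumerate(levels):
        cfg = SimConfig(
            n_molecules=n_molecules,
            outcome_proportions={
                "DELETION": 2 * level / 3,
                "INVERSION": level / 3,
                "WILDTYPE": 1 - level,
            },
            duplicates_per_umi=("constant", 1),
            substitution_error_rate=error_rate,
            seed=seed * 1000 + j,
        )
        spec = [{"name": "titr", "primer": "P323", "config": cfg}]
        with tempfile.TemporaryDirectory() as tmp:
            summary, _ = run_simulated_experiment(model, spec, tmp)
        freqs = summary["samples"]["titr"]["frequencies"]
        measured.append(freqs.get("DELETION", 0.0) + freqs.get("INVERSION", 0.0))
    return measured


def assignment_accuracy(seed: int, n_molecules: int = 10_000, error_rate: float = 0.001) -> float:
    """Fraction of simulated read pairs assigned to the amplicon of their
    truth class (mixed outcome population, one read pair per molecule)."""
    import tempfile

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    from .align import PairAligner
    from .pipeline import build_run_amplicons
    from .reference import JunctionKind

    model = dual_cut_model(seed)
    cfg = SimConfig(
        n_molecules=n_molecules,
        outcome_proportions=dict(DUAL_CUT_PROPORTIONS),
        duplicates_per_umi=("constant", 1),
        substitution_error_rate=error_rate,
        seed=seed + 1,
    )
    classes, amplicons = build_run_amplicons(model, flank=350)
    aligner = PairAligner(amplicons)
    primer = model.primer_by_name("P323")
    cut2 = primer.end.cut
    wt_ids = {a.id for a in amplicons if a.is_wildtype}
    expected = {
        "WILDTYPE": wt_ids,
        "SMALL_INDEL": wt_ids,
        "DELETION": {a.id for a in amplicons if not a.is_wildtype and a.junction_class.kind is JunctionKind.DELETION},
        "INVERSION": {
            a.id
            for a in amplicons
            if not a.is_wildtype
            and a.junction_class.kind in (JunctionKind.INVERSION_J1, JunctionKind.INVERSION_J2)
        },
    }
    with tempfile.TemporaryDirectory() as tmp:
        sim = simulate_library(cfg, model, "P323", tmp, prefix="acc")
        truth = sim["truth"].set_index("molecule_id")
        n_pairs = n_correct = 0
        with open(sim["paths"]["r1"]) as f1, open(sim["paths"]["r2"]) as f2:
            for (t1, s1, _), (t2, s2, _) in zip(
                FastqGeneralIterator(f1), FastqGeneralIterator(f2)
            ):
                rid = t1.split()[0]
                mol_id = rid.rsplit(":", 1)[0]
                cls = truth.loc[mol_id, "true_class"]
                n_pairs += 1
                assignment = aligner.assign(s1, s2)
                if not assignment.assigned:
                    continue
                exp = expected.get(cls, {cls})  # junction-class ids are amplicon ids
                if assignment.amplicon_id in exp:
                    n_correct += 1
    return n_correct / n_pairs if n_pairs else 0.0
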