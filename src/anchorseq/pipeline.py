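"""End-to-end runs: demultiplex -> trim/UMI -> amplicons -> align -> quantify.

One run processes every sample in the sheet independently (the per-sample
loop is the parallelism seam; samples never interact), writes per-sample
frequency and QC tables, the amplicon references, a machine-readable JSON
summary, and a log whose per-stage counts allow conservation checks.  All
coordinates in outputs are 0-based, half-open.  Identical inputs and
configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .align import PairAligner, ScoringScheme, write_sam
from .preprocess import DEFAULT_ADAPTER, SampleSheet, demultiplex, trim_adapter
from .quantify import (
    ClassifiedRead,
    QuantifyConfig,
    classify_pair,
    collapse_umis,
    tally,
)
from .reference import (
    JunctionKind,
    ReferenceModel,
    build_amplicons,
    detectable_classes,
    enumerate_outcomes,
    write_amplicon_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    model: ReferenceModel
    flank: int = 350
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    adapter: str = DEFAULT_ADAPTER
    umi_length: int = 10
    max_barcode_mismatch: int = 1
    trim: bool = True
    sam_export: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def echo(self) -> dict:
        return {
            "flank": self.flank,
            "scheme": {
                "match": self.scheme.match,
                "mismatch": self.scheme.mismatch,
                "gap_open": self.scheme.gap_open,
                "gap_extend": self.scheme.gap_extend,
                "min_identity": self.scheme.min_identity,
                "min_aligned_fraction": self.scheme.min_aligned_fraction,
            },
            "quantify": {
                "junction_window": self.quantify.junction_window,
                "indel_window": self.quantify.indel_window,
                "umi_collapse": self.quantify.umi_collapse,
                "min_reads_per_umi": self.quantify.min_reads_per_umi,
                "require_contiguous": self.quantify.require_contiguous,
            },
            "adapter": self.adapter,
            "umi_length": self.umi_length,
            "max_barcode_mismatch": self.max_barcode_mismatch,
            "trim": self.trim,
            "sam_export": self.sam_export,
            "seed": self.seed,
            "coordinates": "0-based, half-open",
        }


def build_run_amplicons(model: ReferenceModel, flank: int):
    """Amplicon set for alignment: all junction classes except NHEJ (whose
    re-ligated sequence equals the wild-type amplicon) plus one wild-type
    amplicon per cut."""
    classes = enumerate_outcomes(model.cuts)
    junction_classes = [jc for jc in classes if jc.kind is not JunctionKind.NHEJ]
    return classes, build_amplicons(junction_classes, flank=flank, include_wildtype=True)


def run_pipeline(
    config: RunConfig,
    r1_path,
    r2_path,
    sheet: SampleSheet,
    out_dir,
    i1_path=None,
    i2_path=None,
) -> dict:
    """Run the full analysis; returns the run summary dict.

    A failure in one sample is isolated: remaining samples still run, the
    summary marks the failure, and the caller decides the exit status.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("anchorseq")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, r1_path, r2_path, sheet, out, i1_path, i2_path)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config, r1_path, r2_path, sheet, out, i1_path, i2_path) -> dict:
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.echo(), fh, sort_keys=True)

    classes, amplicons = build_run_amplicons(config.model, config.flank)
    write_amplicon_fasta(amplicons, out / "amplicons.fasta", out / "amplicons.tsv")
    amp_by_id = {a.id: a for a in amplicons}
    aligner = PairAligner(amplicons, config.scheme)

    per_sample, demux_summary = demultiplex(
        r1_path,
        r2_path,
        sheet,
        max_mismatch=config.max_barcode_mismatch,
        umi_length=config.umi_length,
        i1_path=i1_path,
        i2_path=i2_path,
    )
    total = demux_summary["total"]
    with open(out / "demux_summary.tsv", "w") as fh:
        fh.write("sample\treads\tfraction\n")
        for name, n in demux_summary["per_sample"].items():
            fh.write(f"{name}\t{n}\t{(n / total if total else 0):.6f}\n")
        fh.write(
            f"undetermined\t{demux_summary['undetermined']}\t"
            f"{(demux_summary['undetermined'] / total if total else 0):.6f}\n"
        )
    logger.info(
        "conservation demux: total=%d assigned=%d undetermined=%d discarded=%d",
        total,
        demux_summary["assigned"],
        demux_summary["undetermined"],
        demux_summary["discarded_umi"],
    )

    summary = {
        "demultiplex": demux_summary,
        "samples": {},
        "failures": {},
        "coordinates": "0-based, half-open",
    }
    for row in sheet.rows:
        name = row.sample_name
        try:
            summary["samples"][name] = _run_sample(
                config, row, per_sample[name], classes, amplicons, amp_by_id, aligner, out
            )
        except Exception as exc:  # isolate the failing sample
            logger.exception("sample %s failed", name)
            summary["failures"][name] = str(exc)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _run_sample(config, row, reads, classes, amplicons, amp_by_id, aligner, out) -> dict:
    name = row.sample_name
    primer = config.model.primer_by_name(row.primer_name)
    detect = [jc for jc, _ in detectable_classes(classes, [primer])]
    classified = []
    sam_rows = []
    n_reads = 0
    reason_counts = {}
    for rec in reads:
        n_reads += 1
        r1, q1 = rec.r1_seq, rec.r1_qual
        r2, q2 = rec.r2_seq, rec.r2_qual
        if config.trim:
            r1, q1 = trim_adapter(r1, q1, config.adapter)
            r2, q2 = trim_adapter(r2, q2, config.adapter)
        assignment = aligner.assign(r1, r2 if r2 else None)
        category, indel, reason = classify_pair(assignment, amp_by_id, config.quantify)
        if reason:
            reason_counts[reason] = reason_counts.get(reason, 0) + 1
        classified.append(
            ClassifiedRead(name, rec.umi, category, indel, rec.umi_has_n)
        )
        if config.sam_export:
            sam_rows.append((rec.read_id, r1, assignment, rec.umi))
        if n_reads % 100_000 == 0:
            logger.info("sample %s: %d reads classified", name, n_reads)
    molecules = collapse_umis(classified, config.quantify)
    table = tally(molecules, detect)
    table.qc["umi_with_n_reads"] = sum(1 for c in classified if c.umi_has_n)
    table.qc["reads"] = n_reads
    table.to_tsv(out / f"{name}.frequencies.tsv")
    with open(out / f"{name}.qc.tsv", "w") as fh:
        fh.write("metric\tcount\n")
        for k in sorted(table.qc):
            fh.write(f"{k}\t{table.qc[k]}\n")
        for k in sorted(reason_counts):
            fh.write(f"reads_{k}\t{reason_counts[k]}\n")
    if config.sam_export:
        write_sam(out / f"{name}.sam", amplicons, sam_rows)
    logger.info(
        "conservation sample %s: reads=%d molecules=%d denominator=%d "
        "unassigned=%d ambiguous=%d",
        name,
        n_reads,
        len(molecules),
        table.denominator,
        table.qc.get("unassigned", 0),
        table.qc.get("ambiguous", 0),
    )
    return {
        "reads": n_reads,
        "molecules": len(molecules),
        "denominator": table.denominator,
        "frequencies": {r["category"]: r["frequency"] for r in table.rows},
        "umi_counts": {r["category"]: r["umi_count"] for r in table.rows},
        "qc": dict(table.qc),
        "detectable_classes": [jc.id for jc in detect],
    }
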