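"""Outcome classification, UMI collapse, and frequency tables.

A read pair assigned to a junction amplicon supports that outcome only if one
mate covers the whole window around the junction (default 15 bp each side)
with match/substitution columns — a gap opening a hole across the junction
disqualifies the read.  On the wild-type amplicon the same window is
inspected for small indels; there the window only needs to be spanned by the
alignment, since the indel itself interrupts match columns.

Frequencies are molecule (UMI) based: reads are grouped by (sample, UMI),
each group becomes one molecule whose category is the majority read call, and
PCR depth therefore cancels out.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import OP_DEL, OP_INS, OP_MATCH, OP_SUB, AlignmentResult, PairAssignment
from .reference import Amplicon, JunctionClass, JunctionKind

WILDTYPE = "WILDTYPE"
SMALL_INDEL = "SMALL_INDEL"
UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"

_KIND_TO_CATEGORY = {
    JunctionKind.NHEJ: WILDTYPE,
    JunctionKind.DELETION: "DELETION",
    JunctionKind.INVERSION_J1: "INVERSION",
    JunctionKind.INVERSION_J2: "INVERSION",
    JunctionKind.HOMOLOG_LL: "HOMOLOG_FUSION",
    JunctionKind.HOMOLOG_RR: "HOMOLOG_FUSION",
    JunctionKind.FUSION_LR: "FUSION_LR",
    JunctionKind.FUSION_RL: "FUSION_RL",
    JunctionKind.FUSION_LL: "FUSION_LL",
    JunctionKind.FUSION_RR: "FUSION_RR",
}


def category_for_class(jc: JunctionClass) -> str:
    return _KIND_TO_CATEGORY[jc.kind]


@dataclass(frozen=True)
class QuantifyConfig:
    junction_window: int = 15
    indel_window: int = 15
    umi_collapse: str = "EXACT"  # or "HAMMING1"
    min_reads_per_umi: int = 1
    require_contiguous: bool = True  # strict junction-window rule

    def __post_init__(self):
        if self.junction_window < 1 or self.indel_window < 1:
            raise ValueError("windows must be >= 1")
        if self.umi_collapse not in ("EXACT", "HAMMING1"):
            raise ValueError("umi_collapse must be EXACT or HAMMING1")


@dataclass(frozen=True)
class IndelDescriptor:
    ref_start: int
    ref_end: int
    deleted_length: int
    inserted_bases: str

    def __str__(self):
        parts = []
        if self.deleted_length:
            parts.append(f"del{self.deleted_length}")
        if self.inserted_bases:
            parts.append(f"ins{len(self.inserted_bases)}:{self.inserted_bases}")
        return f"{'+'.join(parts)}@{self.ref_start}-{self.ref_end}"


@dataclass
class ClassifiedRead:
    sample: str
    umi: str
    category: str
    indel: Optional[IndelDescriptor] = None
    umi_has_n: bool = False


@dataclass
class ClassifiedMolecule:
    sample: str
    umi: str
    category: str
    supporting_reads: int
    indel: Optional[IndelDescriptor] = None


def covers_junction(
    alignments: Sequence[Optional[AlignmentResult]],
    junction_offset: int,
    window: int,
    require_contiguous: bool = True,
) -> bool:
    """True iff some mate's aligned span contains the full window
    [offset-window, offset+window) — with every base in it consumed by
    match/substitution columns when ``require_contiguous``.
    """
    lo, hi = junction_offset - window, junction_offset + window
    for aln in alignments:
        if aln is None:
            continue
        if aln.ref_start > lo or aln.ref_end < hi:
            continue
        if not require_contiguous:
            return True
        ok = True
        for e in aln.edits:
            if e.op == OP_DEL and e.ref_pos < hi and e.ref_pos + e.length > lo:
                ok = False
                break
            if e.op == OP_INS and lo < e.ref_pos < hi:
                ok = False
                break
        if ok:
            return True
    return False


def call_small_indel(
    alignments: Sequence[Optional[AlignmentResult]],
    cut_offset: int,
    indel_window: int = 15,
) -> Optional[IndelDescriptor]:
    """Merged descriptor of INS/DEL edits intersecting the cut window, from
    the first mate whose alignment spans the window; None if the window is
    pure match/substitution (wild type).
    """
    lo, hi = cut_offset - indel_window, cut_offset + indel_window
    for aln in alignments:
        if aln is None or aln.ref_start > lo or aln.ref_end < hi:
            continue
        dels = ins = 0
        span_lo, span_hi = None, None
        bases = []
        for e in aln.edits:
            hit = False
            if e.op == OP_DEL and e.ref_pos < hi and e.ref_pos + e.length > lo:
                dels += e.length
                hit = True
            elif e.op == OP_INS and lo <= e.ref_pos < hi:
                ins += e.length
                bases.append(e.bases)
                hit = True
            if hit:
                span_lo = e.ref_pos if span_lo is None else min(span_lo, e.ref_pos)
                span_hi = max(span_hi or 0, e.ref_pos + (e.length if e.op == OP_DEL else 0))
        if dels or ins:
            return IndelDescriptor(span_lo, span_hi, dels, "".join(bases))
        return None
    return None


def classify_pair(
    assignment: PairAssignment,
    amplicons_by_id: dict,
    config: QuantifyConfig,
):
    """(category, indel_descriptor, reason) for one assigned read pair."""
    if not assignment.assigned:
        return UNASSIGNED, None, "unaligned"
    amp: Amplicon = amplicons_by_id[assignment.amplicon_id]
    alns = (assignment.aln1, assignment.aln2)
    offset = amp.junction_offsets[0]
    if amp.is_wildtype:
        if not covers_junction(alns, offset, config.indel_window, require_contiguous=False):
            return UNASSIGNED, None, "no_junction_coverage"
        desc = call_small_indel(alns, offset, config.indel_window)
        if desc is None:
            return WILDTYPE, None, ""
        return SMALL_INDEL, desc, ""
    if covers_junction(alns, offset, config.junction_window, config.require_contiguous):
        return category_for_class(amp.junction_class), None, ""
    return UNASSIGNED, None, "no_junction_coverage"


def _directional_collapse(groups: dict) -> dict:
    """Directional UMI collapse: a UMI is absorbed into a Hamming-1 neighbor
    whose read count is at least 2x its own minus 1.
    """
    merged = dict(groups)
    order = sorted(merged, key=lambda u: (-len(merged[u]), u))
    alphabet = "ACGT"
    for umi in order:
        if umi not in merged:
            continue
        count = len(merged[umi])
        # try to absorb this UMI into a larger neighbor
        best_parent = None
        for pos in range(len(umi)):
            for base in alphabet:
                if base == umi[pos]:
                    continue
                neigh = umi[:pos] + base + umi[pos + 1 :]
                if neigh in merged and neigh != umi:
                    if len(merged[neigh]) >= 2 * count - 1:
                        if best_parent is None or len(merged[neigh]) > len(merged[best_parent]):
                            best_parent = neigh
        if best_parent is not None:
            merged[best_parent] = merged[best_parent] + merged[umi]
            del merged[umi]
    return merged


def collapse_umis(
    reads: Iterable[ClassifiedRead], config: QuantifyConfig = QuantifyConfig()
) -> list:
    """Group classified reads into molecules by (sample, UMI).

    The molecule's category is the majority read category; an exact tie makes
    the molecule AMBIGUOUS.  With ``umi_collapse="HAMMING1"`` UMIs one
    substitution apart are merged by the directional rule before grouping.
    """
    by_sample = defaultdict(lambda: defaultdict(list))
    for r in reads:
        by_sample[r.sample][r.umi].append(r)
    molecules = []
    for sample in sorted(by_sample):
        groups = by_sample[sample]
        if config.umi_collapse == "HAMMING1":
            groups = _directional_collapse(groups)
        for umi in sorted(groups):
            grp = groups[umi]
            if len(grp) < config.min_reads_per_umi:
                continue
            counts = Counter(r.category for r in grp)
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                category = AMBIGUOUS
                indel = None
            else:
                category = top[0][0]
                descs = Counter(
                    str(r.indel) for r in grp if r.category == category and r.indel is not None
                )
                indel = None
                if category == SMALL_INDEL and descs:
                    target = descs.most_common(1)[0][0]
                    indel = next(r.indel for r in grp if str(r.indel) == target)
            molecules.append(
                ClassifiedMolecule(sample, umi, category, len(grp), indel)
            )
    return molecules


@dataclass
class FrequencyTable:
    rows: list  # of dicts: category, umi_count, read_count, frequency
    denominator: int
    qc: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["category", "umi_count", "read_count", "frequency"])

    def frequency(self, category: str) -> float:
        for r in self.rows:
            if r["category"] == category:
                return r["frequency"]
        return 0.0

    def umi_count(self, category: str) -> int:
        for r in self.rows:
            if r["category"] == category:
                return r["umi_count"]
        return 0

    def fusion_frequency(self) -> float:
        """Summed frequency of inter-end fusion categories (translocations)."""
        return sum(r["frequency"] for r in self.rows if r["category"].startswith("FUSION_"))

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("# coordinates: 0-based, half-open; frequency = umi_count / denominator\n")
            fh.write(f"# denominator\t{self.denominator}\n")
            fh.write("category\tumi_count\tread_count\tfrequency\n")
            for r in self.rows:
                fh.write(
                    f"{r['category']}\t{r['umi_count']}\t{r['read_count']}\t{r['frequency']:.6f}\n"
                )


def tally(
    molecules: Sequence[ClassifiedMolecule],
    detectable: Sequence[JunctionClass],
    include_categories: Optional[Sequence[str]] = None,
) -> FrequencyTable:
    """Per-category UMI counts and frequencies for one sample.

    The denominator is every molecule assigned to a detectable category
    (including WILDTYPE and SMALL_INDEL); UNASSIGNED and AMBIGUOUS molecules
    are excluded and reported in the QC block.  Inversion junction subclasses
    are aggregated (a molecule supporting either junction counts once).
    """
    categories = [WILDTYPE, SMALL_INDEL]
    for jc in detectable:
        cat = category_for_class(jc)
        if cat not in categories:
            categories.append(cat)
    if include_categories:
        for cat in include_categories:
            if cat not in categories:
                categories.append(cat)
    umi_counts = Counter()
    read_counts = Counter()
    qc = Counter({"unassigned": 0, "ambiguous": 0, "unexpected_category": 0})
    for mol in molecules:
        if mol.category == UNASSIGNED:
            qc["unassigned"] += 1
        elif mol.category == AMBIGUOUS:
            qc["ambiguous"] += 1
        elif mol.category in categories:
            umi_counts[mol.category] += 1
            read_counts[mol.category] += mol.supporting_reads
        else:
            qc["unexpected_category"] += 1
    denominator = sum(umi_counts.values())
    rows = []
    for cat in categories:
        freq = umi_counts[cat] / denominator if denominator else 0.0
        rows.append(
            {
                "category": cat,
                "umi_count": umi_counts[cat],
                "read_count": read_counts[cat],
                "frequency": freq,
            }
        )
    qc["total_molecules"] = len(molecules)
    return FrequencyTable(rows=rows, denominator=denominator, qc=dict(qc))
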