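"""Ground-truth-labeled synthetic libraries for anchored one-sided sequencing.

Each simulated molecule is one edited (or unedited) genomic DNA molecule.  A
library is built the way the assay works: the anchor primer fixes one side of
every fragment, a tagmentation breakpoint drawn from the fragment-length law
fixes the other, R1 reads from the primer's 3' terminus into the molecule
(crossing any junction after ``distance_to_cut`` bases), and R2 reads back
from the breakpoint (the transposase side).  PCR duplicates share the UMI and
fragment ends and re-draw sequencing errors independently.  A truth table
maps every read back to its source molecule.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reference import (
    AnchorPrimer,
    ConfigurationError,
    CutSite,
    End,
    JunctionClass,
    JunctionKind,
    ReferenceModel,
    Side,
    enumerate_outcomes,
    reverse_complement,
)

WILDTYPE = "WILDTYPE"
SMALL_INDEL = "SMALL_INDEL"
DELETION = "DELETION"
INVERSION = "INVERSION"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_locus(length: int, seed, name: str = "locus", chrom_label: str = "") -> "Locus":
    """A uniform-random synthetic locus (stand-in for a real genomic region)."""
    from .reference import Locus

    rng = np.random.default_rng(seed)
    seq = rng.integers(0, 4, size=length)
    return Locus(
        name=name,
        sequence=bytes(_BASES[seq]).decode("ascii"),
        chrom_label=chrom_label or name,
    )


@dataclass(frozen=True)
class IndelSizeModel:
    """Small-indel model at a cut: insertion/deletion 50/50, geometric sizes.

    Sizes follow a geometric law (p = 0.3, so mean ~3.3 bp) capped at
    ``max_size``.  A deletion's interval is placed uniformly among the
    placements that touch the cut point; insertions go at the cut.
    """

    p_insertion: float = 0.5
    geometric_p: float = 0.3
    max_size: int = 30

    def draw(self, rng: np.random.Generator):
        size = min(int(rng.geometric(self.geometric_p)), self.max_size)
        kind = "ins" if rng.random() < self.p_insertion else "del"
        return kind, size


@dataclass
class SimConfig:
    """Study conditions for one simulated library (one sample)."""

    n_molecules: int
    outcome_proportions: dict
    umi_length: int = 10
    i5_barcode: str = "TAGATCGC"
    i7_barcode: str = "AGCGGAAT"
    read_length: int = 150
    fragment_length: tuple = ("uniform", 150, 600)
    duplicates_per_umi: tuple = ("geometric", 5.0)
    substitution_error_rate: float = 0.001
    indel_model: IndelSizeModel = field(default_factory=IndelSizeModel)
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.outcome_proportions.values())
        if any(v < 0 for v in self.outcome_proportions.values()):
            raise ConfigurationError("outcome proportions must be >= 0")
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"outcome proportions sum to {total}, not 1")
        if len(self.i5_barcode) != len(self.i7_barcode):
            raise ConfigurationError("i5 and i7 barcodes must have equal length")


@dataclass
class MoleculeTruth:
    molecule_id: str
    umi: str
    true_class: str
    indel_descriptor: str
    fragment_start: int
    fragment_end: int
    n_duplicates: int
    truncated: bool
    captured: bool
    umi_collision: bool = False


def _apply_indel(sequence: str, cut: int, kind: str, size: int, rng: np.random.Generator):
    """Apply one small indel touching ``cut``; returns (seq, descriptor, shift_at(fn))."""
    if kind == "ins":
        ins = bytes(_BASES[rng.integers(0, 4, size=size)]).decode("ascii")
        edited = sequence[:cut] + ins + sequence[cut:]
        desc = f"ins:{cut}-{cut}:{ins}"

        def shift(pos):  # edited coordinate of original position
            return pos + size if pos >= cut else pos

    else:
        a = int(rng.integers(cut - size, cut + 1))
        a = max(a, 0)
        b = a + size
        edited = sequence[:a] + sequence[b:]
        desc = f"del:{a}-{b}:{size}"

        def shift(pos):
            if pos >= b:
                return pos - size
            if pos > a:
                return a
            return pos

    return edited, desc, shift


def _oriented_toward(end: End) -> str:
    """The end's full fragment laid 5'->3' ending at the junction."""
    frag = end.full_fragment()
    return frag if end.side is Side.LEFT else reverse_complement(frag)


def _oriented_away(end: End) -> str:
    """The end's full fragment laid 5'->3' starting at the junction."""
    frag = end.full_fragment()
    return frag if end.side is Side.RIGHT else reverse_complement(frag)


def resolve_class_label(label, primer: Optional[AnchorPrimer], cuts: Sequence[CutSite]):
    """Map a proportion key to a concrete class.

    Accepts the special labels WILDTYPE / SMALL_INDEL / DELETION / INVERSION,
    a :class:`JunctionClass`, a class id, or a junction-kind name (resolved
    against the enumerated classes, disambiguated by the primer's end).
    """
    if isinstance(label, JunctionClass):
        return label
    if label in (WILDTYPE, SMALL_INDEL, DELETION, INVERSION):
        return label
    classes = enumerate_outcomes(cuts)
    by_id = [jc for jc in classes if jc.id == label]
    if by_id:
        return by_id[0]
    by_kind = [jc for jc in classes if jc.kind.value == label]
    if primer is not None and len(by_kind) > 1:
        by_kind = [jc for jc in by_kind if jc.involves(primer.end)]
    if len(by_kind) == 1:
        return by_kind[0]
    raise ConfigurationError(f"cannot resolve outcome label {label!r}")


def realize_molecule(label, cuts: Sequence[CutSite], *, rng=None, indel_model: Optional[IndelSizeModel] = None, forced_indel=None) -> str:
    """The full edited molecule for one outcome class (canonical orientation)."""
    label = resolve_class_label(label, None, cuts) if isinstance(label, str) and label not in (
        WILDTYPE,
        SMALL_INDEL,
        DELETION,
        INVERSION,
    ) else label
    if isinstance(label, JunctionClass):
        e1, e2 = label.ends
        return _oriented_toward(e1) + _oriented_away(e2)
    seq = cuts[0].locus.sequence
    if label == WILDTYPE:
        return seq
    if label == SMALL_INDEL:
        cut = cuts[0].position
        if forced_indel is not None:
            kind, size = forced_indel
        else:
            if rng is None:
                raise ValueError("SMALL_INDEL needs an rng (or forced_indel)")
            kind, size = (indel_model or IndelSizeModel()).draw(rng)
        edited, _, _ = _apply_indel(seq, cut, kind, size, rng or np.random.default_rng(0))
        return edited
    if len(cuts) != 2 or cuts[0].locus != cuts[1].locus:
        raise ConfigurationError(f"{label} requires two cuts on one locus")
    c1, c2 = sorted(c.position for c in cuts)
    if label == DELETION:
        return seq[:c1] + seq[c2:]
    if label == INVERSION:
        return seq[:c1] + reverse_complement(seq[c1:c2]) + seq[c2:]
    raise ConfigurationError(f"unknown outcome label {label!r}")


def _primer_template(label, primer: AnchorPrimer, cuts: Sequence[CutSite], rng, indel_model):
    """Primer-oriented template and fragment start for one molecule.

    Returns (template, start, indel_descriptor, captured).  ``template`` is
    the molecule read 5'->3' in the primer's direction; ``start`` is the
    index of the primer's 3' terminus, so the junction/cut sits
    ``distance_to_cut`` bases into every R1.
    """
    e = primer.end
    c = e.cut
    d = primer.distance_to_cut
    seq = c.locus.sequence
    desc = ""
    if isinstance(label, JunctionClass):
        if not label.involves(e):
            return None, 0, "", False
        other = label.ends[0] if label.ends[1] == e else label.ends[1]
        if label.ends[0] == label.ends[1]:
            other = e
        head = _oriented_toward(e)
        template = head + _oriented_away(other)
        return template, len(head) - d, desc, True
    if label == WILDTYPE or label == SMALL_INDEL:
        if label == SMALL_INDEL:
            kind, size = indel_model.draw(rng)
            edited, desc, shift = _apply_indel(seq, c.position, kind, size, rng)
        else:
            edited, shift = seq, lambda p: p
        if e.side is Side.LEFT:
            return edited, shift(c.position - d), desc, True
        return (
            reverse_complement(edited),
            len(edited) - shift(c.position + d),
            desc,
            True,
        )
    # same-locus two-cut molecules
    c1, c2 = sorted(cuts, key=lambda x: x.position)
    p1, p2 = c1.position, c2.position
    if label == DELETION:
        if e not in (c1.left_end, c2.right_end):
            return None, 0, "", False
        mol = seq[:p1] + seq[p2:]
        if e.side is Side.LEFT:
            return mol, p1 - d, desc, True
        return reverse_complement(mol), len(mol) - (p1 + d), desc, True
    if label == INVERSION:
        if e not in (c1.left_end, c2.right_end):
            return None, 0, "", False
        mol = seq[:p1] + reverse_complement(seq[p1:p2]) + seq[p2:]
        if e.side is Side.LEFT:
            return mol, p1 - d, desc, True
        return reverse_complement(mol), len(mol) - (p2 + d), desc, True
    raise ConfigurationError(f"unknown outcome label {label!r}")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    arr = bytearray(seq.encode("ascii"))
    pos = rng.choice(len(arr), size=n, replace=False)
    for p in pos:
        cur = arr[p]
        alt = _BASES[rng.integers(0, 3)]
        if alt == cur:  # pick a different base
            alt = _BASES[3] if cur != _BASES[3] else _BASES[(3 + 1) % 4]
        arr[p] = alt
    return arr.decode("ascii")


def _fastq_open(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _draw_fragment_length(spec, rng) -> int:
    kind = spec[0]
    if kind == "uniform":
        return int(rng.integers(spec[1], spec[2] + 1))
    if kind == "constant":
        return int(spec[1])
    raise ConfigurationError(f"unknown fragment length distribution {spec!r}")


def _draw_duplicates(spec, rng) -> int:
    kind = spec[0]
    if kind == "geometric":
        return int(rng.geometric(1.0 / spec[1]))
    if kind == "constant":
        return int(spec[1])
    raise ConfigurationError(f"unknown duplicate distribution {spec!r}")


def simulate_library(
    config: SimConfig,
    model: ReferenceModel,
    primer_name: str,
    out_dir,
    prefix: str = "sim",
    write_index_reads: bool = False,
    gzip_output: bool = False,
):
    """Simulate one library; write R1/R2 FASTQ (+ optional I1/I2) and a truth TSV.

    Fully reproducible from ``config.seed``.  Returns a dict with the output
    paths and the truth table as a DataFrame.
    """
    if not model.primers:
        raise ConfigurationError("model has no anchor primers")
    primer = model.primer_by_name(primer_name)
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_output else ".fastq"
    paths = {
        "r1": out_dir / f"{prefix}_R1{ext}",
        "r2": out_dir / f"{prefix}_R2{ext}",
        "truth": out_dir / f"{prefix}_truth.tsv",
        "config": out_dir / f"{prefix}_simconfig.json",
    }
    if write_index_reads:
        paths["i1"] = out_dir / f"{prefix}_I1{ext}"
        paths["i2"] = out_dir / f"{prefix}_I2{ext}"

    labels = list(config.outcome_proportions.keys())
    resolved = [resolve_class_label(l, primer, model.cuts) for l in labels]
    probs = np.array([config.outcome_proportions[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    choice = rng.choice(len(labels), size=config.n_molecules, p=probs)
    umis_arr = rng.integers(0, 4, size=(config.n_molecules, config.umi_length))
    umis = ["".join("ACGT"[b] for b in row) for row in umis_arr]
    umi_counts = {}
    for u in umis:
        umi_counts[u] = umi_counts.get(u, 0) + 1

    # deterministic templates cached per class; indels re-drawn per molecule
    template_cache = {}
    truth_rows = []
    read_len = config.read_length
    qline = "I" * read_len
    handles = {k: _fastq_open(paths[k]) for k in ("r1", "r2")}
    if write_index_reads:
        handles["i1"] = _fastq_open(paths["i1"])
        handles["i2"] = _fastq_open(paths["i2"])
    try:
        for i in range(config.n_molecules):
            label_key = labels[choice[i]]
            label = resolved[choice[i]]
            mol_id = f"{prefix}:M{i:07d}"
            umi = umis[i]
            if label_key == SMALL_INDEL or (
                isinstance(label, str) and label == SMALL_INDEL
            ):
                template, f0, desc, captured = _primer_template(
                    SMALL_INDEL, primer, model.cuts, rng, config.indel_model
                )
            else:
                key = id(label) if isinstance(label, JunctionClass) else label
                if key not in template_cache:
                    template_cache[key] = _primer_template(
                        label, primer, model.cuts, rng, config.indel_model
                    )
                template, f0, desc, captured = template_cache[key]
            cls_name = label.id if isinstance(label, JunctionClass) else str(label)
            if config.dropout_rate > 0 and rng.random() < config.dropout_rate:
                truth_rows.append(
                    MoleculeTruth(mol_id, umi, cls_name, desc, -1, -1, 0, False, False)
                )
                continue
            if not captured:
                truth_rows.append(
                    MoleculeTruth(mol_id, umi, cls_name, desc, -1, -1, 0, False, False)
                )
                continue
            frag_len = _draw_fragment_length(config.fragment_length, rng)
            start = f0
            end = min(start + frag_len, len(template))
            if start < 0:
                raise ConfigurationError(
                    "primer lies outside the realized molecule; locus flanks too short"
                )
            fragment = template[start:end]
            truncated = len(fragment) < read_len
            n_dup = _draw_duplicates(config.duplicates_per_umi, rng)
            truth_rows.append(
                MoleculeTruth(
                    mol_id,
                    umi,
                    cls_name,
                    desc,
                    start,
                    end,
                    n_dup,
                    truncated,
                    True,
                    umi_collision=umi_counts[umi] > 1,
                )
            )
            r1_t = fragment[:read_len]
            r2_t = reverse_complement(fragment[-read_len:])
            err = config.substitution_error_rate
            for dup in range(n_dup):
                r1 = _mutate(r1_t, err, rng)
                r2 = _mutate(r2_t, err, rng)
                u = _mutate(umi, err, rng)
                bc5 = _mutate(config.i5_barcode, err, rng)
                bc7 = _mutate(config.i7_barcode, err, rng)
                rid = f"{mol_id}:D{dup}"
                head = f"@{rid} BC:{bc5}+{bc7} UMI:{u}"
                handles["r1"].write(f"{head}\n{r1}\n+\n{qline[:len(r1)]}\n")
                handles["r2"].write(f"{head}\n{r2}\n+\n{qline[:len(r2)]}\n")
                if write_index_reads:
                    handles["i1"].write(f"@{rid}\n{bc7}\n+\n{'I'*len(bc7)}\n")
                    handles["i2"].write(f"@{rid}\n{u}{bc5}\n+\n{'I'*(len(u)+len(bc5))}\n")
    finally:
        for fh in handles.values():
            fh.close()

    truth = pd.DataFrame([t.__dict__ for t in truth_rows])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    echo = {
        "n_molecules": config.n_molecules,
        "outcome_proportions": {
            (k.id if isinstance(k, JunctionClass) else str(k)): v
            for k, v in config.outcome_proportions.items()
        },
        "umi_length": config.umi_length,
        "i5_barcode": config.i5_barcode,
        "i7_barcode": config.i7_barcode,
        "read_length": config.read_length,
        "fragment_length": list(config.fragment_length),
        "duplicates_per_umi": list(config.duplicates_per_umi),
        "substitution_error_rate": config.substitution_error_rate,
        "dropout_rate": config.dropout_rate,
        "seed": config.seed,
        "primer": primer_name,
    }
    with open(paths["config"], "w") as fh:
        json.dump(echo, fh, indent=2)
    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth}
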