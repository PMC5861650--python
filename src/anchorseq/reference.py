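"""Genomic model for anchored editing-outcome sequencing.

Represents loci, CRISPR cut sites, the free DNA ends a cut creates, the
end-joining outcome classes one or two cuts can produce, and the reference
"junction amplicons" built for each class.  A cut at position ``p`` falls
between bases ``p-1`` and ``p`` (0-based, half-open coordinates throughout).

Two free ends can ligate in exactly one way once you know which termini are
free: a LEFT end (upstream fragment, free at its right terminus) joined to a
RIGHT end (downstream fragment, free at its left terminus) gives a direct,
collinear junction; LEFT+LEFT or RIGHT+RIGHT joins require one fragment to
flip, producing head-to-head (inversion-type / dicentric / acentric)
junctions.  Junctions that are reverse complements of one another are the
same molecule read from the other strand and are stored once, in a canonical
orientation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import yaml

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    """Raised for model configurations the package does not support."""


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class JunctionKind(str, Enum):
    NHEJ = "NHEJ"
    DELETION = "DELETION"
    INVERSION_J1 = "INVERSION_J1"
    INVERSION_J2 = "INVERSION_J2"
    HOMOLOG_LL = "HOMOLOG_LL"
    HOMOLOG_RR = "HOMOLOG_RR"
    FUSION_LR = "FUSION_LR"
    FUSION_RL = "FUSION_RL"
    FUSION_LL = "FUSION_LL"
    FUSION_RR = "FUSION_RR"


@dataclass(frozen=True)
class Locus:
    """A (synthetic) genomic region containing zero or more cut sites.

    ``centromere_side`` optionally says on which side of the region the
    centromere lies ("LEFT" or "RIGHT"); it is only used to annotate fusion
    classes as balanced / dicentric / acentric.
    """

    name: str
    sequence: str
    chrom_label: str = ""
    centromere_side: Optional[str] = None

    def __post_init__(self):
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ConfigurationError(
                f"locus {self.name!r}: sequence contains invalid bases {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CutSite:
    """A blunt double-strand break between ``position-1`` and ``position``."""

    locus: Locus
    position: int
    guide_name: str = ""

    def __post_init__(self):
        if not 0 < self.position < len(self.locus):
            raise ConfigurationError(
                f"cut {self.guide_name!r}: position {self.position} outside "
                f"locus {self.locus.name!r} (length {len(self.locus)})"
            )

    @property
    def left_end(self) -> "End":
        return End(self, Side.LEFT)

    @property
    def right_end(self) -> "End":
        return End(self, Side.RIGHT)

    def sort_key(self):
        return (self.locus.name, self.position)


@dataclass(frozen=True)
class End:
    """One of the two free DNA ends created by a cut.

    LEFT = the upstream fragment (sequence ending at the cut);
    RIGHT = the downstream fragment (sequence starting at the cut).
    """

    cut: CutSite
    side: Side

    def sort_key(self):
        return (self.cut.locus.name, self.cut.position, self.side.value)

    def flank(self, length: int) -> str:
        """The ``length`` bases of this fragment adjacent to the cut."""
        locus, pos = self.cut.locus, self.cut.position
        if self.side is Side.LEFT:
            if pos - length < 0:
                raise ConfigurationError(
                    f"flank {length} exceeds sequence left of cut at "
                    f"{locus.name}:{pos}"
                )
            return locus.sequence[pos - length : pos]
        if pos + length > len(locus):
            raise ConfigurationError(
                f"flank {length} exceeds sequence right of cut at {locus.name}:{pos}"
            )
        return locus.sequence[pos : pos + length]

    def full_fragment(self) -> str:
        locus, pos = self.cut.locus, self.cut.position
        return locus.sequence[:pos] if self.side is Side.LEFT else locus.sequence[pos:]

    def __str__(self):
        return f"{self.cut.locus.name}:{self.cut.position}:{self.side.value[0]}"


@dataclass(frozen=True)
class JunctionClass:
    """One end-joining outcome: an unordered pair of free ends, canonicalized.

    ``ends`` is stored in canonical order (a LEFT end first when possible,
    ties broken by locus name then position); reverse-complement-equivalent
    joins are therefore represented exactly once.
    """

    kind: JunctionKind
    ends: tuple  # (End, End)
    label: str = ""

    @property
    def id(self) -> str:
        e1, e2 = self.ends
        return f"{self.kind.value}__{e1}__{e2}".replace(":", "_")

    def involves(self, end: End) -> bool:
        return end in self.ends


@dataclass(frozen=True)
class Amplicon:
    """A reference sequence for one outcome class (or the unedited locus).

    For junction amplicons the junction sits at offset ``source_flank``; for
    wild-type amplicons the cut offset is stored in ``junction_offsets`` the
    same way so that window logic downstream is uniform.
    """

    id: str
    junction_class: Optional[JunctionClass]  # None => wild type
    sequence: str
    junction_offsets: tuple
    source_flank: int
    cut: Optional[CutSite] = None  # set for wild-type amplicons

    @property
    def is_wildtype(self) -> bool:
        return self.junction_class is None

    def __len__(self):
        return len(self.sequence)


@dataclass(frozen=True)
class AnchorPrimer:
    """A locus-specific primer annealed on one free end's flank.

    The primer's 3' terminus sits ``distance_to_cut`` bases from the cut
    point, pointing toward it; the read it primes therefore crosses any
    junction formed at that end after ``distance_to_cut`` bases.
    """

    name: str
    end: End
    distance_to_cut: int
    primer_sequence: str = ""

    def __post_init__(self):
        if self.distance_to_cut < 0:
            raise ConfigurationError(
                f"primer {self.name!r}: distance_to_cut must be >= 0"
            )


def _canonical_pair(e1: End, e2: End) -> tuple:
    """Canonical ordering of an unordered end pair.

    LEFT ends come first when the pair is mixed; remaining ties break on
    (locus name, position, side).
    """
    a, b = sorted((e1, e2), key=lambda e: e.sort_key())
    if a.side is Side.RIGHT and b.side is Side.LEFT:
        a, b = b, a
    return (a, b)


def _classify_pair(e1: End, e2: End) -> JunctionKind:
    a, b = _canonical_pair(e1, e2)
    if a == b:
        return JunctionKind.HOMOLOG_LL if a.side is Side.LEFT else JunctionKind.HOMOLOG_RR
    same_cut = a.cut == b.cut
    same_locus = a.cut.locus == b.cut.locus
    if a.side is Side.LEFT and b.side is Side.RIGHT:
        if same_cut:
            return JunctionKind.NHEJ
        if same_locus:
            # collinear join across two cuts on one molecule
            if a.cut.position < b.cut.position:
                return JunctionKind.DELETION
            return JunctionKind.FUSION_RL  # duplication/circle junction
        # cross-locus balanced joins: LR when the first-named locus donates
        # its LEFT end, RL when it donates its RIGHT end
        if a.cut.locus.name <= b.cut.locus.name:
            return JunctionKind.FUSION_LR
        return JunctionKind.FUSION_RL
    if a.side is Side.LEFT and b.side is Side.LEFT:
        if same_locus:
            return JunctionKind.INVERSION_J1
        return JunctionKind.FUSION_LL
    # RIGHT + RIGHT
    if same_locus:
        return JunctionKind.INVERSION_J2
    return JunctionKind.FUSION_RR


def _fusion_label(kind: JunctionKind, a: End, b: End) -> str:
    """Centromere-relative annotation for fusion classes, when known.

    A fusion keeping exactly one centromere is balanced; two is dicentric;
    none is acentric.  Requires ``centromere_side`` on both loci.
    """
    if kind in (JunctionKind.NHEJ, JunctionKind.DELETION):
        return kind.value.lower()
    sides = []
    for e in (a, b):
        cs = e.cut.locus.centromere_side
        if cs is None:
            return ""
        # fragment retains its centromere iff the centromere lies on the
        # fragment's side of the cut
        sides.append(cs.upper() == e.side.value)
    n = sum(sides)
    return {0: "acentric", 1: "balanced", 2: "dicentric"}[n]


def enumerate_outcomes(cuts: Sequence[CutSite]) -> list:
    """All distinct end-joining junction classes for one or two cuts.

    Every unordered pair of free ends (with replacement: joining like ends of
    two homologous copies is allowed) yields exactly one junction class after
    reverse-complement deduplication: 3 classes for one cut, 10 for two.
    """
    if not cuts:
        raise ConfigurationError("at least one cut site is required")
    if len(cuts) > 2:
        raise ConfigurationError(
            f"{len(cuts)} cut sites given; outcome enumeration supports at most 2"
        )
    cuts = sorted(cuts, key=lambda c: c.sort_key())
    ends = [e for c in cuts for e in (c.left_end, c.right_end)]
    seen = {}
    for e1, e2 in itertools.combinations_with_replacement(ends, 2):
        pair = _canonical_pair(e1, e2)
        if pair in seen:
            continue
        kind = _classify_pair(*pair)
        seen[pair] = JunctionClass(kind=kind, ends=pair, label=_fusion_label(kind, *pair))
    return sorted(seen.values(), key=lambda jc: (jc.ends[0].sort_key(), jc.ends[1].sort_key()))


def junction_sequence(jc: JunctionClass, flank: int) -> str:
    """The reference sequence across a junction, ``flank`` bases each side.

    Built from the canonical end order: the first end's fragment is laid
    5'->3' ending at the junction, then the second end's fragment continues
    away from it (reverse-complemented when its free terminus demands it).
    """
    a, b = jc.ends
    left = a.flank(flank) if a.side is Side.LEFT else reverse_complement(a.flank(flank))
    right = b.flank(flank) if b.side is Side.RIGHT else reverse_complement(b.flank(flank))
    return left + right


def build_amplicons(
    classes: Iterable[JunctionClass],
    flank: int = 350,
    include_wildtype: bool = True,
) -> list:
    """Reference amplicons for a set of junction classes.

    Junction amplicons are ``2*flank`` long with the junction at offset
    ``flank``.  Wild-type amplicons (one per distinct cut) span cut +/- flank
    with the cut offset recorded at ``flank``.  NHEJ-class amplicons equal
    the wild-type amplicon of their cut by construction (re-ligation restores
    the reference sequence).
    """
    amplicons = []
    cuts_seen = []
    for jc in classes:
        seq = junction_sequence(jc, flank)
        amplicons.append(
            Amplicon(
                id=jc.id,
                junction_class=jc,
                sequence=seq,
                junction_offsets=(flank,),
                source_flank=flank,
            )
        )
        for e in jc.ends:
            if e.cut not in cuts_seen:
                cuts_seen.append(e.cut)
    if include_wildtype:
        for cut in sorted(cuts_seen, key=lambda c: c.sort_key()):
            seq = cut.left_end.flank(flank) + cut.right_end.flank(flank)
            amplicons.append(
                Amplicon(
                    id=f"WT__{cut.locus.name}_{cut.position}",
                    junction_class=None,
                    sequence=seq,
                    junction_offsets=(flank,),
                    source_flank=flank,
                    cut=cut,
                )
            )
    return amplicons


def detectable_classes(
    classes: Sequence[JunctionClass], primers: Sequence[AnchorPrimer]
) -> list:
    """The subset of classes at least one anchor primer can read across.

    A class is detectable iff some primer's end is one of the class's two
    ends; the detecting primers are returned alongside each class.
    """
    out = []
    for jc in classes:
        hits = tuple(p for p in primers if jc.involves(p.end))
        if hits:
            out.append((jc, hits))
    return out


# ---------------------------------------------------------------------------
# configuration I/O


@dataclass
class ReferenceModel:
    """Loci, cuts and primers for one experiment."""

    loci: dict = field(default_factory=dict)  # name -> Locus
    cuts: list = field(default_factory=list)
    primers: list = field(default_factory=list)

    def cut_by_guide(self, guide_name: str) -> CutSite:
        for c in self.cuts:
            if c.guide_name == guide_name:
                return c
        raise KeyError(guide_name)

    def primer_by_name(self, name: str) -> AnchorPrimer:
        for p in self.primers:
            if p.name == name:
                return p
        raise KeyError(name)

    def outcome_classes(self) -> list:
        return enumerate_outcomes(self.cuts)


def load_model_config(path_or_dict) -> ReferenceModel:
    """Build a :class:`ReferenceModel` from a YAML file or parsed dict.

    Expected keys: ``loci`` [{name, sequence | fasta, centromere_side?}],
    ``cuts`` [{locus, position, guide}], ``primers`` [{name, locus, side,
    distance_to_cut, guide?}].
    """
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    model = ReferenceModel()
    for entry in cfg.get("loci", []):
        seq = entry.get("sequence")
        if seq is None and "fasta" in entry:
            from Bio import SeqIO

            rec = next(SeqIO.parse(entry["fasta"], "fasta"))
            seq = str(rec.seq)
        if seq is None:
            raise ConfigurationError(
                f"locus {entry.get('name')!r}: needs 'sequence' or 'fasta'"
            )
        locus = Locus(
            name=entry["name"],
            sequence=seq.upper(),
            chrom_label=entry.get("chrom_label", ""),
            centromere_side=entry.get("centromere_side"),
        )
        model.loci[locus.name] = locus
    for entry in cfg.get("cuts", []):
        model.cuts.append(
            CutSite(
                locus=model.loci[entry["locus"]],
                position=int(entry["position"]),
                guide_name=entry.get("guide", ""),
            )
        )
    for entry in cfg.get("primers", []):
        if "guide" in entry:
            cut = model.cut_by_guide(entry["guide"])
        else:
            matches = [c for c in model.cuts if c.locus.name == entry["locus"]]
            if len(matches) != 1:
                raise ConfigurationError(
                    f"primer {entry.get('name')!r}: ambiguous locus; give 'guide'"
                )
            cut = matches[0]
        side = Side(entry["side"].upper())
        end = cut.left_end if side is Side.LEFT else cut.right_end
        model.primers.append(
            AnchorPrimer(
                name=entry["name"],
                end=end,
                distance_to_cut=int(entry["distance_to_cut"]),
                primer_sequence=entry.get("primer_sequence", ""),
            )
        )
    return model


def write_amplicon_fasta(amplicons: Sequence[Amplicon], fasta_path, tsv_path=None):
    """Export amplicons as FASTA plus a junction-offset sidecar TSV.

    Coordinates in the TSV are 0-based offsets into the amplicon sequence.
    """
    with open(fasta_path, "w") as fh:
        for amp in amplicons:
            fh.write(f">{amp.id}\n{amp.sequence}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("# coordinates: 0-based, half-open\n")
            fh.write("amplicon_id\tclass\tjunction_offset\n")
            for amp in amplicons:
                cls = "WILDTYPE" if amp.is_wildtype else amp.junction_class.kind.value
                for off in amp.junction_offsets:
                    fh.write(f"{amp.id}\t{cls}\t{off}\n")
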