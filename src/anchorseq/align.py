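"""Semi-global affine-gap alignment of reads to reference amplicons.

The aligner is "glocal": every read base is consumed (terminal read overhangs
are penalized insertions) while the reference contributes free end gaps, so a
read finds its best placement anywhere on an amplicon.  Gap costs are affine
(open + extend).  Traceback is deterministic with op priority
MATCH/SUB > DEL > INS and, among equal-scoring end columns, the leftmost.

`assign_amplicon` scores a read pair against every amplicon exhaustively.
`PairAligner` is the batch path used by the pipeline: it shortlists candidate
amplicons per read with an exact edit-distance prescreen (edlib) and runs the
affine DP on a window around the reported location; thresholds, scoring and
tie-breaking are identical to the exhaustive path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .reference import Amplicon, reverse_complement

OP_MATCH = "MATCH"
OP_SUB = "SUB"
OP_DEL = "DEL"
OP_INS = "INS"

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_NEG = np.int32(-(10**9))


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1
    min_identity: float = 0.8
    min_aligned_fraction: float = 0.8

    def __post_init__(self):
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("match must be positive; penalties negative")
        for t in (self.min_identity, self.min_aligned_fraction):
            if not 0 < t <= 1:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class Edit:
    op: str
    ref_pos: int
    length: int
    bases: str = ""


@dataclass
class AlignmentResult:
    amplicon_id: Optional[str]
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    score: int
    edits: tuple
    mate: str = "R1"
    strand: int = 1  # +1: read as given; -1: reverse complement aligned
    n_matches: int = 0
    n_columns: int = 0

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0

    def aligned_fraction(self, read_length: int) -> float:
        return (self.read_end - self.read_start) / read_length if read_length else 0.0

    def passes(self, scheme: ScoringScheme, read_length: int) -> bool:
        return (
            self.identity >= scheme.min_identity
            and self.aligned_fraction(read_length) >= scheme.min_aligned_fraction
        )

    def cigar(self) -> list:
        """CIGAR tuples (pysam op codes): M/I/D with terminal INS as soft clips."""
        out = []
        for e in self.edits:
            if e.op in (OP_MATCH, OP_SUB):
                code = 0
            elif e.op == OP_INS:
                code = 1
            else:
                code = 2
            if out and out[-1][0] == code:
                out[-1] = (code, out[-1][1] + e.length)
            else:
                out.append((code, e.length))
        return out


@njit(cache=True)
def _fill_traceback(read, ref, match, mismatch, gap_open, gap_extend):
    """Full semiglobal affine DP with deterministic traceback.

    Returns (score, ref_start, ops, n_ops) where ops[k] is 0=MATCH 1=SUB
    2=DEL 3=INS, in read order.
    """
    m, n = read.shape[0], ref.shape[0]
    NEG = np.int32(-(10**8))
    go = np.int32(gap_open)
    ge = np.int32(gap_extend)
    ma = np.int32(match)
    mi = np.int32(mismatch)
    H = np.empty((m + 1, n + 1), np.int32)
    D = np.empty((m + 1, n + 1), np.int32)
    I = np.empty((m + 1, n + 1), np.int32)
    for j in range(n + 1):
        H[0, j] = 0
        D[0, j] = NEG
        I[0, j] = NEG
    for i in range(1, m + 1):
        rb = read[i - 1]
        h0 = go + np.int32(i) * ge
        H[i, 0] = h0
        I[i, 0] = h0
        D[i, 0] = NEG
        h_diag = H[i - 1, 0]
        h_left = h0
        d_left = NEG
        for j in range(1, n + 1):
            s = ma if (rb == ref[j - 1] and rb < 4) else mi
            mm = h_diag + s
            d_open = h_left + go + ge
            d_left = d_left + ge
            if d_open > d_left:
                d_left = d_open
            i_open = H[i - 1, j] + go + ge
            i_ext = I[i - 1, j] + ge
            ii = i_open if i_open > i_ext else i_ext
            best = mm
            if d_left > best:
                best = d_left
            if ii > best:
                best = ii
            D[i, j] = d_left
            I[i, j] = ii
            H[i, j] = best
            h_diag = H[i - 1, j]
            h_left = best
    best_j = 0
    best = H[m, 0]
    for j in range(1, n + 1):
        if H[m, j] > best:  # strict: leftmost end column on ties
            best = H[m, j]
            best_j = j
    ops = np.empty(m + n + 2, np.int8)
    k = 0
    i, j = m, best_j
    state = 0  # 0=H, 2=D, 3=I
    while i > 0:
        if state == 0:
            s = match if (j > 0 and read[i - 1] == ref[j - 1] and read[i - 1] < 4) else mismatch
            if j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ops[k] = 0 if (read[i - 1] == ref[j - 1] and read[i - 1] < 4) else 1
                k += 1
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == D[i, j]:
                state = 2
            else:
                state = 3
        elif state == 2:
            ops[k] = 2
            k += 1
            # prefer closing the gap (exit to H) when scores tie
            if D[i, j] == H[i, j - 1] + gap_open + gap_extend:
                state = 0
            j -= 1
        else:
            ops[k] = 3
            k += 1
            if i > 0 and I[i, j] == H[i - 1, j] + gap_open + gap_extend:
                state = 0
            i -= 1
    # trailing DEL ops cannot occur at i == 0 (leading ref gap is free)
    return best, j, ops, k


def _ops_to_edits(ops: np.ndarray, n_ops: int, ref_start: int, read: str, ref: str):
    """Merge traceback ops (reversed order) into Edit runs with coordinates."""
    edits = []
    i, j = 0, ref_start
    k = n_ops - 1
    while k >= 0:
        op = ops[k]
        run = 0
        start_i, start_j = i, j
        while k >= 0 and ops[k] == op:
            run += 1
            k -= 1
            if op == 0 or op == 1:
                i += 1
                j += 1
            elif op == 2:
                j += 1
            else:
                i += 1
        if op == 0:
            edits.append(Edit(OP_MATCH, start_j, run))
        elif op == 1:
            edits.append(Edit(OP_SUB, start_j, run, read[start_i:i]))
        elif op == 2:
            edits.append(Edit(OP_DEL, start_j, run))
        else:
            edits.append(Edit(OP_INS, start_j, run, read[start_i:i]))
    return tuple(edits), j


def align_semiglobal(read: str, ref: str, scheme: ScoringScheme = ScoringScheme(), *, mate: str = "R1", strand: int = 1) -> AlignmentResult:
    """Optimal semiglobal affine-gap alignment of ``read`` against ``ref``."""
    if not read or not ref:
        raise ValueError("both sequences must be non-empty")
    r, t = encode(read), encode(ref)
    score, ref_start, ops, n_ops = _fill_traceback(
        r, t, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    edits, ref_end = _ops_to_edits(ops, n_ops, ref_start, read, ref)
    # trim terminal insertion runs for the aligned-span accounting
    lead = edits[0].length if edits and edits[0].op == OP_INS else 0
    trail = edits[-1].length if len(edits) > (1 if lead else 0) and edits[-1].op == OP_INS else 0
    if len(edits) == 1 and edits[0].op == OP_INS:
        trail = 0
    n_matches = sum(e.length for e in edits if e.op == OP_MATCH)
    n_cols = sum(e.length for e in edits) - lead - trail
    return AlignmentResult(
        amplicon_id=None,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=lead,
        read_end=len(read) - trail,
        score=int(score),
        edits=edits,
        mate=mate,
        strand=strand,
        n_matches=n_matches,
        n_columns=n_cols,
    )


def score_semiglobal(read: str, ref: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    score, _, _, _ = _fill_traceback(
        encode(read), encode(ref), scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    return int(score)


def _best_strand(read: str, ref: str, scheme: ScoringScheme, mate: str) -> AlignmentResult:
    fwd = align_semiglobal(read, ref, scheme, mate=mate, strand=1)
    rev = align_semiglobal(reverse_complement(read), ref, scheme, mate=mate, strand=-1)
    return fwd if fwd.score >= rev.score else rev


UNASSIGNED = "UNASSIGNED"


@dataclass
class PairAssignment:
    amplicon_id: Optional[str]  # None => unassigned
    aln1: Optional[AlignmentResult] = None
    aln2: Optional[AlignmentResult] = None
    single_mate: bool = False
    pair_score: int = 0

    @property
    def assigned(self) -> bool:
        return self.amplicon_id is not None


def _amplicon_rank_key(amp: Amplicon):
    # wild-type amplicons win score ties; then lexicographic id
    return (not amp.is_wildtype, amp.id)


def assign_amplicon(
    r1: str,
    r2: Optional[str],
    amplicons: Sequence[Amplicon],
    scheme: ScoringScheme = ScoringScheme(),
) -> PairAssignment:
    """Assign a read pair to its best reference amplicon (exhaustive).

    The best amplicon maximizes the summed mate score among amplicons where
    every present mate passes ``min_identity`` and ``min_aligned_fraction``;
    ties prefer wild-type amplicons, then lexicographic id.  If no amplicon
    qualifies on all mates, a single passing mate may carry the assignment
    (flagged ``single_mate``); otherwise the pair is unassigned.
    """
    if not amplicons:
        raise ValueError("amplicon set must be non-empty")
    results = []
    for amp in amplicons:
        a1 = _best_strand(r1, amp.sequence, scheme, "R1")
        a1.amplicon_id = amp.id
        a2 = None
        if r2 is not None:
            a2 = _best_strand(r2, amp.sequence, scheme, "R2")
            a2.amplicon_id = amp.id
        results.append((amp, a1, a2))
    return _pick_assignment(results, r1, r2, scheme)


def _pick_assignment(results, r1, r2, scheme) -> PairAssignment:
    both = []
    for amp, a1, a2 in results:
        ok1 = a1 is not None and a1.passes(scheme, len(r1))
        if r2 is None:
            if ok1:
                both.append((amp, a1, None, a1.score))
        elif ok1 and a2 is not None and a2.passes(scheme, len(r2)):
            both.append((amp, a1, a2, a1.score + a2.score))
    if both:
        amp, a1, a2, s = min(both, key=lambda t: (-t[3],) + _amplicon_rank_key(t[0]))
        return PairAssignment(amp.id, a1, a2, single_mate=False, pair_score=s)
    if r2 is not None:
        singles = []
        for amp, a1, a2 in results:
            if a1 is not None and a1.passes(scheme, len(r1)):
                singles.append((amp, a1, None, a1.score))
            elif a2 is not None and a2.passes(scheme, len(r2)):
                singles.append((amp, None, a2, a2.score))
        if singles:
            amp, a1, a2, s = min(singles, key=lambda t: (-t[3],) + _amplicon_rank_key(t[0]))
            return PairAssignment(amp.id, a1, a2, single_mate=True, pair_score=s)
    return PairAssignment(None)


class PairAligner:
    """Batch read-pair assignment with an exact-distance prescreen.

    For each mate and strand, an edit-distance scan (edlib, infix mode) over
    all amplicons shortlists candidates within ``margin`` of the best
    distance; the affine DP then scores a located window (padded by
    ``window_pad``) on each candidate.  With near-reference reads this is
    equivalent to the exhaustive scan at a fraction of the cost.
    """

    def __init__(self, amplicons: Sequence[Amplicon], scheme: ScoringScheme = ScoringScheme(), *, margin: int = 8, window_pad: int = 24):
        import edlib

        self._edlib = edlib
        self.amplicons = list(amplicons)
        self.scheme = scheme
        self.margin = margin
        self.window_pad = window_pad

    def _mate_candidates(self, read: str):
        """Per (amplicon index, strand): edit distance and end location.

        Two-stage distance cap: most reads sit within a few edits of their
        amplicon, so a tight first pass handles them cheaply; reads carrying
        larger indels escalate to a generous cap.
        """
        edlib = self._edlib
        rc = reverse_complement(read)
        for k in (6, max(40, int(0.4 * len(read)))):
            out = []
            best = None
            for idx, amp in enumerate(self.amplicons):
                for strand, q in ((1, read), (-1, rc)):
                    res = edlib.align(q, amp.sequence, mode="HW", task="locations", k=k)
                    d = res["editDistance"]
                    if d < 0:
                        continue
                    loc = res["locations"][0]
                    out.append((d, idx, strand, q, loc))
                    if best is None or d < best:
                        best = d
            if best is not None:
                return [c for c in out if c[0] <= best + self.margin]
        return []

    def _windowed(self, q: str, amp: Amplicon, loc, strand: int, mate: str) -> AlignmentResult:
        start = 0 if loc[0] is None else loc[0]
        end = loc[1] + 1
        ws = max(0, start - self.window_pad)
        we = min(len(amp.sequence), end + self.window_pad)
        aln = align_semiglobal(q, amp.sequence[ws:we], self.scheme, mate=mate, strand=strand)
        aln.ref_start += ws
        aln.ref_end += ws
        aln.edits = tuple(
            Edit(e.op, e.ref_pos + ws, e.length, e.bases) for e in aln.edits
        )
        aln.amplicon_id = amp.id
        return aln

    def assign(self, r1: str, r2: Optional[str]) -> PairAssignment:
        cands1 = self._mate_candidates(r1)
        cands2 = self._mate_candidates(r2) if r2 else []
        amp_ids = sorted({idx for _, idx, _, _, _ in cands1} | {idx for _, idx, _, _, _ in cands2})
        if not amp_ids:
            return PairAssignment(None)
        results = []
        for idx in amp_ids:
            amp = self.amplicons[idx]
            a1 = self._mate_best(cands1, idx, amp, "R1", r1)
            a2 = self._mate_best(cands2, idx, amp, "R2", r2) if r2 else None
            # a mate with no prescreen hit on this amplicon sits far beyond
            # the distance margin and could not pass the identity threshold;
            # it is treated as a failing mate rather than aligned in full
            results.append((amp, a1, a2))
        return _pick_assignment(results, r1, r2, self.scheme)

    def _mate_best(self, cands, idx, amp, mate, read) -> Optional[AlignmentResult]:
        best = None
        for d, i, strand, q, loc in cands:
            if i != idx:
                continue
            aln = self._windowed(q, amp, loc, strand, mate)
            if best is None or aln.score > best.score or (aln.score == best.score and aln.strand > best.strand):
                best = aln
        return best


def write_sam(path, amplicons: Sequence[Amplicon], rows):
    """Export assignments as SAM (amplicons as reference sequences).

    ``rows`` yields (read_id, read_seq, assignment:PairAssignment, umi).
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": a.id, "LN": len(a.sequence)} for a in amplicons],
    }
    ref_ids = {a.id: i for i, a in enumerate(amplicons)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read_id, seq, assignment, umi in rows:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read_id
            aln = assignment.aln1 or assignment.aln2
            if assignment.assigned and aln is not None:
                a.reference_id = ref_ids[assignment.amplicon_id]
                a.reference_start = aln.ref_start
                a.query_sequence = seq if aln.strand == 1 else reverse_complement(seq)
                a.cigartuples = aln.cigar()
                a.flag = 16 if aln.strand == -1 else 0
            else:
                a.query_sequence = seq
                a.flag = 4
            a.set_tag("RX", umi)
            fh.write(a)
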