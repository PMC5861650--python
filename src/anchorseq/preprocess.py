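"""Demultiplexing, UMI extraction and 3' adapter trimming.

Reads carry their dual sample barcodes and UMI either in the FASTQ header
comment (``BC:<i5>+<i7> UMI:<seq>``) or as separate I1/I2 index reads (I1 =
i7 barcode, I2 = UMI followed by the i5 barcode); both dialects are accepted.

A read is assigned to a sample only if each barcode independently resolves to
exactly one sample-sheet barcode within ``max_mismatch`` substitutions — a
second sheet barcode inside the mismatch radius makes the read undetermined,
even when one match is exact.
"""

from __future__ import annotations

import csv
import gzip
import logging
import warnings
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

# reverse complement of the transposase mosaic-end construct a read runs into
# when the fragment is shorter than the read
DEFAULT_ADAPTER = "CTGTCTCTTATACACATCTGACGCTGCCGACGA"


class DemuxError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRow:
    sample_name: str
    i5_barcode: str
    i7_barcode: str
    primer_name: str


@dataclass
class SampleSheet:
    rows: list

    def __post_init__(self):
        pairs = [(r.i5_barcode, r.i7_barcode) for r in self.rows]
        if len(set(pairs)) != len(pairs):
            raise DemuxError("sample sheet has duplicate (i5, i7) pairs")
        for col in ("i5_barcode", "i7_barcode"):
            vals = [getattr(r, col) for r in self.rows]
            if len({len(v) for v in vals}) > 1:
                raise DemuxError(f"{col}s differ in length")
            uniq = sorted(set(vals))
            for i in range(len(uniq)):
                for j in range(i + 1, len(uniq)):
                    if hamming(uniq[i], uniq[j]) < 3:
                        warnings.warn(
                            f"{col} barcodes {uniq[i]} and {uniq[j]} are fewer than "
                            "3 substitutions apart; 1-mismatch demultiplexing may tie",
                            stacklevel=2,
                        )

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            rows = [
                SampleRow(
                    r["sample_name"].strip(),
                    r["i5_barcode"].strip().upper(),
                    r["i7_barcode"].strip().upper(),
                    r.get("primer_name", "").strip(),
                )
                for r in reader
            ]
        return cls(rows)

    def to_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["sample_name", "i5_barcode", "i7_barcode", "primer_name"])
            for r in self.rows:
                w.writerow([r.sample_name, r.i5_barcode, r.i7_barcode, r.primer_name])


@dataclass
class ReadRecord:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str
    umi: str = ""
    sample_name: str = ""
    umi_has_n: bool = False


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    return sum(x != y for x, y in zip(a, b))


def _open_fastq(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_header_tags(title: str):
    """(read_id, i5, i7, umi) from a ``id BC:i5+i7 UMI:seq`` FASTQ title."""
    parts = title.split()
    read_id = parts[0]
    i5 = i7 = umi = None
    for p in parts[1:]:
        if p.startswith("BC:"):
            bc = p[3:]
            if "+" in bc:
                i5, i7 = bc.split("+", 1)
        elif p.startswith("UMI:"):
            umi = p[4:]
    return read_id, i5, i7, umi


class _BarcodeResolver:
    """Memoized nearest-unique-barcode lookup for one index column."""

    def __init__(self, barcodes, max_mismatch: int):
        self.barcodes = sorted(set(barcodes))
        self.max_mismatch = max_mismatch
        self._cache = {}

    def resolve(self, observed: str) -> Optional[str]:
        try:
            return self._cache[observed]
        except KeyError:
            pass
        hits = [b for b in self.barcodes if hamming(observed, b) <= self.max_mismatch]
        result = hits[0] if len(hits) == 1 else None
        self._cache[observed] = result
        return result


def extract_umi(umi: Optional[str], umi_length: int):
    """Validate a UMI string: (umi, has_n, ok)."""
    if umi is None or len(umi) < umi_length:
        return "", False, False
    umi = umi[:umi_length]
    return umi, "N" in umi.upper(), True


def demultiplex(
    r1_path,
    r2_path,
    sheet: SampleSheet,
    max_mismatch: int = 1,
    umi_length: int = 10,
    i1_path=None,
    i2_path=None,
    log_every: int = 100_000,
):
    """Assign read pairs to samples by dual barcodes (<= ``max_mismatch`` each).

    Returns (per_sample: dict name -> [ReadRecord], summary: dict).  The
    summary counts partition the input exactly: assigned per sample +
    undetermined + discarded (missing/short UMI) = total.
    """
    res5 = _BarcodeResolver([r.i5_barcode for r in sheet.rows], max_mismatch)
    res7 = _BarcodeResolver([r.i7_barcode for r in sheet.rows], max_mismatch)
    pair_to_sample = {(r.i5_barcode, r.i7_barcode): r.sample_name for r in sheet.rows}
    per_sample = {r.sample_name: [] for r in sheet.rows}
    undetermined = []
    counts = {r.sample_name: 0 for r in sheet.rows}
    n_total = n_undet = n_discard = n_umi_n = 0

    index_iter = None
    handles = []
    try:
        fh1, fh2 = _open_fastq(r1_path), _open_fastq(r2_path)
        handles = [fh1, fh2]
        it1, it2 = FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        if i1_path is not None and i2_path is not None:
            fhi1, fhi2 = _open_fastq(i1_path), _open_fastq(i2_path)
            handles += [fhi1, fhi2]
            index_iter = zip(FastqGeneralIterator(fhi1), FastqGeneralIterator(fhi2))
        for (t1, s1, q1), (t2, s2, q2) in zip_longest(it1, it2, fillvalue=(None,) * 3):
            if t1 is None or t2 is None:
                raise DemuxError("R1 and R2 files have unequal read counts")
            n_total += 1
            rid, i5, i7, umi = parse_header_tags(t1)
            if index_iter is not None:
                (ti1, si1, _), (ti2, si2, _) = next(index_iter)
                i7 = si1
                umi = si2[:umi_length]
                i5 = si2[umi_length:]
            if i5 is None or i7 is None:
                raise DemuxError(f"read {rid}: no barcode information available")
            b5, b7 = res5.resolve(i5), res7.resolve(i7)
            sample = pair_to_sample.get((b5, b7)) if b5 and b7 else None
            if sample is None:
                n_undet += 1
                undetermined.append(rid)
            else:
                u, has_n, ok = extract_umi(umi, umi_length)
                if not ok:
                    n_discard += 1
                    logger.info("read %s discarded: UMI missing or short", rid)
                else:
                    n_umi_n += has_n
                    counts[sample] += 1
                    per_sample[sample].append(
                        ReadRecord(rid, s1, q1, s2, q2, umi=u, sample_name=sample, umi_has_n=has_n)
                    )
            if log_every and n_total % log_every == 0:
                logger.info("demultiplex: %d reads processed", n_total)
    finally:
        for fh in handles:
            fh.close()
    summary = {
        "total": n_total,
        "assigned": sum(counts.values()),
        "undetermined": n_undet,
        "discarded_umi": n_discard,
        "umi_with_n": n_umi_n,
        "per_sample": counts,
    }
    logger.info(
        "demultiplex: %d reads, %d assigned, %d undetermined, %d discarded",
        n_total,
        summary["assigned"],
        n_undet,
        n_discard,
    )
    return per_sample, summary


def trim_adapter(
    seq: str,
    qual: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
):
    """Remove 3' adapter read-through: the longest read suffix matching an
    adapter prefix with at most ``max_error_rate`` mismatches.

    Only suffix/prefix overlaps are considered (no internal trimming); with no
    acceptable overlap the read is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    max_ov = min(len(seq), len(adapter))
    for ov in range(max_ov, min_overlap - 1, -1):
        mism = hamming(seq[-ov:], adapter[:ov])
        if mism <= int(max_error_rate * ov):
            return seq[:-ov], qual[:-ov]
    return seq, qual
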