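import numpy as np
import pytest

from anchorseq.align import AlignmentResult, Edit
from anchorseq.reference import CutSite, Locus
from anchorseq.simulate import random_locus


@pytest.fixture(scope="session")
def toy_locus():
    return random_locus(60, seed=7, name="toy")


@pytest.fixture(scope="session")
def toy_two_cuts(toy_locus):
    return [CutSite(toy_locus, 20, "a"), CutSite(toy_locus, 40, "b")]


@pytest.fixture(scope="session")
def cross_loci():
    la = random_locus(1200, seed=3, name="A", chrom_label="chr1")
    lb = random_locus(1200, seed=4, name="B", chrom_label="chr2")
    return [CutSite(la, 600, "ga"), CutSite(lb, 600, "gb")]


def make_alignment(ref_start, ref_end, edits, amplicon_id="amp", score=0):
    """Crafted AlignmentResult for window-logic tests."""
    n_match = sum(e.length for e in edits if e.op == "MATCH")
    n_cols = sum(e.length for e in edits)
    read_len = sum(e.length for e in edits if e.op in ("MATCH", "SUB", "INS"))
    return AlignmentResult(
        amplicon_id=amplicon_id,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=0,
        read_end=read_len,
        score=score,
        edits=tuple(edits),
        n_matches=n_match,
        n_columns=n_cols,
    )


@pytest.fixture
def crafted_alignment():
    return make_alignment
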