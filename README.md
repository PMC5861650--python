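# anchorseq

Quantification of CRISPR editing outcomes — small indels, large deletions,
inversions, homolog/sister-chromatid fusions and inter-chromosomal
translocations — from **anchored uni-directional tagmentation sequencing**
libraries, in which a Tn5 adapter carries a 10-nt UMI and sample barcode and
a locus-specific anchor primer fixes one side of every fragment. Because
only one side of the amplicon is primer-defined, a single library captures
structural rearrangements that conventional two-primer amplicon sequencing
cannot see, and UMIs make every count a molecule count.

The package is for people building or validating such assays: it contains
the full analysis pipeline, a ground-truth read simulator for testing it
offline, and the assay-validation statistics (binomial detection power,
titration linearity, detection limit).

## What it computes

For each sample, reads are demultiplexed by dual 8-nt barcodes (≤1 mismatch
per index, ties undetermined), UMI-extracted, adapter-trimmed, and aligned
with an affine-gap semi-global DP (match +2 / mismatch −4 / gap open −6 /
extend −1; read end-to-end, free reference end gaps) against reference
amplicons built for every end-joining outcome of the configured cuts. A read
supports a junction only if it covers the junction ± 15 bp contiguously with
match/substitution columns; on the wild-type amplicon the same window is
inspected for indels touching the cut. Reads collapse to molecules by UMI
(majority vote; optional directional Hamming-1 merging), and per-category
frequencies are UMI counts over all classified molecules:

```
frequency(category) = UMIs(category) / UMIs(all detectable categories incl. wild type)
```

Validation statistics follow the binomial sampling model: a library of `n`
unique molecules observes an event at frequency `p` as `X ~ Binomial(n, p)`;
`min_trials(k, p, c)` inverts the exact tail; titration linearity is the
log–log OLS slope β with a t-based CI; slope differences use the F-test on
the group × input interaction.

## Worked example

Simulate a dual-guide editing experiment (two cuts 1176 bp apart on one
locus, anchor primer 50 bp downstream of the distal cut) in which 17% of
molecules carry small indels, 40% the excision deletion, 18% the inversion
and 0.75% homolog fusions, then run the complete pipeline on the simulated
FASTQs:

```python
from anchorseq.experiments import run_dual_cut_experiment

summary, truth = run_dual_cut_experiment(seed=99, n_molecules=2000)
print("molecules:", summary["denominator"])
for category, freq in summary["frequencies"].items():
    print(f"{category:16s} {freq:.4f}")
```

prints (9,790 read pairs from 2,000 molecules at ~5 PCR duplicates each):

```
molecules: 2098
WILDTYPE         0.2407
SMALL_INDEL      0.1668
DELETION         0.4037
INVERSION        0.1811
HOMOLOG_FUSION   0.0076
```

The pipeline's molecule-frequency estimates match the simulator's drawn
truth (40.35% deletion, 18.05% inversion, 16.65% indels in this draw) to a
few parts per thousand; the extra ~98 molecules over 2,000 are sequencing
errors inside UMIs creating satellite singletons, which spread across
categories in proportion and leave frequencies unbiased.

The same machinery is exposed as a CLI:

```bash
anchorseq amplicons --config model.yaml --out-fasta amplicons.fasta --out-tsv amplicons.tsv
anchorseq simulate  --config model.yaml --out sim/ --seed 7
anchorseq run       --config model.yaml --sheet samples.csv \
                    --r1 sim/sim_R1.fastq --r2 sim/sim_R2.fastq --out results/
anchorseq stats power-table --frequencies 0.01,0.001,0.0001
```

`model.yaml` holds loci (inline sequence or FASTA), cuts and primers; the
run directory contains per-sample frequency and QC tables, the amplicon
FASTA with a junction-offset TSV, a JSON run summary, the echoed
configuration and a log with per-stage conservation counts. All coordinates
are 0-based, half-open.

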