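# msa-outliers

Outlier detection for multiple sequence alignments (MSAs) based on gap
patterns. Aberrant sequences — accidental non-homologues, partial
mistranslations, fragments, barely alignable distant relatives — disturb
alignment construction and every downstream analysis (trees, conservation,
structure prediction), and in alignments of thousands of rows they are
effectively invisible in a viewer. This package flags them automatically so
the core set can be realigned cleanly. It is written for people who build or
consume large protein alignments: pipeline authors, curators of family
databases, and anyone about to hand an MSA to a phylogenetics program.

## Method

Each aligned sequence is recoded as a binary gap mask (`X[i, l] = 1` if row
*i* has a gap in column *l*). A pairwise distance between rows *i* and *j*
sums per-column penalties over the columns where the masks disagree:

- **linear** — 1 per disagreeing column (Hamming distance on the masks);
- **affine** — 3 when the disagreement opens a run (previous column agreed),
  1 when it extends one;
- **cumulative** — 1, 2, 3, … within each run, so a run of *k* columns
  contributes *k*(*k*+1)/2.

The per-sequence raw score `D_i` is the mean distance of sequence *i* to the
others, taken from the full *N*×*N* matrix or, for large *N*, from an
mBed-style reduction: distances to *M* = max(5, ⌈log₂ *N*⌉) randomly chosen
seed sequences, dropping the cost from *O*(*N*²) to *O*(*N* log *N*).

Raw scores are family-specific, so they are normalised before thresholding:

- **bootstrap** — *B* pseudo-replicates of the score vector resampled with
  replacement give estimates s̄ (mean of replicate means) and σ (mean of
  replicate standard deviations); the outlier score is *z*ᵢ = (*D*ᵢ − s̄)/σ;
- **IQR** — with quartiles Q1, Q3 and *r* = Q3 − Q1, scores inside
  (Q1, Q3) get 0, scores above Q3 get (*D*ᵢ − Q3)/*r*, scores below Q1 get
  (Q1 − *D*ᵢ)/*r* on the lower tail.

A sequence is flagged when its outlier score exceeds the threshold *T*
(default 2; 2–10 is the sensible range). Unaligned FASTA input is supported
through an all-vs-all BLASTP search: summed best bit scores per sequence take
the place of distances, with the tail convention flipped (low total
similarity is suspicious). Precomputed square Phylip distance matrices are
accepted directly.

## Worked example

`examples/detect_outliers_in_alignment.py` builds a 500-sequence synthetic
family (495 rows sharing one gap architecture plus 5 injected rows with a
disjoint architecture) and runs the default pipeline:

```
alignment: N=500 sequences, L=300 columns
flagged 12 sequences at threshold 2 (bootstrap estimates: mean=45.53, sd=8.52)
id        raw distance   outlier score
out0003         90.5          5.27 <- flagged
out0004         88.0          4.98 <- flagged
out0002         80.6          4.11 <- flagged
out0005         74.6          3.41 <- flagged
out0001         69.6          2.82 <- flagged
seq0460         68.8          2.73 <- flagged
seq0418         68.1          2.65 <- flagged
injected outliers recovered: 5/5, false positives: 7
```

The raw distance is a sequence's mean gap-pattern distance to the rest; the
outlier score expresses it in bootstrap standard deviations above the
estimated family mean. All five injected outliers take the top five scores;
the seven flagged core sequences (1.4 % of the family) are the tail of the
family's own gap-pattern variability, the price of a permissive threshold.

The same pipeline is available from the shell:

```sh
msa-outliers detect --in family.fasta --metric linear --norm bootstrap --threshold 2
msa-outliers simulate --n-core 495 --outliers 5 --out-fasta demo.fasta
```

`detect` writes a tab-separated report (id, raw score, outlier score, flag)
plus core and outlier FASTA files that partition the input. The other
examples cover the mBed approximation (`large_family_mbed.py`), precomputed
matrices (`precomputed_distance_matrix.py`), the BLASTP path
(`unaligned_blast_screen.py`) and threshold benchmarking
(`benchmark_detector.py`).

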