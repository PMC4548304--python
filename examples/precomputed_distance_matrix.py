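"""Screen a precomputed Phylip distance matrix for outliers.

Any square symmetric distance matrix works — not only gap distances —
so the normalisation and classification machinery can be reused on
distances from other programs. Here a toy 8-sequence matrix has one
row of inflated distances.
"""

import tempfile
from pathlib import Path

import numpy as np

from msa_outliers import DistanceMatrixFile, RunConfig, run, write_phylip_distmat

rng = np.random.default_rng(3)
n = 8
base = rng.uniform(0.1, 0.3, size=(n, n))
values = np.triu(base, 1)
values[:, -1] = np.linspace(0.9, 1.1, n)  # the last sequence is far from everyone
values = np.triu(values, 1) + np.triu(values, 1).T

workdir = Path(tempfile.mkdtemp())
matrix_path = workdir / "distances.phy"
write_phylip_distmat(DistanceMatrixFile(
    labels=tuple(f"seq{i}" for i in range(n)), values=values), matrix_path)

result = run(RunConfig(
    input_path=matrix_path,
    normalisation="iqr",
    out_report=workdir / "report.tsv",
))
report = result.report
print(f"read {n}x{n} matrix; IQR stats: Q1={report.stats.q1:.3f}, "
      f"Q3={report.stats.q3:.3f}, r={report.stats.iqr:.3f}")
for i, seq_id in enumerate(report.ids):
    mark = " <- flagged" if report.flags[i] else ""
    print(f"{seq_id}: mean distance {report.raw_scores.scores[i]:.3f}, "
          f"outlier score {report.outlier_scores[i]:.2f}{mark}")
# An outlier score of s means the sequence's mean distance lies s
# interquartile ranges above the third quartile; only the report is
# written for matrix input (there are no sequences to partition).
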