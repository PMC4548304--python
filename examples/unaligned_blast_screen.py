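"""Screen unaligned sequences using all-vs-all BLASTP bit scores.

Without an alignment there is no gap signal, so similarity substitutes
for distance: every pair is searched with blastp at default parameters,
the best bit score per pair is kept, and each sequence's summed
similarity to the rest is bootstrapped. A sequence with anomalously LOW
total similarity is the outlier candidate. Requires NCBI BLAST+ on PATH.
"""

import shutil
import sys

import numpy as np

from msa_outliers import (
    SequenceRecord,
    all_vs_all_similarity,
    bootstrap_stats,
    classify,
    normalise,
    similarity_scores,
)

if shutil.which("blastp") is None:
    sys.exit("blastp not found on PATH; install NCBI BLAST+ to run this example")

rng = np.random.default_rng(0)
AA = list("ACDEFGHIKLMNPQRSTVWY")
master = rng.choice(AA, size=120)
records = []
for i in range(8):  # eight mutated copies of one protein
    seq = master.copy()
    pos = rng.choice(120, size=12, replace=False)
    seq[pos] = rng.choice(AA, size=12)
    records.append(SequenceRecord(id=f"hom{i}", residues="".join(seq)))
records.append(SequenceRecord(id="rogue", residues="".join(rng.choice(AA, size=120))))

table = all_vs_all_similarity(records)
totals = similarity_scores(table, [r.id for r in records])
stats = bootstrap_stats(totals, replicates=1000, rng_seed=1)
report = classify(normalise(totals, stats), threshold=2.0, tail="upper",
                  kind="similarity", ids=totals.ids, raw_scores=totals, stats=stats)

print("id      total bit score   outlier score")
for i, seq_id in enumerate(report.ids):
    mark = " <- flagged" if report.flags[i] else ""
    print(f"{seq_id:<8}{totals.scores[i]:>15.1f}{report.outlier_scores[i]:>14.2f}{mark}")
# The rogue random sequence accumulates almost no similarity and lands
# far on the suspicious tail; homologues cluster near score 0.
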