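# Methods

## The model

The detector treats an alignment purely as a binary gap matrix
`X[N, L]` (1 = gap). The working assumption is that members of a family
share a common *gap architecture* — insertions and deletions fall in the
same column ranges — while a sequence that does not belong (a
non-homologue, a mistranslation, a fragment, a barely alignable distant
relative) is forced by the aligner into a gap pattern unlike everyone
else's. Its mean pairwise gap distance to the rest is therefore
anomalously large. Residue identity is deliberately ignored: the signal
is cheap, alignment-program-agnostic, and grows with exactly the kind of
misalignment that hurts downstream analyses. The flip side is that the
method has no power on gap-free or near-gap-free alignments (heavy gap
penalties upstream starve it of signal), and it cannot see a short
mismatched segment inside an otherwise well-aligned sequence — those are
jobs for column- or segment-level tools, not this one.

## Pairwise metrics

For mask rows `a`, `b`, let a *run* be a maximal stretch of columns
where `a[l] != b[l]`.

| metric     | per-column charge                     | run of length k |
|------------|---------------------------------------|-----------------|
| linear     | 1                                     | k               |
| affine     | 3 at run start, 1 inside              | k + 2           |
| cumulative | 1, 2, 3, … within the run             | k(k+1)/2        |

Two boundary conventions are fixed here because the recurrences
reference a column `l-1` that does not exist at `l = 0`: a disagreement
at column 0 is an *opening* (affine charge 3), and the cumulative
counter starts from an implicit agreeing column (`C[-1] = 0`), making
column 0 an ordinary case of the general branch. All three metrics
depend only on the column-agreement sequence, hence are symmetric; the
linear metric is a Hamming distance and satisfies the triangle
inequality, the other two do not claim to. Useful algebra, asserted as
test invariants: `linear <= affine <= 3*linear`, `cumulative >= linear`,
with equality of cumulative and linear exactly when no two adjacent
columns both disagree.

The implementation is vectorised (per-row batches over numpy boolean
arrays; the cumulative run position is computed with a
maximum-accumulate trick rather than a column loop), but the contract is
stated in pair evaluations: the full matrix performs exactly
`N(N-1)/2`, the seed mode `M(N-1)`. That count, not wall time, is how
the complexity claim is tested.

## Per-sequence scores

The raw score of sequence `i` is the *mean* of its pairwise distances to
the contributing set — all others in full mode, the `M` seeds in seed
mode (a seed's zero self-distance is excluded from its own mean, over
`M-1`, to avoid systematically deflating seed scores). Using the mean
rather than the plain sum makes full-mode and seed-mode scores
commensurable and thresholds comparable across `N`; since both
normalisations are scale-invariant, full-mode classifications are
unchanged by the choice.

### Seed (mBed-style) approximation

`M = max(5, ceil(log2 N))` seeds are drawn uniformly without
replacement under an explicit RNG seed (default fixed, so repeated runs
agree). The floor of 5 keeps tiny inputs stable; the user can override
`M`. `M = N` reduces exactly to full mode; `M = 1` is rejected because
the seed's own mean would be over zero pairs.

How faithful is the approximation? Under a family model where each of
`B` gap blocks (widths `w_b`) is carried independently with probability
`p`, the variance of the true mean distances across sequences is
`(1-2p)^2 p(1-p) * sum(w_b^2)` while the sampling variance of a mean
over `M` random seeds is `p(1-p) * sum(w_b^2) / M`, so the expected
squared correlation between seed means and full means is

    rho^2 = (1-2p)^2 / ((1-2p)^2 + 1/M)

— independent of `B` and the widths. At `M = 9` (i.e. `N = 500`) this
exceeds 0.9 only for block probabilities below roughly 0.15: rare-indel
families, which are exactly the regime where `N` is large and the
approximation is needed. The fidelity test therefore uses a 500-sequence
family with 20 ten-column blocks at `p = 0.08` (observed Spearman
~0.96–0.98); on denser architectures the ranking is noisier and the
full matrix is preferable — at `N = 500` it costs well under a second
anyway.

## Normalisation and classification

**Bootstrap** (default): `B = 1000` replicates of size `N` drawn with
replacement; `s_bar` = mean of replicate means, `sigma` = mean of
replicate sample standard deviations (divisor `N-1`). The replicate
count and divisor are this package's choices; `B = 1000` puts the Monte
Carlo error of the estimates well below the spacing of scores near the
threshold at the problem sizes involved. The resampler accepts an
injectable index sampler so tests can pin exact expectations (identity
replicate at `B = 1` reproduces the plain mean and sd).

**IQR**: quartiles by linear interpolation at ranks `0.25(N-1)` and
`0.75(N-1)` on the sorted vector (the common "type 7" convention; the
estimator is a configuration point of the code and pinned in tests).
Scores strictly inside `(Q1, Q3)` are exactly 0. One signed vector
carries both tails: upper-tail excess is positive, lower-tail shortfall
is stored negative with magnitude `(Q1 - D_i)/r`.

A sequence is flagged when its score on the active tail *exceeds* `T`.
The published description of the lower-tail IQR rule inverts the
inequality relative to the other two rules; this implementation treats
that as a typo and flags score-exceeds-threshold on every tail. The
default tail is upper-only for distance input — a sequence unusually
*close* to everything is not an alignment outlier — with `lower` and
`both` available. For similarity input (unaligned mode) the sign is
flipped before tail logic, so anomalously low total similarity lands on
the upper tail. `T = 2` is the default operating point; raising `T`
can only shrink the flagged set.

**Degenerate spread**: `sigma = 0` (all scores identical) and `r = 0`
(too many ties) raise explicit errors — the `r = 0` message advises
switching to the bootstrap, whose estimators tolerate ties — rather than
silently reporting an all-core result. The one deliberate exception is
an alignment with *no gap signal at all* (gap-free, or all masks
identical): that is a valid input on which the method simply has nothing
to say, so the pipeline writes an all-core result with a notice instead
of failing.

## Unaligned mode

All-vs-all `blastp` at default parameters against a temporary database
built from the input itself, tabular output; per ordered pair the best
bit score across HSPs is kept and the pair is symmetrised by the maximum
of the two directions (best-hit is the least surprising aggregation;
summing HSPs would double-count split alignments). Missing hits count 0.
Only bootstrap normalisation is offered (bit-score totals are heavily
tied when rogues have no hits, which breaks quartiles), and no seed
mode (the reduction is defined over the alignment gap metric). This
path is noticeably less sensitive than the aligned one and exists as a
pre-alignment screen.

## Synthetic data generator

`synthgen` emulates the seeded-family evaluation design: a core family
shares a layout of gap blocks, each carried per-sequence with
probability `p` and jittered at the boundaries by ±`jitter` columns;
outliers are drawn from a second model with a disjoint (unrelated
family) or half-shared (distant homologue) layout and must fall within
±10 % of the family's average ungapped length so length alone cannot
give them away. Residues are uniform random amino acids — irrelevant to
the gap-only detector, which is also why unaligned-mode tests instead
use mutated copies of a master sequence. All randomness flows from
explicit seeds; every dataset is regenerable byte-for-byte.

The canonical study conditions (`study_family_model`) are `N = 500`,
`L = 300`, ten 10-column blocks at `p = 0.3`, jitter 2; outliers use ten
disjoint 8-column blocks at `p = 0.5` (expected ungapped length 260 vs
the family's 270, inside the ±10 % rule), about 1 % of the dataset —
preserving the class imbalance that makes precision interesting. Under
these conditions the measured operating characteristics are a mean ROC
AUC around 0.97 for disjoint-architecture outliers and a false-positive
rate around 3–4 % at `T = 2` on outlier-free controls (recomputed by
`scripts/acceptance.py` and the acceptance tests at 20 datasets × 500
sequences; sizes chosen to keep the whole suite in minutes on one core).

What passing these tests does *not* show: the generator composes gap
masks directly rather than running an aligner over seeded sequences, so
its gap architectures are cleaner than those an aligner would produce
and absolute AUC/FPR values are not comparable to benchmarks on real
family databases — only the qualitative ordering (disjoint
architectures easy, overlapping architectures harder, FPR roughly
constant with or without outliers) carries over. Real families also
correlate block presence with phylogeny, which the independent-Bernoulli
model ignores.

## Input handling

FASTA is the one alignment dialect parsed (gap characters `-` and `.`
by default, configurable; residues uppercased; duplicate ids are a hard
error since scores are reported per id). Distance matrices are square
relaxed Phylip: leading count, whitespace-terminated labels of any
length, symmetric within 1e-6 with zero diagonal; lower-triangular
files are rejected with a pointer to the expected layout. Input kind is
auto-detected (leading integer → matrix; equal-length gapped FASTA →
MSA; otherwise unaligned) and overridable, because a gap-free alignment
is indistinguishable from unaligned input by content alone.

## Known limitations

- No power without gaps; not a residue-conservation method.
- Segment-level outliers (short mistranslated stretches) are out of
  scope by design.
- Nucleotide alignments are untested territory.
- The IQR path inflates scores when `r` is small; the bootstrap is the
  robust default.
- Seed-mode fidelity degrades on dense, high-entropy gap architectures
  (see the correlation formula above); use the full matrix when `N`
  permits.
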