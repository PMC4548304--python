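"""Gap-pattern distances between aligned sequences.

The detector never looks at residue identity: each aligned sequence is
reduced to a binary gap mask (1 = gap, 0 = residue) and sequences are
compared purely by how their gap placement differs. Three pairwise
metrics are offered:

``linear``
    counts the columns where exactly one of the two sequences has a gap
    (Hamming distance on the masks); insensitive to whether the
    disagreement comes as one long run or many short ones.
``affine``
    charges 3 for a column that opens a run of disagreement (previous
    column agreed, or the run starts at column 0) and 1 for each column
    that extends it, so short scattered indel differences are penalised
    relatively more than one long one.
``cumulative``
    charges 1, 2, 3, ... for successive columns of a disagreement run,
    so a maximal run of k columns contributes k(k+1)/2 and long
    architectural differences dominate.

Per-sequence scores are the mean pairwise distance to the other
sequences, either from the full N x N matrix or from an mBed-style
reduced matrix against ~log2(N) randomly chosen seed sequences, which
drops the cost from O(N^2) to O(N log N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import MsaOutliersError
from .io import DEFAULT_GAP_CHARS, Alignment

METRICS = ("linear", "affine", "cumulative")

#: Default RNG seed for mBed seed selection, so repeated runs of the tool
#: flag the same sequences unless the user asks for a different seed.
DEFAULT_RNG_SEED = 42


@dataclass(frozen=True)
class GapMask:
    """Binary gap matrix for an alignment: 1 = gap, 0 = residue."""

    mask: np.ndarray = field(repr=False)  # (N, L) uint8
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        mask = np.ascontiguousarray(self.mask, dtype=np.uint8)
        if mask.ndim != 2 or mask.shape[0] != len(self.ids):
            raise MsaOutliersError("mask shape does not match id list")
        if not np.isin(mask, (0, 1)).all():
            raise MsaOutliersError("gap mask entries must be 0 or 1")
        object.__setattr__(self, "mask", mask)

    @property
    def n(self) -> int:
        return self.mask.shape[0]

    @property
    def length(self) -> int:
        return self.mask.shape[1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise gap distances: full N x N or reduced M x N (mBed mode).

    ``n_pair_evals`` counts the distinct sequence pairs actually evaluated,
    which is how the O(N^2) vs O(N log N) contract is asserted without
    timing anything.
    """

    values: np.ndarray = field(repr=False)
    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    mode: str  # "full" | "mbed"
    metric: str
    n_pair_evals: int
    seed_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if (values < 0).any():
            raise MsaOutliersError("distances must be non-negative")
        if self.mode == "full":
            if values.shape[0] != values.shape[1]:
                raise MsaOutliersError("full-mode matrix must be square")


@dataclass(frozen=True)
class ScoreVector:
    """Per-sequence aggregate score, one entry per input sequence.

    ``kind`` is "distance" for gap metrics (large = suspicious) and
    "similarity" for summed search bit scores (small = suspicious).
    """

    scores: np.ndarray = field(repr=False)
    ids: tuple[str, ...]
    kind: str = "distance"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.shape[0] != len(self.ids):
            raise MsaOutliersError("score vector length does not match ids")
        if self.kind == "distance" and (scores < 0).any():
            raise MsaOutliersError("distance scores must be non-negative")
        if self.kind not in ("distance", "similarity"):
            raise MsaOutliersError(f"unknown score kind {self.kind!r}")


def gap_mask(alignment: Alignment, gap_chars: Iterable[str] = DEFAULT_GAP_CHARS) -> GapMask:
    """Binary-encode an alignment: mask[i, l] = 1 iff column l of row i is a gap."""
    gaps = set(gap_chars)
    chars = np.array([list(rec.residues) for rec in alignment.records])
    mask = np.isin(chars, sorted(gaps)).astype(np.uint8)
    return GapMask(mask=mask, ids=alignment.ids)


def _as_row(x: Sequence[int] | np.ndarray) -> np.ndarray:
    row = np.asarray(x, dtype=np.uint8)
    if row.ndim != 1:
        raise MsaOutliersError("mask rows must be one-dimensional")
    return row


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise MsaOutliersError(
            f"mask rows have different lengths ({a.shape[0]} vs {b.shape[0]})"
        )


def _batch_linear(diff: np.ndarray) -> np.ndarray:
    return diff.sum(axis=1, dtype=np.int64).astype(float)


def _batch_affine(diff: np.ndarray) -> np.ndarray:
    prev = np.zeros_like(diff)
    prev[:, 1:] = diff[:, :-1]
    opens = diff & ~prev
    extends = diff & prev
    return (3 * opens.sum(axis=1, dtype=np.int64)
            + extends.sum(axis=1, dtype=np.int64)).astype(float)


def _batch_cumulative(diff: np.ndarray) -> np.ndarray:
    # Position of the most recent agreeing column gives the running run
    # length without a per-column Python loop.
    r, length = diff.shape
    idx = np.arange(length)
    last_agree = np.where(~diff, idx, -1)
    np.maximum.accumulate(last_agree, axis=1, out=last_agree)
    run_pos = (idx - last_agree) * diff
    return run_pos.sum(axis=1, dtype=np.int64).astype(float)


_BATCH = {"linear": _batch_linear, "affine": _batch_affine, "cumulative": _batch_cumulative}


def _batch_distances(row: np.ndarray, others: np.ndarray, metric: str) -> np.ndarray:
    """Distances from one mask row to a block of rows, vectorised."""
    if metric not in METRICS:
        raise MsaOutliersError(f"unknown metric {metric!r}; choose from {METRICS}")
    diff = (others != row[None, :])
    return _BATCH[metric](diff)


def pair_linear(a: Sequence[int], b: Sequence[int]) -> float:
    """Count of columns where the two gap masks disagree."""
    a, b = _as_row(a), _as_row(b)
    _check_pair(a, b)
    return float(_batch_distances(a, b[None, :], "linear")[0])


def pair_affine(a: Sequence[int], b: Sequence[int]) -> float:
    """Disagreement score with opening penalty 3, extension penalty 1."""
    a, b = _as_row(a), _as_row(b)
    _check_pair(a, b)
    return float(_batch_distances(a, b[None, :], "affine")[0])


def pair_cumulative(a: Sequence[int], b: Sequence[int]) -> float:
    """Disagreement score growing 1, 2, 3, ... within each run."""
    a, b = _as_row(a), _as_row(b)
    _check_pair(a, b)
    return float(_batch_distances(a, b[None, :], "cumulative")[0])


def full_matrix(mask: GapMask, metric: str = "linear") -> DistanceMatrix:
    """All-vs-all distance matrix; exactly N(N-1)/2 pair evaluations."""
    n = mask.n
    if n < 2:
        raise MsaOutliersError("need at least 2 sequences for a distance matrix")
    if metric not in METRICS:
        raise MsaOutliersError(f"unknown metric {metric!r}; choose from {METRICS}")
    values = np.zeros((n, n), dtype=float)
    n_evals = 0
    for i in range(n - 1):
        d = _batch_distances(mask.mask[i], mask.mask[i + 1:], metric)
        values[i, i + 1:] = d
        values[i + 1:, i] = d
        n_evals += n - 1 - i
    return DistanceMatrix(
        values=values, row_ids=mask.ids, col_ids=mask.ids,
        mode="full", metric=metric, n_pair_evals=n_evals,
    )


def default_seed_count(n: int) -> int:
    """mBed seed count: max(5, ceil(log2 N)), capped at N."""
    return min(n, max(5, math.ceil(math.log2(n))))


def mean_scores(matrix: DistanceMatrix) -> ScoreVector:
    """Mean distance of each sequence to the others (full mode only)."""
    if matrix.mode != "full":
        raise MsaOutliersError("mean_scores requires a full-mode matrix; "
                               "mBed mode computes its means directly")
    n = matrix.values.shape[0]
    if n < 2:
        raise MsaOutliersError("need at least 2 sequences")
    scores = matrix.values.sum(axis=1) / (n - 1)
    return ScoreVector(scores=scores, ids=matrix.row_ids, kind="distance")


def mbed_means(mask: GapMask, metric: str = "linear",
               n_seeds: int | None = None,
               rng_seed: int = DEFAULT_RNG_SEED) -> ScoreVector:
    """Approximate per-sequence mean distances from M random seed sequences.

    M distinct seeds are drawn uniformly without replacement (reproducible
    under ``rng_seed``); each sequence's score is its mean distance to the
    seeds, excluding the zero self-distance when the sequence is itself a
    seed. At most M*N - M pairs are evaluated, which is the O(N log N)
    saving over the full matrix. With ``n_seeds == N`` the result equals
    ``mean_scores(full_matrix(...))`` exactly.
    """
    n = mask.n
    if n < 2:
        raise MsaOutliersError("need at least 2 sequences")
    m = default_seed_count(n) if n_seeds is None else n_seeds
    if not 2 <= m <= n:
        raise MsaOutliersError(
            f"n_seeds must be between 2 and N={n} (got {m}); a single seed "
            "leaves its own mean undefined"
        )
    rng = np.random.default_rng(rng_seed)
    seeds = np.sort(rng.choice(n, size=m, replace=False))
    values = np.zeros((m, n), dtype=float)
    n_evals = 0
    for k, s in enumerate(seeds):
        # Evaluate all non-self pairs for this seed in one batch.
        others = np.delete(np.arange(n), s)
        values[k, others] = _batch_distances(mask.mask[s], mask.mask[others], metric)
        n_evals += n - 1
    totals = values.sum(axis=0)
    denom = np.full(n, m, dtype=float)
    denom[seeds] = m - 1  # a seed's zero self-distance does not count
    scores = totals / denom
    # n_evals tracks the evaluation-count contract: M*(N-1) <= M*N.
    assert n_evals == m * (n - 1)
    return ScoreVector(scores=scores, ids=mask.ids, kind="distance")
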