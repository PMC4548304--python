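"""Normalise per-sequence scores and flag outliers.

Raw mean distances depend on the particular family (its length, gap
density, diversity), so they are normalised before a universal threshold
T can be applied. Two normalisations are offered:

bootstrap
    B pseudo-replicates of the score vector are drawn with replacement;
    the estimated centre s_bar is the mean of the replicate means and the
    estimated spread sigma the mean of the replicate sample standard
    deviations. Each sequence gets the z-like score (D_i - s_bar) / sigma.

interquartile range (IQR)
    Q1 and Q3 of the sorted scores give r = Q3 - Q1. Scores strictly
    inside (Q1, Q3) get 0; a score above Q3 gets (D_i - Q3) / r; a score
    below Q1 gets magnitude (Q1 - D_i) / r on the lower tail (stored
    negative here so one signed vector carries both tails).

A sequence is flagged when its score on the active tail exceeds T
(default 2; between roughly 2 and 10 is sensible, trading stringency for
sensitivity). With identical or near-identical scores sigma or r can be
zero; those degenerate cases raise instead of silently flagging nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import MsaOutliersError, ZeroSpreadError
from .gapdist import ScoreVector

DEFAULT_THRESHOLD = 2.0
DEFAULT_REPLICATES = 1000

#: Optional override for the bootstrap's index draws, mapping
#: (rng, n_replicates, n) -> integer index array of shape (n_replicates, n).
IndexSampler = Callable[[np.random.Generator, int, int], np.ndarray]


@dataclass(frozen=True)
class NormalisationStats:
    """The statistics a normalisation was computed from."""

    method: str  # "bootstrap" | "iqr"
    est_mean: float | None = None
    est_sd: float | None = None
    replicates: int | None = None
    rng_seed: int | None = None
    q1: float | None = None
    q3: float | None = None
    iqr: float | None = None

    def __post_init__(self) -> None:
        if self.method == "bootstrap":
            if self.est_sd is not None and self.est_sd < 0:
                raise MsaOutliersError("estimated sd must be non-negative")
        elif self.method == "iqr":
            if self.q3 is not None and self.q1 is not None and self.q3 < self.q1:
                raise MsaOutliersError("Q3 must be >= Q1")
        else:
            raise MsaOutliersError(f"unknown normalisation method {self.method!r}")


@dataclass(frozen=True)
class OutlierReport:
    """Per-sequence scores, flags and the statistics behind them."""

    ids: tuple[str, ...]
    raw_scores: ScoreVector
    outlier_scores: np.ndarray = field(repr=False)
    flags: np.ndarray = field(repr=False)
    threshold: float
    stats: NormalisationStats
    tail: str

    @property
    def n_flagged(self) -> int:
        return int(np.count_nonzero(self.flags))


def bootstrap_stats(scores: ScoreVector, replicates: int = DEFAULT_REPLICATES,
                    rng_seed: int = 0,
                    index_sampler: IndexSampler | None = None) -> NormalisationStats:
    """Bootstrap estimates of the score distribution's mean and sd.

    Each replicate resamples all N scores with replacement; its sample
    standard deviation uses the N-1 divisor. ``index_sampler`` lets tests
    inject deterministic draws (e.g. the identity permutation).
    """
    x = scores.scores
    n = x.shape[0]
    if n < 2:
        raise MsaOutliersError("need at least 2 scores to bootstrap")
    if replicates < 1:
        raise MsaOutliersError("replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    if index_sampler is None:
        idx = rng.integers(0, n, size=(replicates, n))
    else:
        idx = np.asarray(index_sampler(rng, replicates, n))
    reps = x[idx]
    est_mean = float(reps.mean(axis=1).mean())
    est_sd = float(reps.std(axis=1, ddof=1).mean())
    return NormalisationStats(
        method="bootstrap", est_mean=est_mean, est_sd=est_sd,
        replicates=replicates, rng_seed=rng_seed,
    )


def iqr_stats(scores: ScoreVector) -> NormalisationStats:
    """Quartiles of the score vector, linearly interpolated (type 7).

    Q1 and Q3 sit at ranks 0.25(N-1) and 0.75(N-1) of the 0-indexed
    sorted vector. A zero interquartile range (many identical scores)
    raises, with the advice to switch to the bootstrap, whose estimators
    tolerate ties.
    """
    x = scores.scores
    if x.shape[0] < 4:
        raise MsaOutliersError("need at least 4 scores for quartiles")
    q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
    r = float(q3 - q1)
    if r == 0.0:
        raise ZeroSpreadError(
            "interquartile range is 0 (too many identical scores); "
            "use bootstrap normalisation instead"
        )
    return NormalisationStats(method="iqr", q1=float(q1), q3=float(q3), iqr=r)


def normalise(scores: ScoreVector, stats: NormalisationStats) -> np.ndarray:
    """Signed normalised outlier scores.

    Bootstrap: z_i = (D_i - s_bar) / sigma. IQR: (D_i - Q3)/r above Q3,
    -(Q1 - D_i)/r below Q1 (negative sign marks the lower tail), 0 inside
    the quartiles. Upper-tail outliers are positive under both methods.
    """
    x = scores.scores
    if stats.method == "bootstrap":
        if stats.est_sd == 0:
            raise ZeroSpreadError(
                "estimated standard deviation is 0 (all scores identical); "
                "no finite outlier scores exist - inspect the input"
            )
        return (x - stats.est_mean) / stats.est_sd
    upper = x > stats.q3
    lower = x < stats.q1
    out = np.zeros_like(x, dtype=float)
    out[upper] = (x[upper] - stats.q3) / stats.iqr
    out[lower] = -(stats.q1 - x[lower]) / stats.iqr
    return out


def classify(normalised: np.ndarray | Sequence[float], threshold: float = DEFAULT_THRESHOLD,
             tail: str = "upper", kind: str = "distance", *,
             ids: tuple[str, ...] | None = None,
             raw_scores: ScoreVector | None = None,
             stats: NormalisationStats | None = None) -> OutlierReport:
    """Flag sequences whose normalised score exceeds T on the active tail.

    For distance scores the upper tail is suspicious (far from
    everything); for similarity scores the convention is flipped first,
    so a sequence with anomalously LOW total similarity lands on the
    upper tail. ``tail`` may be "upper", "lower" or "both"; raising T
    can only shrink the flagged set.
    """
    if threshold < 0:
        raise MsaOutliersError("threshold must be non-negative")
    if tail not in ("upper", "lower", "both"):
        raise MsaOutliersError(f"unknown tail {tail!r}")
    z = np.asarray(normalised, dtype=float)
    if kind == "similarity":
        z = -z
    elif kind != "distance":
        raise MsaOutliersError(f"unknown score kind {kind!r}")
    if tail == "upper":
        flags = z > threshold
    elif tail == "lower":
        flags = -z > threshold
    else:
        flags = np.abs(z) > threshold
    if ids is None:
        ids = raw_scores.ids if raw_scores is not None else tuple(
            str(i) for i in range(z.shape[0]))
    if raw_scores is None:
        raw_scores = ScoreVector(scores=np.abs(z), ids=ids, kind="distance")
    if stats is None:
        stats = NormalisationStats(method="bootstrap", est_mean=0.0, est_sd=1.0,
                                   replicates=1, rng_seed=0)
    return OutlierReport(
        ids=tuple(ids), raw_scores=raw_scores, outlier_scores=z,
        flags=flags, threshold=float(threshold), stats=stats, tail=tail,
    )
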