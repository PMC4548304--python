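"""Synthetic alignment families with known, labelled outliers.

Real evaluation data for this problem comes from protein-family
alignments seeded with sequences from unrelated families; at desk scale
the same design is emulated directly on gap architectures. A *family* is
a set of equal-length rows sharing a layout of gap blocks: each core
sequence carries each block with some probability, with small random
jitter on the block boundaries. Injected *outliers* are drawn from a
second family model whose block layout is disjoint (unrelated family) or
partially overlapping (distant homologue), and must be within a length
tolerance of the family average (default +-10 %) so that sheer length
does not give them away. Residue columns are filled with uniform random
amino acids: the aligned-mode detector never reads residue identity, so
residue realism is irrelevant here (unaligned-mode tests instead mutate
copies of a master sequence).

``benchmark_run`` sweeps classification thresholds over such labelled
datasets and reports TPR/FPR/precision/recall plus the trapezoidal ROC
AUC, mirroring how detectors of this kind are benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MsaOutliersError
from .gapdist import METRICS, full_matrix, gap_mask, mbed_means, mean_scores
from .io import Alignment, SequenceRecord
from .outlier import bootstrap_stats, classify, iqr_stats, normalise

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FamilyModel:
    """Generative model for one gap-architecture family."""

    length: int
    n_core: int
    gap_block_positions: tuple[tuple[int, int], ...]
    per_block_gap_prob: float
    jitter: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_core < 2:
            raise MsaOutliersError("need length >= 1 and n_core >= 2")
        if not 0.0 <= self.per_block_gap_prob <= 1.0:
            raise MsaOutliersError("per_block_gap_prob must be in [0, 1]")
        if self.jitter < 0:
            raise MsaOutliersError("jitter must be non-negative")
        for start, end in self.gap_block_positions:
            if not (0 <= start < end <= self.length):
                raise MsaOutliersError(
                    f"gap block [{start}, {end}) outside [0, {self.length})"
                )

    @property
    def expected_ungapped_length(self) -> float:
        gap_cols = sum(e - s for s, e in self.gap_block_positions)
        return self.length - self.per_block_gap_prob * gap_cols


@dataclass(frozen=True)
class SeededDataset:
    """A family alignment with injected outliers and ground-truth labels."""

    alignment: Alignment
    labels: np.ndarray = field(repr=False)  # bool, True = injected outlier

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=bool)
        object.__setattr__(self, "labels", labels)
        if labels.shape[0] != self.alignment.n:
            raise MsaOutliersError("labels length does not match alignment")

    @property
    def n_outliers(self) -> int:
        return int(self.labels.sum())


def _sample_rows(model: FamilyModel, n: int, rng: np.random.Generator,
                 id_prefix: str) -> list[SequenceRecord]:
    length = model.length
    records = []
    for i in range(n):
        row = rng.choice(AMINO_ACIDS, size=length)
        for start, end in model.gap_block_positions:
            if rng.random() < model.per_block_gap_prob:
                if model.jitter:
                    start = start + int(rng.integers(-model.jitter, model.jitter + 1))
                    end = end + int(rng.integers(-model.jitter, model.jitter + 1))
                start, end = max(0, start), min(length, max(start + 1, end))
                row[start:end] = "-"
        records.append(SequenceRecord(id=f"{id_prefix}{i + 1:04d}",
                                      residues="".join(row)))
    return records


def make_family(model: FamilyModel) -> Alignment:
    """Sample ``n_core`` sequences from a family model, reproducibly."""
    rng = np.random.default_rng(model.rng_seed)
    return Alignment(records=tuple(_sample_rows(model, model.n_core, rng, "seq")))


def inject_outliers(family: Alignment, k: int, outlier_model: FamilyModel,
                    length_tolerance: float = 0.10) -> SeededDataset:
    """Seed a family with ``k`` sequences from a different family model.

    The outlier model's expected ungapped length must be within
    ``length_tolerance`` of the family's average ungapped length.
    The combined rows are shuffled; all randomness (outlier draws and the
    shuffle) is driven by ``outlier_model.rng_seed``.
    """
    if k < 0:
        raise MsaOutliersError("k must be non-negative")
    mean_len = float(np.mean([len(rec.ungapped()) for rec in family.records]))
    expected = outlier_model.expected_ungapped_length
    if k > 0 and abs(expected - mean_len) > length_tolerance * mean_len:
        raise MsaOutliersError(
            f"outlier model expected ungapped length {expected:.1f} deviates "
            f"more than {length_tolerance:.0%} from the family average "
            f"{mean_len:.1f}"
        )
    if k > 0 and outlier_model.length != family.length:
        raise MsaOutliersError("outlier model length must match the alignment length")
    rng = np.random.default_rng(outlier_model.rng_seed)
    outliers = _sample_rows(outlier_model, k, rng, "out") if k else []
    records = list(family.records) + outliers
    labels = np.array([False] * family.n + [True] * k)
    order = rng.permutation(len(records))
    return SeededDataset(
        alignment=Alignment(records=tuple(records[i] for i in order)),
        labels=labels[order],
    )


# ---------------------------------------------------------------------------
# Canonical study conditions: a 500-sequence family of length 300 with ten
# 10-column gap blocks, each carried by 30 % of sequences, boundary jitter
# +-2; outliers come from a disjoint block layout of matching expected
# length. These are the fixed conditions under which detection performance
# is measured; they are not tuning knobs.

def study_family_model(n_core: int = 500, rng_seed: int = 0) -> FamilyModel:
    blocks = tuple((30 * b + 10, 30 * b + 20) for b in range(10))
    return FamilyModel(length=300, n_core=n_core, gap_block_positions=blocks,
                       per_block_gap_prob=0.3, jitter=2, rng_seed=rng_seed)


def study_outlier_model(rng_seed: int = 0, overlap: bool = False) -> FamilyModel:
    """Outlier family: disjoint blocks, or half-shared ("same clan" analog)."""
    disjoint = tuple((30 * b, 30 * b + 8) for b in range(10))
    if overlap:
        shared = tuple((30 * b + 10, 30 * b + 20) for b in range(5))
        blocks = shared + disjoint[5:]
    else:
        blocks = disjoint
    return FamilyModel(length=300, n_core=2, gap_block_positions=blocks,
                       per_block_gap_prob=0.5, jitter=2, rng_seed=rng_seed)


@dataclass(frozen=True)
class DetectorConfig:
    """Detector settings used by ``benchmark_run``."""

    metric: str = "linear"
    mode: str = "full"  # "full" | "mbed"
    n_seeds: int | None = None
    normalisation: str = "bootstrap"  # "bootstrap" | "iqr"
    replicates: int = 1000
    rng_seed: int = 0
    tail: str = "upper"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise MsaOutliersError(f"unknown metric {self.metric!r}")
        if self.mode not in ("full", "mbed"):
            raise MsaOutliersError(f"unknown mode {self.mode!r}")
        if self.normalisation not in ("bootstrap", "iqr"):
            raise MsaOutliersError(f"unknown normalisation {self.normalisation!r}")


def detector_scores(alignment: Alignment, config: DetectorConfig = DetectorConfig()) -> np.ndarray:
    """Normalised outlier scores for one alignment under a detector config."""
    mask = gap_mask(alignment)
    if config.mode == "mbed":
        raw = mbed_means(mask, config.metric, config.n_seeds, config.rng_seed)
    else:
        raw = mean_scores(full_matrix(mask, config.metric))
    if config.normalisation == "bootstrap":
        stats = bootstrap_stats(raw, config.replicates, config.rng_seed)
    else:
        stats = iqr_stats(raw)
    return normalise(raw, stats)


def _roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the ROC built from every score threshold."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    pos = int(y.sum())
    neg = y.shape[0] - pos
    if pos == 0 or neg == 0:
        raise MsaOutliersError("AUC needs both classes present")
    tpr = np.concatenate([[0.0], np.cumsum(y) / pos])
    fpr = np.concatenate([[0.0], np.cumsum(~y) / neg])
    return float(np.trapezoid(tpr, fpr))


def benchmark_run(datasets: Iterable[SeededDataset],
                  config: DetectorConfig = DetectorConfig(),
                  thresholds: Sequence[float] = tuple(np.arange(0.0, 10.5, 0.5)),
                  ) -> tuple[pd.DataFrame, list[float]]:
    """Run the detector on labelled datasets and sweep the threshold.

    Returns a tidy table with one row per (dataset, threshold) holding
    TPR, FPR, precision and recall, plus the per-dataset trapezoidal ROC
    AUC computed from the continuous normalised scores.
    """
    rows = []
    aucs = []
    for d_idx, dataset in enumerate(datasets):
        scores = detector_scores(dataset.alignment, config)
        labels = dataset.labels
        if labels.any() and not labels.all():
            aucs.append(_roc_auc(scores, labels))
        else:
            aucs.append(float("nan"))
        pos = max(int(labels.sum()), 0)
        neg = labels.shape[0] - pos
        for t in thresholds:
            report = classify(scores, threshold=t, tail=config.tail)
            flags = report.flags
            tp = int((flags & labels).sum())
            fp = int((flags & ~labels).sum())
            rows.append({
                "dataset": d_idx,
                "threshold": float(t),
                "tpr": tp / pos if pos else float("nan"),
                "fpr": fp / neg if neg else float("nan"),
                "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
                "recall": tp / pos if pos else float("nan"),
            })
    return pd.DataFrame(rows), aucs


def write_dataset(dataset: SeededDataset, out_fasta, out_labels) -> None:
    """Write a seeded dataset as FASTA plus a tab-separated label file."""
    from .io import write_fasta

    write_fasta(dataset.alignment.records, out_fasta)
    from pathlib import Path

    with Path(out_labels).open("w") as fh:
        fh.write("sequence_id\tis_outlier\n")
        for rec, lab in zip(dataset.alignment.records, dataset.labels):
            fh.write(f"{rec.id}\t{'yes' if lab else 'no'}\n")
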