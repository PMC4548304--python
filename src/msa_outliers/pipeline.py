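"""End-to-end wiring: input detection, scoring, normalisation, output.

The workflow mirrors how the tool is meant to sit in an alignment
pipeline: align, screen for outliers, drop them, realign the core set.
Input may be a multiple sequence alignment (gap metric path), a
precomputed square Phylip distance matrix (means taken directly), or
unaligned sequences (external all-vs-all protein search, similarity
path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import gapdist, io, outlier, unaligned
from .errors import MsaOutliersError
from .gapdist import DEFAULT_RNG_SEED, ScoreVector
from .io import DEFAULT_GAP_CHARS

logger = logging.getLogger("msa_outliers")


@dataclass
class RunConfig:
    """Everything one detection run needs."""

    input_path: str | Path
    input_kind: str | None = None  # "msa" | "unaligned" | "distmat" | None = auto
    metric: str = "linear"
    mode: str = "full"  # "full" | "mbed"
    n_seeds: int | None = None
    normalisation: str = "bootstrap"  # "bootstrap" | "iqr"
    threshold: float = outlier.DEFAULT_THRESHOLD
    tail: str = "upper"
    replicates: int = outlier.DEFAULT_REPLICATES
    rng_seed: int = DEFAULT_RNG_SEED
    gap_chars: frozenset[str] = DEFAULT_GAP_CHARS
    out_report: str | Path = "outliers.tsv"
    out_core: str | Path = "core.fasta"
    out_outliers: str | Path = "outliers.fasta"
    blast_exe: str = "blastp"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise MsaOutliersError("threshold must be non-negative")


def detect_input_kind(path: str | Path) -> str:
    """Guess the input kind from file content.

    A leading integer token means a Phylip distance matrix; FASTA whose
    rows are all the same length and contain gap characters is an MSA;
    anything else FASTA-like is treated as unaligned. Heuristics can
    misfire (a gap-free alignment looks unaligned), so the kind is
    user-overridable.
    """
    path = Path(path)
    with path.open() as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.strip()
                break
    if not first:
        raise MsaOutliersError(f"{path} is empty")
    if not first.startswith(">"):
        try:
            int(first.split()[0])
            return "distmat"
        except ValueError:
            raise MsaOutliersError(f"{path}: not FASTA and not a Phylip matrix")
    records = io._parse_fasta(path)
    lengths = {len(r.residues) for r in records}
    gapped = any(c in DEFAULT_GAP_CHARS for r in records for c in r.residues)
    if len(lengths) == 1 and gapped and len(records) >= 2:
        return "msa"
    return "unaligned"


def _distmat_scores(path: str | Path) -> ScoreVector:
    dm = io.read_phylip_distmat(path)
    n = len(dm.labels)
    if n < 2:
        raise MsaOutliersError("distance matrix must cover at least 2 sequences")
    scores = dm.values.sum(axis=1) / (n - 1)
    return ScoreVector(scores=scores, ids=dm.labels, kind="distance")


@dataclass(frozen=True)
class RunResult:
    report: outlier.OutlierReport
    no_gap_signal: bool = False


def run(config: RunConfig) -> RunResult:
    """Execute one detection run and write the output files.

    Raises an ``MsaOutliersError`` subclass on any failure; the CLI turns
    that into a nonzero exit. A gap-free (or identically gapped) MSA is
    not an error: there is nothing for a gap-based detector to see, so an
    all-core result is written and flagged in the return value.
    """
    kind = config.input_kind or detect_input_kind(config.input_path)
    logger.info("input %s detected as %s", config.input_path, kind)

    alignment = None
    if kind == "msa":
        alignment = io.read_alignment(config.input_path, config.gap_chars)
        logger.info("alignment: N=%d, L=%d", alignment.n, alignment.length)
        if alignment.n > 1000 and config.mode == "full":
            logger.info("N > 1000: consider --mbed for O(N log N) scoring")
        mask = gapdist.gap_mask(alignment, config.gap_chars)
        if config.mode == "mbed":
            raw = gapdist.mbed_means(mask, config.metric, config.n_seeds,
                                     config.rng_seed)
        else:
            raw = gapdist.mean_scores(gapdist.full_matrix(mask, config.metric))
        if not raw.scores.any():
            logger.warning("no gap signal; no outliers detectable by this method")
            stats = outlier.NormalisationStats(
                method="iqr" if config.normalisation == "iqr" else "bootstrap",
                est_mean=0.0, est_sd=0.0, replicates=config.replicates,
                rng_seed=config.rng_seed, q1=0.0, q3=0.0, iqr=0.0)
            report = outlier.OutlierReport(
                ids=raw.ids, raw_scores=raw,
                outlier_scores=np.zeros(alignment.n),
                flags=np.zeros(alignment.n, dtype=bool),
                threshold=config.threshold, stats=stats, tail=config.tail)
            io.write_outputs(report, alignment, config.out_report,
                             config.out_core, config.out_outliers)
            return RunResult(report=report, no_gap_signal=True)
    elif kind == "distmat":
        if config.mode == "mbed":
            raise MsaOutliersError(
                "mBed mode needs sequences; a precomputed matrix is already full")
        raw = _distmat_scores(config.input_path)
    elif kind == "unaligned":
        records = io.read_unaligned(config.input_path)
        if len(records) < 2:
            raise MsaOutliersError("need at least 2 sequences")
        if config.normalisation != "bootstrap":
            raise MsaOutliersError("unaligned mode supports bootstrap normalisation only")
        if config.mode == "mbed":
            raise MsaOutliersError("mBed mode applies to the alignment gap metric only")
        table = unaligned.all_vs_all_similarity(records, config.blast_exe)
        raw = unaligned.similarity_scores(table, [r.id for r in records])
    else:
        raise MsaOutliersError(f"unknown input kind {kind!r}")

    if config.normalisation == "bootstrap":
        stats = outlier.bootstrap_stats(raw, config.replicates, config.rng_seed)
    else:
        stats = outlier.iqr_stats(raw)
    scores = outlier.normalise(raw, stats)
    report = outlier.classify(scores, config.threshold, config.tail, raw.kind,
                              ids=raw.ids, raw_scores=raw, stats=stats)
    logger.info("metric=%s mode=%s normalisation=%s flagged=%d/%d",
                config.metric, config.mode, config.normalisation,
                report.n_flagged, len(report.ids))

    if alignment is not None:
        io.write_outputs(report, alignment, config.out_report,
                         config.out_core, config.out_outliers)
    elif kind == "unaligned":
        io.write_report(report, config.out_report)
        io.write_partition(records, report.flags, config.out_core,
                           config.out_outliers)
    else:
        io.write_report(report, config.out_report)
        logger.info("distance-matrix input: core/outlier FASTA skipped")
    return RunResult(report=report)
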