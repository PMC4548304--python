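"""Outlier screening for unaligned protein sequences.

Without an alignment there is no gap signal, so similarity stands in for
distance: an all-vs-all protein search (NCBI BLAST+ ``blastp`` at default
parameters) scores every pair, the best bit score per pair is kept, and
each sequence's total similarity to the rest becomes its raw score. A
genuine outlier accumulates anomalously LITTLE similarity, so the score
vector is handed to the bootstrap/classification machinery with kind
"similarity", which flips the tail convention. This mode is less
sensitive than the aligned one and supports bootstrap normalisation only.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ExternalToolError, MsaOutliersError
from .gapdist import ScoreVector
from .io import SequenceRecord, write_fasta

import numpy as np


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SimilarityTable:
    """Best bit score per unordered sequence pair; absent pairs score 0."""

    pairs: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), score in self.pairs.items():
            if a == b:
                raise MsaOutliersError(f"self-pair ({a!r}) is not allowed")
            if score < 0:
                raise MsaOutliersError("bit scores must be non-negative")

    def score(self, a: str, b: str) -> float:
        return float(self.pairs.get(_pair_key(a, b), 0.0))


def all_vs_all_similarity(records: Sequence[SequenceRecord],
                          tool_path: str = "blastp",
                          workdir: str | Path | None = None) -> SimilarityTable:
    """All-vs-all protein search; best bit score per pair, symmetrised.

    Builds a temporary database from the input itself, runs the search at
    default parameters with tabular output, and keeps the maximum bit
    score across HSPs and across the two query/subject directions.
    Pairs with no reported hit are simply absent (score 0).
    """
    if len(records) < 2:
        raise MsaOutliersError("need at least 2 sequences for all-vs-all search")
    blastp = shutil.which(tool_path)
    if blastp is None:
        raise ExternalToolError(
            f"protein search tool {tool_path!r} not found on PATH; "
            "install NCBI BLAST+ or point --blast-exe at the executable"
        )
    makedb = shutil.which("makeblastdb", path=str(Path(blastp).parent)) or shutil.which("makeblastdb")
    if makedb is None:
        raise ExternalToolError("makeblastdb not found next to the search tool or on PATH")

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(ctx.name) if ctx is not None else Path(workdir)
    try:
        base.mkdir(parents=True, exist_ok=True)
        fasta = base / "query.fasta"
        write_fasta(records, fasta)
        db = base / "selfdb"
        for cmd in (
            [makedb, "-in", str(fasta), "-dbtype", "prot", "-out", str(db)],
            [blastp, "-query", str(fasta), "-db", str(db),
             "-outfmt", "6 qseqid sseqid bitscore",
             "-out", str(base / "hits.tsv")],
        ):
            proc = subprocess.run(cmd, capture_output=True, text=True)
            if proc.returncode != 0:
                raise ExternalToolError(
                    f"{Path(cmd[0]).name} failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip() or proc.stdout.strip()}"
                )
        pairs: dict[tuple[str, str], float] = {}
        for line in (base / "hits.tsv").read_text().splitlines():
            qid, sid, bits = line.split("\t")
            if qid == sid:
                continue
            key = _pair_key(qid, sid)
            score = float(bits)
            if score > pairs.get(key, -1.0):
                pairs[key] = score
        return SimilarityTable(pairs=pairs)
    finally:
        if ctx is not None:
            ctx.cleanup()


def similarity_scores(table: SimilarityTable, ids: Sequence[str]) -> ScoreVector:
    """Total bit score of each sequence against all the others."""
    totals = np.zeros(len(ids), dtype=float)
    index = {seq_id: i for i, seq_id in enumerate(ids)}
    for (a, b), score in table.pairs.items():
        if a not in index or b not in index:
            raise MsaOutliersError(f"pair ({a!r}, {b!r}) has ids outside the input set")
        totals[index[a]] += score
        totals[index[b]] += score
    return ScoreVector(scores=totals, ids=tuple(ids), kind="similarity")
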