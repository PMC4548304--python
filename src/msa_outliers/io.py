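"""Reading and writing the external formats the tool touches.

Sequence input/output is FASTA (via Biopython); precomputed distance
matrices are square Phylip files in the relaxed dialect (whitespace-
delimited labels of any length). Results are written as a tab-separated
report plus two FASTA files partitioning the input into core and outlier
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DistanceMatrixFormatError,
    DuplicateIdError,
    MsaOutliersError,
    UnalignedInputError,
)

#: Gap characters recognised by default. Pfam full alignments use '.'
#: alongside the usual '-'.
DEFAULT_GAP_CHARS = frozenset({"-", "."})


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence, aligned or not.

    Residues are stored uppercased; gap characters are kept as written.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise MsaOutliersError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise MsaOutliersError(f"sequence {self.id!r} has no residues")

    def ungapped(self, gap_chars: Iterable[str] = DEFAULT_GAP_CHARS) -> str:
        """Residue string with gap characters removed."""
        gaps = set(gap_chars)
        return "".join(c for c in self.residues if c not in gaps)


@dataclass(frozen=True)
class Alignment:
    """An ordered set of equal-length gapped sequences.

    ``n`` sequences by ``length`` alignment columns; ids are unique.
    """

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise MsaOutliersError("alignment has no records")
        length = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != length:
                raise UnalignedInputError(
                    f"unaligned input: sequence {rec.id!r} has length "
                    f"{len(rec.residues)}, expected {length}"
                )
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)


@dataclass(frozen=True)
class DistanceMatrixFile:
    """A labelled square distance matrix read from (or bound for) disk."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if values.shape != (n, n):
            raise DistanceMatrixFormatError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.allclose(values, values.T, atol=1e-6):
            raise DistanceMatrixFormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-6):
            raise DistanceMatrixFormatError("distance matrix diagonal is not zero")


def _parse_fasta(path: str | Path) -> list[SequenceRecord]:
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        description = rec.description
        if description.startswith(rec.id):
            description = description[len(rec.id):].strip()
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=description)
        )
    if not records:
        raise MsaOutliersError(f"no FASTA records found in {path}")
    return records


def read_alignment(path: str | Path, gap_chars: Iterable[str] = DEFAULT_GAP_CHARS) -> Alignment:
    """Read an aligned FASTA file.

    All rows must have the same length; at least two records are required
    for any distance computation. Residues are uppercased; characters
    outside the amino-acid alphabet are accepted permissively (only the
    gap/non-gap distinction matters downstream). ``gap_chars`` is accepted
    here for interface symmetry with the mask builder; it does not affect
    parsing.
    """
    del gap_chars  # parsing is gap-agnostic; masks are built downstream
    records = _parse_fasta(path)
    if len(records) < 2:
        raise MsaOutliersError(
            f"alignment {path} has {len(records)} record(s); at least 2 are required"
        )
    return Alignment(records=tuple(records))


def read_unaligned(path: str | Path) -> list[SequenceRecord]:
    """Read unaligned FASTA records in file order, stripping any gaps."""
    records = _parse_fasta(path)
    return [
        SequenceRecord(id=r.id, residues=r.ungapped() or r.residues, description=r.description)
        for r in records
    ]


def read_phylip_distmat(path: str | Path) -> DistanceMatrixFile:
    """Read a square Phylip distance matrix (relaxed dialect).

    The first token is the sequence count N; each of the N following rows
    carries a whitespace-terminated label of any length and N numeric
    fields. Lower-triangular files are rejected.
    """
    path = Path(path)
    tokens_per_line = [line.split() for line in path.read_text().splitlines()]
    tokens_per_line = [t for t in tokens_per_line if t]
    if not tokens_per_line:
        raise DistanceMatrixFormatError(f"{path} is empty")
    header = tokens_per_line[0]
    try:
        n = int(header[0])
    except ValueError as exc:
        raise DistanceMatrixFormatError(
            f"{path}: first token {header[0]!r} is not a sequence count"
        ) from exc
    # Rows may wrap across physical lines; re-tokenise the remainder.
    flat = header[1:]
    for line in tokens_per_line[1:]:
        flat.extend(line)
    if len(flat) != n * (n + 1):
        if len(flat) == n + n * (n - 1) // 2:
            raise DistanceMatrixFormatError(
                f"{path}: lower-triangular Phylip is not supported; "
                "provide a full square matrix"
            )
        raise DistanceMatrixFormatError(
            f"{path}: expected {n} rows of a label plus {n} values "
            f"({n * (n + 1)} tokens), found {len(flat)}"
        )
    labels: list[str] = []
    values = np.empty((n, n), dtype=float)
    for i in range(n):
        row = flat[i * (n + 1): (i + 1) * (n + 1)]
        labels.append(row[0])
        try:
            values[i] = [float(x) for x in row[1:]]
        except ValueError as exc:
            raise DistanceMatrixFormatError(
                f"{path}: non-numeric field in row for {row[0]!r}"
            ) from exc
    if len(set(labels)) != n:
        raise DuplicateIdError(f"{path}: duplicate labels in distance matrix")
    return DistanceMatrixFile(labels=tuple(labels), values=values)


def write_phylip_distmat(matrix: DistanceMatrixFile, path: str | Path) -> None:
    """Write a square Phylip distance matrix (relaxed labels)."""
    path = Path(path)
    n = len(matrix.labels)
    with path.open("w") as fh:
        fh.write(f"{n}\n")
        for label, row in zip(matrix.labels, matrix.values):
            fields = " ".join(f"{v:.9f}" for v in row)
            fh.write(f"{label} {fields}\n")


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving order and descriptions."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_report(report, path: str | Path) -> None:
    """Write the tab-separated outlier report.

    One line per sequence (id, raw score, normalised outlier score,
    flag), preceded by ``#``-prefixed lines recording the normalisation
    statistics and threshold so a reader can recompute the flags from
    the file alone. Floats in the header are repr-exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        stats = report.stats
        if stats.method == "bootstrap":
            fh.write(
                f"# method=bootstrap est_mean={stats.est_mean!r} "
                f"est_sd={stats.est_sd!r} replicates={stats.replicates} "
                f"rng_seed={stats.rng_seed}\n"
            )
        else:
            fh.write(
                f"# method=iqr q1={stats.q1!r} q3={stats.q3!r} iqr={stats.iqr!r}\n"
            )
        fh.write(f"# threshold={report.threshold!r} tail={report.tail}\n")
        fh.write("sequence_id\traw_score\toutlier_score\tis_outlier\n")
        for i, seq_id in enumerate(report.ids):
            fh.write(
                f"{seq_id}\t{report.raw_scores.scores[i]:.6g}\t"
                f"{report.outlier_scores[i]:.6g}\t"
                f"{'yes' if report.flags[i] else 'no'}\n"
            )


def write_partition(records: Sequence[SequenceRecord], flags,
                    out_core: str | Path, out_outliers: str | Path) -> None:
    """Split records into core (unflagged) and outlier FASTA files.

    The two files partition the input in original order; an empty
    outlier set still produces an (empty) file.
    """
    core = [rec for rec, flag in zip(records, flags) if not flag]
    outliers = [rec for rec, flag in zip(records, flags) if flag]
    write_fasta(core, out_core)
    Path(out_outliers).write_text("")
    if outliers:
        write_fasta(outliers, out_outliers)


def write_outputs(report, alignment: Alignment, out_report: str | Path,
                  out_core: str | Path, out_outliers: str | Path) -> None:
    """Write the outlier report and the core/outlier FASTA partition."""
    if list(report.ids) != list(alignment.ids):
        raise MsaOutliersError("report ids do not match alignment ids")
    write_report(report, out_report)
    write_partition(alignment.records, report.flags, out_core, out_outliers)
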