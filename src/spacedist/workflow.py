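"""FASTA input, all-vs-all distance matrices and PHYLIP output.

This layer turns a multi-record FASTA file into a square distance
matrix suitable for distance-based tree builders.  Pairs whose distance
is undefined (match count at background level, Jukes-Cantor saturation)
are replaced by a configurable ceiling so the matrix stays complete;
the substitutions are flagged and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .counting import DnaSequence, SequenceError
from .evodist import DistanceResult, distance_dN, distance_dRC
from .patterns import PatternSet

__all__ = [
    "DistanceMatrix",
    "read_fasta",
    "all_vs_all",
    "write_phylip",
    "read_phylip",
]

logger = logging.getLogger("spacedist")

_NUC = set("ACGTUNRYSWKMBDHV")


@dataclass
class DistanceMatrix:
    """A symmetric all-vs-all distance matrix with ceiling flags."""

    ids: list[str]
    values: np.ndarray
    ceiled: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} identifiers"
            )
        if self.ceiled is None:
            self.ceiled = np.zeros((n, n), dtype=bool)
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("distance matrix must have a zero diagonal")


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read all records of a (possibly line-wrapped) FASTA file.

    Identifiers are the header up to the first whitespace; residues are
    uppercased.  Rejects empty files, duplicate identifiers, and records
    that are not mostly nucleotides.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    out: list[DnaSequence] = []
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise SequenceError(f"record {rec.id!r} in {path} is empty")
        n_nuc = sum(c in _NUC for c in residues)
        if n_nuc < 0.9 * len(residues):
            raise SequenceError(
                f"record {rec.id!r} in {path} does not look like a "
                f"nucleotide sequence ({n_nuc}/{len(residues)} IUPAC letters)"
            )
        out.append(DnaSequence(rec.id, residues))
    return out


def all_vs_all(
    sequences: list[DnaSequence],
    pset: PatternSet,
    estimator: str = "dN",
    mode: str = "full",
    q: float = 0.25,
    ceiling: float = 10.0,
) -> DistanceMatrix:
    """Distance matrix over every unordered sequence pair.

    ``estimator`` is ``dN`` (same strand) or ``dRC`` (strand-aware);
    ``mode`` is ``full`` or ``binary`` (repeat-robust).  Each pair is
    computed once; non-ok statuses are replaced by ``ceiling`` and
    logged as warnings.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences for a distance matrix")
    if estimator not in ("dN", "dRC"):
        raise ValueError(f"estimator must be 'dN' or 'dRC', got {estimator!r}")
    fn = distance_dN if estimator == "dN" else distance_dRC
    n = len(sequences)
    values = np.zeros((n, n))
    ceiled = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            res: DistanceResult = fn(sequences[i], sequences[j], pset, mode, q)
            if res.d is None:
                logger.warning(
                    "pair (%s, %s): status %s; substituting ceiling %.3f",
                    sequences[i].id, sequences[j].id, res.status, ceiling,
                )
                d = ceiling
                ceiled[i, j] = ceiled[j, i] = True
            else:
                d = res.d
            values[i, j] = values[j, i] = d
    return DistanceMatrix([s.id for s in sequences], values, ceiled)


def _phylip_names(ids: list[str], relaxed: bool) -> list[str]:
    if relaxed:
        return list(ids)
    names = [name[:10] for name in ids]
    if len(set(names)) != len(names):
        raise ValueError(
            "sequence identifiers collide after truncation to 10 characters; "
            "rename them or use relaxed PHYLIP names"
        )
    return [name.ljust(10) for name in names]


def write_phylip(
    matrix: DistanceMatrix, path: str | Path, relaxed: bool = False
) -> None:
    """Write a square PHYLIP distance matrix (6-decimal distances).

    Strict mode pads/truncates names to 10 characters and refuses
    truncation collisions; relaxed mode keeps full names separated by
    whitespace.
    """
    names = _phylip_names(matrix.ids, relaxed)
    sep = "  " if relaxed else " "
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for name, row in zip(names, matrix.values):
            fh.write(name + sep + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Parse a square PHYLIP distance matrix written by :func:`write_phylip`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    ids: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[-n:]])
    return DistanceMatrix(ids, np.asarray(rows))
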