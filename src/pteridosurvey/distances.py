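"""Raw (uncorrected) p-distances with pairwise deletion, plus alignment stats.

The barcode analysis rests on exact identity calls, so no substitution-model
correction is applied: the distance between two specimens is the proportion
of differing sites among the sites where *both* have an unambiguous base
(A/C/G/T).  Gaps, ``N``, ``?`` and IUPAC ambiguity codes are all pairwise-
deleted.  Distances are rationals (differences / overlap), so exact
comparison against zero is safe downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AlignedSequenceSet

__all__ = [
    "DEFAULT_MIN_OVERLAP",
    "AlignmentStats",
    "DistanceMatrix",
    "alignment_stats",
    "build_distance_matrix",
    "encode_alignment",
    "p_distance",
]

#: Minimum compared sites for a pair to yield a defined distance.  Guards
#: against spurious zero distances between barely-overlapping partial
#: sequences (partial rbcL reads cover roughly one half of the gene).
DEFAULT_MIN_OVERLAP = 100

_MISSING = np.uint8(255)
_CODE_TABLE = np.full(256, _MISSING, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i  # lowercase


def encode_alignment(aln: AlignedSequenceSet) -> np.ndarray:
    """Encode rows as uint8 codes: A..T -> 0..3, everything else missing."""
    buf = np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.length)
    return _CODE_TABLE[buf]


def _encode_row(row: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]


def p_distance(
    row_a: str, row_b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> tuple[float | None, int]:
    """Uncorrected distance between two aligned rows with pairwise deletion.

    Returns ``(distance, overlap)``; ``distance`` is ``None`` when fewer
    than ``min_overlap`` sites could be compared.

    >>> p_distance("ACGT", "ACGT", min_overlap=1)
    (0.0, 4)
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"length mismatch: {len(row_a)} vs {len(row_b)} columns"
        )
    a = _encode_row(row_a)
    b = _encode_row(row_b)
    shared = (a != _MISSING) & (b != _MISSING)
    overlap = int(shared.sum())
    if overlap < max(min_overlap, 1):
        return None, overlap
    diff = int(((a != b) & shared).sum())
    return diff / overlap, overlap


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric specimen x specimen p-distance matrix.

    ``d[i, j]`` is NaN where the pair is undefined (overlap below
    ``min_overlap``); ``overlap[i, i]`` is the number of unambiguous sites
    in row *i* and ``d[i, i]`` is 0.
    """

    specimen_ids: tuple[str, ...]
    d: np.ndarray        # float64, NaN where undefined
    overlap: np.ndarray  # int64 compared-site counts
    min_overlap: int

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of pairs with a defined distance (diagonal True)."""
        return ~np.isnan(self.d)

    def index_of(self, specimen_id: str) -> int:
        return self.specimen_ids.index(specimen_id)

    def get(self, id_a: str, id_b: str) -> tuple[float | None, int]:
        i, j = self.index_of(id_a), self.index_of(id_b)
        val = self.d[i, j]
        return (None if np.isnan(val) else float(val)), int(self.overlap[i, j])

    def write_square_tsv(self, path: str | Path) -> None:
        """Square matrix TSV: ids in first row and column; NA = undefined."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(("specimen", *self.specimen_ids)) + "\n")
            for i, sid in enumerate(self.specimen_ids):
                cells = [
                    "NA" if np.isnan(v) else repr(float(v))
                    for v in self.d[i]
                ]
                fh.write("\t".join((sid, *cells)) + "\n")

    def write_long_tsv(self, path: str | Path) -> None:
        """Long-format TSV: one row per unordered pair (i < j)."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("idA\tidB\tdistance\toverlap\n")
            for i in range(self.n):
                for j in range(i + 1, self.n):
                    v = self.d[i, j]
                    dist = "NA" if np.isnan(v) else repr(float(v))
                    fh.write(
                        f"{self.specimen_ids[i]}\t{self.specimen_ids[j]}\t"
                        f"{dist}\t{int(self.overlap[i, j])}\n"
                    )


def build_distance_matrix(
    aln: AlignedSequenceSet, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    """All-pairs p-distances for an alignment.

    Pairs with fewer than ``min_overlap`` compared sites are recorded as
    undefined (NaN), never silently zeroed.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    codes = encode_alignment(aln)
    valid = codes != _MISSING
    d = np.zeros((n, n), dtype=np.float64)
    overlap = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(overlap, valid.sum(axis=1))
    for i in range(n - 1):
        shared = valid[i] & valid[i + 1 :]
        ov = shared.sum(axis=1)
        diff = ((codes[i] != codes[i + 1 :]) & shared).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.where(ov > 0, diff / np.maximum(ov, 1), np.nan)
        dist = np.where(ov < min_overlap, np.nan, dist)
        d[i, i + 1 :] = dist
        d[i + 1 :, i] = dist
        overlap[i, i + 1 :] = ov
        overlap[i + 1 :, i] = ov
    return DistanceMatrix(tuple(aln.specimen_ids), d, overlap, min_overlap)


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of an alignment: size and parsimony-informative site count."""

    n_sequences: int
    length: int
    parsimony_informative: int

    def __post_init__(self) -> None:
        if not 0 <= self.parsimony_informative <= self.length:
            raise ValueError("parsimony_informative out of range")


def alignment_stats(aln: AlignedSequenceSet) -> AlignmentStats:
    """Count parsimony-informative sites.

    A column is informative iff at least two distinct unambiguous bases each
    occur in at least two sequences at that column.
    """
    codes = encode_alignment(aln)
    base_counts = np.stack(
        [(codes == k).sum(axis=0) for k in range(4)]
    )  # 4 x length
    informative = (base_counts >= 2).sum(axis=0) >= 2
    return AlignmentStats(
        n_sequences=len(aln),
        length=aln.length,
        parsimony_informative=int(informative.sum()),
    )
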