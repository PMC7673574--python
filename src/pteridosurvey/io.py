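"""Domain types and readers/writers for the survey's three input formats.

The pipeline consumes (a) a pre-aligned nucleotide FASTA, one row per
specimen; (b) a specimen checklist CSV linking specimens to terminal taxa
with rank, genus, family, growth habits, native status and flora label; and
(c) a binary taxon x sampling-unit incidence table (sampling units are
collection days).  All readers validate aggressively: downstream distance
and richness code assumes these invariants and never re-checks them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALLOWED_HABITS",
    "NUCLEOTIDE_ALPHABET",
    "AlignedSequenceSet",
    "ChecklistError",
    "IncidenceMatrix",
    "SurveyChecklist",
    "TaxonRecord",
    "ValidationError",
    "read_aligned_fasta",
    "read_checklist",
    "read_incidence",
    "write_aligned_fasta",
    "write_checklist",
    "write_incidence",
]

#: Unambiguous bases, IUPAC ambiguity codes, gap and missing-data symbols.
NUCLEOTIDE_ALPHABET = frozenset("ACGTRYSWKMBDHVN-?")

#: Growth-habit vocabulary used in the checklist (multi-label per taxon).
ALLOWED_HABITS = frozenset({"climbing", "epipetric", "epiphytic", "terrestrial"})

#: Delimiter for multi-label cells (habits, never commas: they break CSV).
MULTILABEL_DELIMITER = "|"


class ValidationError(ValueError):
    """An input violates a structural invariant of its format."""


class ChecklistError(ValidationError):
    """A checklist-specific violation (vocabulary or referential integrity)."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An aligned set of nucleotide sequences, one per specimen.

    Rows are equal-length uppercase strings over ``NUCLEOTIDE_ALPHABET``.
    ``'-'``, ``'N'``, ``'?'`` and the IUPAC ambiguity codes all mean "no
    usable information" to the distance module (pairwise deletion).
    """

    specimen_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.specimen_ids) != len(self.rows):
            raise ValidationError("specimen_ids and rows differ in length")
        if not self.specimen_ids:
            raise ValidationError("alignment has no sequences")
        seen: set[str] = set()
        for sid in self.specimen_ids:
            if not sid:
                raise ValidationError("empty specimen id")
            if sid in seen:
                raise ValidationError(f"duplicate specimen id {sid!r}")
            seen.add(sid)
        length = len(self.rows[0])
        for sid, row in zip(self.specimen_ids, self.rows):
            if len(row) != length:
                raise ValidationError(
                    f"unaligned input: record {sid!r} has {len(row)} columns, "
                    f"expected {length}"
                )
            for pos, ch in enumerate(row):
                if ch not in NUCLEOTIDE_ALPHABET:
                    raise ValidationError(
                        f"illegal character {ch!r} in record {sid!r} "
                        f"at position {pos + 1}"
                    )

    @property
    def length(self) -> int:
        """Number of alignment columns (bp)."""
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.specimen_ids)

    def row(self, specimen_id: str) -> str:
        return self.rows[self.specimen_ids.index(specimen_id)]

    def subset(self, specimen_ids: Iterable[str]) -> "AlignedSequenceSet":
        """Restrict to the given specimens, preserving current row order."""
        keep = set(specimen_ids)
        missing = keep - set(self.specimen_ids)
        if missing:
            raise ValidationError(f"unknown specimen ids: {sorted(missing)}")
        pairs = [
            (sid, row)
            for sid, row in zip(self.specimen_ids, self.rows)
            if sid in keep
        ]
        return AlignedSequenceSet(
            tuple(p[0] for p in pairs), tuple(p[1] for p in pairs)
        )


def read_aligned_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA file.

    Headers are taken verbatim up to the first whitespace; lowercase bases
    are normalised to uppercase.  Ragged records, duplicate headers and
    characters outside the nucleotide alphabet raise ``ValidationError``.
    """
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise ValidationError(f"no FASTA records in {path}")
    return AlignedSequenceSet(tuple(ids), tuple(rows))


def write_aligned_fasta(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Write aligned FASTA, wrapping sequence lines at 80 columns."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.specimen_ids, aln.rows)
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=80)
        writer.write_file(records)


@dataclass(frozen=True)
class TaxonRecord:
    """Checklist entry for one terminal taxon (species or infraspecies)."""

    name: str
    rank: str  # "species" | "infraspecies"
    genus: str
    family: str
    growth_habits: frozenset[str]
    native: bool
    floras: frozenset[str]

    def __post_init__(self) -> None:
        if self.rank not in ("species", "infraspecies"):
            raise ChecklistError(
                f"taxon {self.name!r}: rank must be 'species' or "
                f"'infraspecies', got {self.rank!r}"
            )
        bad = set(self.growth_habits) - ALLOWED_HABITS
        if bad:
            raise ChecklistError(
                f"taxon {self.name!r}: unknown habit token(s) {sorted(bad)}; "
                f"allowed: {sorted(ALLOWED_HABITS)}"
            )

    @property
    def species_name(self) -> str:
        """Binomial the terminal belongs to (infraspecific epithet dropped)."""
        for marker in (" var. ", " subsp. "):
            if marker in self.name:
                return self.name.split(marker)[0]
        return self.name


@dataclass
class SurveyChecklist:
    """Terminal-taxon records plus specimen links.

    ``specimen_map`` maps specimen id -> taxon name; ``specimen_flora`` maps
    specimen id -> the single flora it was collected in.  A taxon may occur
    in several floras (its record carries the set).
    """

    records: dict[str, TaxonRecord]
    specimen_map: dict[str, str] = field(default_factory=dict)
    specimen_flora: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, taxon in self.specimen_map.items():
            if taxon not in self.records:
                raise ChecklistError(
                    f"specimen {sid!r} refers to undeclared taxon {taxon!r}"
                )
        for sid in self.specimen_flora:
            if sid not in self.specimen_map:
                raise ChecklistError(
                    f"flora label for unknown specimen {sid!r}"
                )

    # -- derived views ------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return sorted(self.records)

    @property
    def n_taxa(self) -> int:
        return len(self.records)

    @property
    def species_names(self) -> set[str]:
        return {rec.species_name for rec in self.records.values()}

    @property
    def floras(self) -> list[str]:
        labels: set[str] = set()
        for rec in self.records.values():
            labels |= rec.floras
        return sorted(labels)

    def specimens_of(self, taxon: str) -> list[str]:
        return sorted(
            sid for sid, t in self.specimen_map.items() if t == taxon
        )

    def taxa_in_flora(self, flora: str) -> list[str]:
        return sorted(
            name for name, rec in self.records.items() if flora in rec.floras
        )

    def exclude_nonnative(self) -> "SurveyChecklist":
        """Drop non-native taxa (and their specimens)."""
        kept = {n: r for n, r in self.records.items() if r.native}
        smap = {s: t for s, t in self.specimen_map.items() if t in kept}
        sflora = {s: f for s, f in self.specimen_flora.items() if s in smap}
        return SurveyChecklist(kept, smap, sflora)


_CHECKLIST_COLUMNS = [
    "taxon",
    "rank",
    "genus",
    "family",
    "habits",
    "native",
    "flora",
    "specimen_id",
]

_TRUE_TOKENS = {"true", "yes", "1", "y"}
_FALSE_TOKENS = {"false", "no", "0", "n"}


def _parse_native(token: str, taxon: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise ChecklistError(
        f"taxon {taxon!r}: cannot parse native flag {token!r}"
    )


def read_checklist(path: str | Path) -> SurveyChecklist:
    """Read a checklist CSV (one row per specimen, or per specimen-less taxon).

    Required columns: taxon, rank, genus, family, habits, native, flora,
    specimen_id.  ``habits`` is a '|'-separated multi-label list.  Rows whose
    rank, genus and family cells are all empty are link-only rows and must
    name an already-declared taxon; otherwise the row declares the taxon and
    any later re-declaration must agree field-for-field.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ChecklistError(f"empty checklist file {path}")
        missing = set(_CHECKLIST_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ChecklistError(
                f"checklist missing required column(s): {sorted(missing)}"
            )
        rows = list(reader)
    if not rows:
        raise ChecklistError(f"checklist {path} has a header but no rows")

    records: dict[str, TaxonRecord] = {}
    taxon_floras: dict[str, set[str]] = {}
    specimen_map: dict[str, str] = {}
    specimen_flora: dict[str, str] = {}
    pending: dict[str, tuple] = {}

    for lineno, row in enumerate(rows, start=2):
        taxon = row["taxon"].strip()
        if not taxon:
            raise ChecklistError(f"line {lineno}: empty taxon name")
        rank = row["rank"].strip()
        genus = row["genus"].strip()
        family = row["family"].strip()
        flora = row["flora"].strip()
        link_only = not (rank or genus or family)
        if link_only:
            if taxon not in pending:
                raise ChecklistError(
                    f"line {lineno}: specimen row refers to undeclared "
                    f"taxon {taxon!r}"
                )
        else:
            habits = frozenset(
                tok.strip()
                for tok in row["habits"].split(MULTILABEL_DELIMITER)
                if tok.strip()
            )
            native = _parse_native(row["native"], taxon)
            decl = (rank, genus, family, habits, native)
            if taxon in pending and pending[taxon] != decl:
                raise ChecklistError(
                    f"line {lineno}: conflicting re-declaration of "
                    f"taxon {taxon!r}"
                )
            pending[taxon] = decl
        if flora:
            taxon_floras.setdefault(taxon, set()).add(flora)
        sid = row["specimen_id"].strip()
        if sid:
            if sid in specimen_map:
                raise ChecklistError(f"line {lineno}: duplicate specimen {sid!r}")
            specimen_map[sid] = taxon
            if flora:
                specimen_flora[sid] = flora

    for taxon, (rank, genus, family, habits, native) in pending.items():
        records[taxon] = TaxonRecord(
            name=taxon,
            rank=rank,
            genus=genus,
            family=family,
            growth_habits=habits,
            native=native,
            floras=frozenset(taxon_floras.get(taxon, set())),
        )
    return SurveyChecklist(records, specimen_map, specimen_flora)


def write_checklist(checklist: SurveyChecklist, path: str | Path) -> None:
    """Write the checklist back to CSV (bit-stable: sorted rows)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CHECKLIST_COLUMNS)
        for taxon in sorted(checklist.records):
            rec = checklist.records[taxon]
            habits = MULTILABEL_DELIMITER.join(sorted(rec.growth_habits))
            native = "true" if rec.native else "false"
            specimens = checklist.specimens_of(taxon)
            base = [taxon, rec.rank, rec.genus, rec.family, habits, native]
            if not specimens:
                flora = sorted(rec.floras)[0] if rec.floras else ""
                writer.writerow(base + [flora, ""])
                continue
            for i, sid in enumerate(specimens):
                flora = checklist.specimen_flora.get(
                    sid, sorted(rec.floras)[0] if rec.floras else ""
                )
                if i == 0:
                    writer.writerow(base + [flora, sid])
                else:
                    # later specimens of a declared taxon are link-only rows
                    writer.writerow([taxon, "", "", "", "", "", flora, sid])


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary taxon x sampling-unit (collection day) matrix."""

    taxa: tuple[str, ...]
    units: tuple[str, ...]
    matrix: np.ndarray  # shape (len(taxa), T), dtype int8, entries 0/1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (len(self.taxa), len(self.units)):
            raise ValidationError("incidence matrix shape mismatch")
        if len(self.units) < 1:
            raise ValidationError("incidence matrix needs >=1 sampling unit")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon in incidence matrix")
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        zero_rows = np.flatnonzero(m.sum(axis=1) == 0)
        if zero_rows.size:
            raise ValidationError(
                f"taxon {self.taxa[zero_rows[0]]!r} has an all-zero "
                "incidence row"
            )
        object.__setattr__(self, "matrix", m.astype(np.int8))

    @property
    def T(self) -> int:
        """Number of sampling units."""
        return len(self.units)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def incidence_counts(self) -> np.ndarray:
        """Per-taxon number of units in which it was detected (Y_i)."""
        return self.matrix.sum(axis=1).astype(int)


def read_incidence(path: str | Path) -> IncidenceMatrix:
    """Read an incidence CSV: first column taxon, remaining columns units."""
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"empty incidence file {path}") from None
        units = tuple(h.strip() for h in header[1:])
        taxa: list[str] = []
        data: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            taxa.append(row[0].strip())
            cells = []
            for col, cell in enumerate(row[1:], start=2):
                tok = cell.strip()
                if tok not in ("0", "1"):
                    raise ValidationError(
                        f"line {lineno}, column {col}: non-binary cell "
                        f"{cell!r}"
                    )
                cells.append(int(tok))
            data.append(cells)
    if not taxa:
        raise ValidationError(f"incidence file {path} has no taxon rows")
    return IncidenceMatrix(tuple(taxa), units, np.array(data, dtype=np.int8))


def write_incidence(inc: IncidenceMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["taxon", *inc.units])
        for taxon, row in zip(inc.taxa, inc.matrix):
            writer.writerow([taxon, *(int(x) for x in row)])
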