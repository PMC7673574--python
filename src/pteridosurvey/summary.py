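"""Checklist summary statistics: growth habits, clade split, coverage, area.

Counts are made at the terminal-taxon level (species and infraspecies both
count as terminals) and percentages are taken against the terminal total,
so multi-habit taxa make the habit column sum past 100% — that is a feature
of the data, not a bug.  Rounding is half-up at one decimal (two for
richness per hectare) and happens only at this presentation layer; every
internal value is kept at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .io import ALLOWED_HABITS, AlignedSequenceSet, SurveyChecklist

__all__ = [
    "LYCOPHYTE_FAMILIES",
    "SummaryReport",
    "richness_per_area",
    "round_half_up",
    "summarize_checklist",
]

#: Families whose members are lycophytes; everything else is a fern.
LYCOPHYTE_FAMILIES = frozenset(
    {"Lycopodiaceae", "Selaginellaceae", "Isoetaceae"}
)


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ndigits decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryReport:
    """Survey totals in the style of a floristic-checklist table."""

    n_taxa: int               # terminal taxa (species + infraspecies)
    n_species: int            # distinct binomials
    n_genera: int
    n_families: int
    n_specimens: int
    habit_counts: dict[str, int]
    habit_pct: dict[str, float]          # of terminal taxa, 1 decimal
    clade_species: dict[str, int]        # ferns / lycophytes, species level
    clade_taxa: dict[str, int]           # ferns / lycophytes, terminal level
    clade_pct: dict[str, float]          # species count over terminal total
    n_barcoded_taxa: int
    barcode_coverage_pct: float          # taxa with >=1 specimen, 1 decimal
    richness_per_area_ha: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_taxa": self.n_taxa,
            "n_species": self.n_species,
            "n_genera": self.n_genera,
            "n_families": self.n_families,
            "n_specimens": self.n_specimens,
            "habit_counts": dict(sorted(self.habit_counts.items())),
            "habit_pct": dict(sorted(self.habit_pct.items())),
            "clade_species": dict(sorted(self.clade_species.items())),
            "clade_taxa": dict(sorted(self.clade_taxa.items())),
            "clade_pct": dict(sorted(self.clade_pct.items())),
            "n_barcoded_taxa": self.n_barcoded_taxa,
            "barcode_coverage_pct": self.barcode_coverage_pct,
            "richness_per_area_ha": self.richness_per_area_ha,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize_checklist(
    checklist: SurveyChecklist,
    alignment: AlignedSequenceSet | None = None,
    exclude_nonnative: bool = False,
    area_ha: float | None = None,
) -> SummaryReport:
    """Tabulate a survey checklist.

    Habit percentages use terminal-taxon counts over the terminal total.
    The clade split reports species-level counts (varieties collapse to
    their binomial) with the percentage likewise taken over the terminal
    total, the convention floristic tables use when varieties are few.
    Barcode coverage is the fraction of terminals with at least one linked
    specimen — restricted, when an alignment is given, to specimens whose
    sequence is actually present in it.
    """
    cl = checklist.exclude_nonnative() if exclude_nonnative else checklist
    n_taxa = cl.n_taxa
    if n_taxa == 0:
        raise ValueError("checklist has no taxa")
    recs = list(cl.records.values())

    habit_counts = {h: 0 for h in sorted(ALLOWED_HABITS)}
    for rec in recs:
        for h in rec.growth_habits:
            habit_counts[h] += 1
    habit_pct = {
        h: round_half_up(100.0 * c / n_taxa, 1)
        for h, c in habit_counts.items()
    }

    def clade_of(rec) -> str:
        return "lycophytes" if rec.family in LYCOPHYTE_FAMILIES else "ferns"

    clade_taxa = {"ferns": 0, "lycophytes": 0}
    clade_species_sets: dict[str, set[str]] = {
        "ferns": set(),
        "lycophytes": set(),
    }
    for rec in recs:
        clade = clade_of(rec)
        clade_taxa[clade] += 1
        clade_species_sets[clade].add(rec.species_name)
    clade_species = {c: len(s) for c, s in clade_species_sets.items()}
    clade_pct = {
        c: round_half_up(100.0 * n / n_taxa, 1)
        for c, n in clade_species.items()
    }

    if alignment is not None:
        sequenced = set(alignment.specimen_ids)
        covered = {
            t
            for s, t in cl.specimen_map.items()
            if s in sequenced and t in cl.records
        }
    else:
        covered = {t for t in cl.records if cl.specimens_of(t)}
    n_barcoded = len(covered)

    rpa = None
    n_species = len(cl.species_names)
    if area_ha is not None:
        rpa = richness_per_area(n_species, area_ha)

    return SummaryReport(
        n_taxa=n_taxa,
        n_species=n_species,
        n_genera=len({r.genus for r in recs}),
        n_families=len({r.family for r in recs}),
        n_specimens=len(cl.specimen_map),
        habit_counts=habit_counts,
        habit_pct=habit_pct,
        clade_species=clade_species,
        clade_taxa=clade_taxa,
        clade_pct=clade_pct,
        n_barcoded_taxa=n_barcoded,
        barcode_coverage_pct=round_half_up(100.0 * n_barcoded / n_taxa, 1),
        richness_per_area_ha=rpa,
    )


def richness_per_area(n_species: int, area_ha: float) -> float:
    """Species per hectare, rounded half-up to two decimals."""
    if area_ha <= 0:
        raise ValueError("area_ha must be positive")
    if n_species < 0:
        raise ValueError("n_species must be non-negative")
    return round_half_up(n_species / area_ha, 2)
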