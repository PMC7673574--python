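"""Barcode-gap evaluation: per-taxon minimum interspecific distance.

A reference library "fails" for a taxon when its minimum distance to any
other taxon is exactly zero — it shares an identical barcode haplotype and
cannot be told apart by the marker.  Minima are taken over all defined
specimen pairs crossing taxon boundaries; conspecific pairs are never
considered.  Failure is a symmetric relation: if A's nearest taxon at
distance 0 is B, then B fails too.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .distances import DEFAULT_MIN_OVERLAP, DistanceMatrix, build_distance_matrix
from .io import AlignedSequenceSet, SurveyChecklist

__all__ = [
    "BarcodeGapReport",
    "DistanceHistogram",
    "TaxonGapResult",
    "compare_floras",
    "distance_histogram",
    "min_interspecific_distances",
]


@dataclass(frozen=True)
class TaxonGapResult:
    """Minimum interspecific distance record for one terminal taxon."""

    taxon: str
    n_specimens: int
    min_interspecific: float | None  # None when unscorable
    nearest_taxon: str | None        # lexicographically first argmin
    nearest_ties: tuple[str, ...]    # all taxa attaining the minimum
    failure: bool | None             # None when unscorable

    @property
    def scorable(self) -> bool:
        return self.min_interspecific is not None


@dataclass(frozen=True)
class BarcodeGapReport:
    """Per-taxon minima plus the flora-level failure summary."""

    per_taxon: dict[str, TaxonGapResult]
    n_taxa_scored: int
    n_failures: int

    @property
    def failure_rate(self) -> float:
        if self.n_taxa_scored == 0:
            return float("nan")
        return self.n_failures / self.n_taxa_scored

    @property
    def failures(self) -> set[str]:
        return {
            t for t, r in self.per_taxon.items() if r.failure
        }

    @property
    def unscorable(self) -> set[str]:
        return {t for t, r in self.per_taxon.items() if not r.scorable}

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(
                "taxon\tn_specimens\tmin_interspecific\tnearest_taxon\t"
                "failure\n"
            )
            for taxon in sorted(self.per_taxon):
                r = self.per_taxon[taxon]
                dist = "NA" if r.min_interspecific is None else repr(
                    float(r.min_interspecific)
                )
                nearest = r.nearest_taxon or "NA"
                fail = "NA" if r.failure is None else str(r.failure).lower()
                fh.write(
                    f"{taxon}\t{r.n_specimens}\t{dist}\t{nearest}\t{fail}\n"
                )

    def summary_dict(self) -> dict:
        return {
            "n_taxa_scored": self.n_taxa_scored,
            "n_failures": self.n_failures,
            "failure_rate": self.failure_rate,
            "n_unscorable": len(self.unscorable),
        }

    def write_summary_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def min_interspecific_distances(
    dm: DistanceMatrix,
    checklist: SurveyChecklist,
    exclude_nonnative: bool = False,
    restrict_taxa: Iterable[str] | None = None,
) -> BarcodeGapReport:
    """Score every taxon's minimum distance to any other taxon.

    Every specimen in ``dm`` must be mapped to a taxon by the checklist
    (specimens of taxa dropped by filtering are ignored).  Taxa whose every
    interspecific pair is undefined are flagged unscorable and excluded
    from the failure-rate denominator.
    """
    cl = checklist.exclude_nonnative() if exclude_nonnative else checklist
    allowed = set(cl.records)
    if restrict_taxa is not None:
        allowed &= set(restrict_taxa)

    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(dm.specimen_ids):
        if sid not in checklist.specimen_map:
            raise KeyError(f"specimen {sid!r} not mapped to any taxon")
        taxon = checklist.specimen_map[sid]
        if taxon in allowed:
            groups.setdefault(taxon, []).append(i)
    if len(groups) < 2:
        raise ValueError("need >=2 taxa with specimens to score minima")

    taxa = sorted(groups)
    idx = {t: np.array(groups[t], dtype=int) for t in taxa}
    # taxon of each matrix row, restricted to scored specimens
    per_taxon: dict[str, TaxonGapResult] = {}
    n_scored = 0
    n_failures = 0
    for s in taxa:
        rows = idx[s]
        best: float | None = None
        ties: list[str] = []
        for t in taxa:
            if t == s:
                continue
            block = dm.d[np.ix_(rows, idx[t])]
            if np.all(np.isnan(block)):
                continue
            m = float(np.nanmin(block))
            if best is None or m < best:
                best, ties = m, [t]
            elif m == best:
                ties.append(t)
        ties.sort()
        if best is None:
            per_taxon[s] = TaxonGapResult(
                s, len(rows), None, None, (), None
            )
            continue
        failure = best == 0.0
        n_scored += 1
        n_failures += int(failure)
        per_taxon[s] = TaxonGapResult(
            s, len(rows), best, ties[0], tuple(ties), failure
        )
    return BarcodeGapReport(per_taxon, n_scored, n_failures)


@dataclass(frozen=True)
class DistanceHistogram:
    """Left-closed binning of minimum distances; zeros kept separate.

    ``zero_count`` is the count of taxa at exactly zero (the failure bar);
    positive distances fall in ``counts[k]`` for the bin
    ``[edges[k], edges[k + 1])`` (the final bin is closed at 1).
    """

    bin_width: float
    edges: np.ndarray
    counts: np.ndarray
    zero_count: int

    @property
    def total(self) -> int:
        return int(self.zero_count + self.counts.sum())

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("bin_low\tbin_high\tcategory\tcount\n")
            fh.write(f"0\t0\tzero\t{self.zero_count}\n")
            for k, c in enumerate(self.counts):
                fh.write(
                    f"{repr(float(self.edges[k]))}\t"
                    f"{repr(float(self.edges[k + 1]))}\tpositive\t{int(c)}\n"
                )


def distance_histogram(
    report: BarcodeGapReport, bin_width: float = 0.005
) -> DistanceHistogram:
    """Bin a report's minimum distances over [0, 1]."""
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must be in (0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts = np.zeros(n_bins, dtype=int)
    zero_count = 0
    for r in report.per_taxon.values():
        if r.min_interspecific is None:
            continue
        if r.min_interspecific == 0.0:
            zero_count += 1
            continue
        # searchsorted keeps left-closed semantics exact at bin boundaries
        k = int(np.searchsorted(edges, r.min_interspecific, side="right")) - 1
        counts[min(k, n_bins - 1)] += 1
    return DistanceHistogram(bin_width, edges, counts, zero_count)


def compare_floras(
    aln: AlignedSequenceSet,
    checklist: SurveyChecklist,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    exclude_nonnative: bool = False,
) -> dict[str, BarcodeGapReport]:
    """Per-flora barcode-gap reports from one combined alignment.

    Distances are computed once on the combined alignment (pairwise deletion
    makes each pair's distance independent of which other sequences are
    present); each flora's minima are then taken only among that flora's
    specimens.  Floras with fewer than two taxa are skipped with a warning.
    """
    cl = checklist.exclude_nonnative() if exclude_nonnative else checklist
    dm = build_distance_matrix(aln, min_overlap=min_overlap)
    reports: dict[str, BarcodeGapReport] = {}
    for flora in cl.floras:
        specimens = [
            sid
            for sid in dm.specimen_ids
            if cl.specimen_flora.get(sid) == flora
            and cl.specimen_map.get(sid) in cl.records
        ]
        taxa = {cl.specimen_map[sid] for sid in specimens}
        if len(taxa) < 2:
            warnings.warn(
                f"flora {flora!r} has fewer than 2 taxa; skipped",
                stacklevel=2,
            )
            continue
        sub = _subset_matrix(dm, specimens)
        reports[flora] = min_interspecific_distances(
            sub, cl, restrict_taxa=taxa
        )
    return reports


def _subset_matrix(dm: DistanceMatrix, specimens: list[str]) -> DistanceMatrix:
    pos = [dm.specimen_ids.index(s) for s in specimens]
    sel = np.array(pos, dtype=int)
    return DistanceMatrix(
        tuple(specimens),
        dm.d[np.ix_(sel, sel)].copy(),
        dm.overlap[np.ix_(sel, sel)].copy(),
        dm.min_overlap,
    )
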