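"""Minimum interspecific distances, failure classification, flora subsetting."""

from __future__ import annotations

import numpy as np
import pytest

from pteridosurvey.barcode_gap import (
    compare_floras,
    distance_histogram,
    min_interspecific_distances,
)
from pteridosurvey.distances import DistanceMatrix, build_distance_matrix
from pteridosurvey.io import AlignedSequenceSet, SurveyChecklist, TaxonRecord

from conftest import make_checklist, random_alignment


def _aln(pairs):
    ids, rows = zip(*pairs)
    return AlignedSequenceSet(tuple(ids), tuple(rows))


SEQ_A = "ACGT" * 30
SEQ_B = "ACGA" * 30  # 30 differences from SEQ_A
SEQ_C = "TGCA" * 30


class TestMinInterspecific:
    def test_shared_haplotype_both_fail(self):
        aln = _aln([("x1", SEQ_A), ("y1", SEQ_A), ("z1", SEQ_C)])
        cl = make_checklist({"X a": ["x1"], "Y a": ["y1"], "Z a": ["z1"]})
        rep = min_interspecific_distances(
            build_distance_matrix(aln, min_overlap=1), cl
        )
        assert rep.per_taxon["X a"].failure and rep.per_taxon["Y a"].failure
        assert rep.per_taxon["X a"].min_interspecific == 0.0
        assert not rep.per_taxon["Z a"].failure
        assert rep.n_taxa_scored == 3 and rep.n_failures == 2
        assert rep.failure_rate == pytest.approx(2 / 3)

    def test_conspecific_pairs_excluded(self):
        # 3 identical conspecific specimens: their mutual distance 0 must
        # not create a failure; only the cross-taxon distance counts
        aln = _aln(
            [("x1", SEQ_A), ("x2", SEQ_A), ("x3", SEQ_A), ("y1", SEQ_B)]
        )
        cl = make_checklist({"X a": ["x1", "x2", "x3"], "Y b": ["y1"]})
        rep = min_interspecific_distances(
            build_distance_matrix(aln, min_overlap=1), cl
        )
        assert rep.n_failures == 0
        assert rep.per_taxon["X a"].min_interspecific == pytest.approx(0.25)
        assert rep.per_taxon["X a"].nearest_taxon == "Y b"

    def test_matches_bruteforce_double_loop(self, rng):
        # random 8-taxon, 12-specimen fixture vs exhaustive cross-pair scan
        aln = random_alignment(rng, 12, 150, missing_fraction=0.05)
        taxa = {f"T {chr(97 + i)}": [] for i in range(8)}
        names = list(taxa)
        for i, sid in enumerate(aln.specimen_ids):
            taxa[names[i % 8]].append(sid)
        cl = make_checklist(taxa)
        dm = build_distance_matrix(aln, min_overlap=1)
        rep = min_interspecific_distances(dm, cl)
        for s in names:
            best = None
            for i, si in enumerate(dm.specimen_ids):
                for j, sj in enumerate(dm.specimen_ids):
                    if i >= j:
                        continue
                    ti, tj = cl.specimen_map[si], cl.specimen_map[sj]
                    if (ti == s) == (tj == s):
                        continue
                    v = dm.d[i, j]
                    if not np.isnan(v) and (best is None or v < best):
                        best = v
            assert rep.per_taxon[s].min_interspecific == pytest.approx(best)

    def test_unscorable_excluded_from_denominator(self):
        blank = "-" * 120
        aln = _aln([("x1", blank), ("y1", SEQ_A), ("z1", SEQ_B)])
        cl = make_checklist({"X a": ["x1"], "Y b": ["y1"], "Z c": ["z1"]})
        rep = min_interspecific_distances(
            build_distance_matrix(aln, min_overlap=10), cl
        )
        assert rep.per_taxon["X a"].min_interspecific is None
        assert rep.unscorable == {"X a"}
        assert rep.n_taxa_scored == 2

    def test_min_bounds_all_interspecific(self, rng):
        aln = random_alignment(rng, 10, 100)
        taxa = {f"T {i}": [sid] for i, sid in enumerate(aln.specimen_ids)}
        cl = make_checklist(taxa)
        dm = build_distance_matrix(aln, min_overlap=1)
        rep = min_interspecific_distances(dm, cl)
        for s, r in rep.per_taxon.items():
            rows = [
                i
                for i, sid in enumerate(dm.specimen_ids)
                if cl.specimen_map[sid] == s
            ]
            others = [i for i in range(dm.n) if i not in rows]
            assert r.min_interspecific <= np.nanmin(
                dm.d[np.ix_(rows, others)]
            ) + 1e-15

    def test_removing_non_nearest_taxon_keeps_minimum(self):
        aln = _aln([("x1", SEQ_A), ("y1", SEQ_B), ("z1", SEQ_C)])
        cl = make_checklist({"X a": ["x1"], "Y b": ["y1"], "Z c": ["z1"]})
        dm = build_distance_matrix(aln, min_overlap=1)
        full = min_interspecific_distances(dm, cl)
        assert full.per_taxon["X a"].nearest_taxon == "Y b"
        reduced = min_interspecific_distances(dm, cl, restrict_taxa=["X a", "Y b"])
        assert (
            reduced.per_taxon["X a"].min_interspecific
            == full.per_taxon["X a"].min_interspecific
        )

    def test_nonnative_excluded_when_configured(self):
        records = {
            "X a": TaxonRecord("X a", "species", "X", "F", frozenset({"terrestrial"}), True, frozenset({"s"})),
            "Y b": TaxonRecord("Y b", "species", "Y", "F", frozenset({"terrestrial"}), False, frozenset({"s"})),
            "Z c": TaxonRecord("Z c", "species", "Z", "F", frozenset({"terrestrial"}), True, frozenset({"s"})),
        }
        cl = SurveyChecklist(
            records,
            {"x1": "X a", "y1": "Y b", "z1": "Z c"},
            {"x1": "s", "y1": "s", "z1": "s"},
        )
        aln = _aln([("x1", SEQ_A), ("y1", SEQ_A), ("z1", SEQ_C)])
        dm = build_distance_matrix(aln, min_overlap=1)
        with_alien = min_interspecific_distances(dm, cl)
        assert with_alien.failures == {"X a", "Y b"}
        natives_only = min_interspecific_distances(dm, cl, exclude_nonnative=True)
        assert natives_only.failures == set()
        assert "Y b" not in natives_only.per_taxon

    def test_tie_break_lexicographic(self):
        aln = _aln([("x1", SEQ_A), ("y1", SEQ_A), ("w1", SEQ_A)])
        cl = make_checklist({"X a": ["x1"], "Y b": ["y1"], "W c": ["w1"]})
        rep = min_interspecific_distances(
            build_distance_matrix(aln, min_overlap=1), cl
        )
        assert rep.per_taxon["X a"].nearest_taxon == "W c"
        assert rep.per_taxon["X a"].nearest_ties == ("W c", "Y b")


class TestHistogram:
    def test_all_zero_single_bar(self):
        aln = _aln([("x1", SEQ_A), ("y1", SEQ_A)])
        cl = make_checklist({"X a": ["x1"], "Y b": ["y1"]})
        rep = min_interspecific_distances(
            build_distance_matrix(aln, min_overlap=1), cl
        )
        hist = distance_histogram(rep)
        assert hist.zero_count == 2
        assert hist.counts.sum() == 0

    def test_conservation_and_rebinning(self, rng):
        aln = random_alignment(rng, 15, 200)
        taxa = {f"T {i}": [sid] for i, sid in enumerate(aln.specimen_ids)}
        cl = make_checklist(taxa)
        rep = min_interspecific_distances(
            build_distance_matrix(aln, min_overlap=1), cl
        )
        hist = distance_histogram(rep, bin_width=0.005)
        assert hist.total == rep.n_taxa_scored
        # direct tally oracle
        for k in range(len(hist.counts)):
            lo, hi = k * 0.005, (k + 1) * 0.005
            expected = sum(
                1
                for r in rep.per_taxon.values()
                if r.min_interspecific is not None
                and r.min_interspecific > 0
                and (
                    lo <= r.min_interspecific < hi
                    or (k == len(hist.counts) - 1 and r.min_interspecific >= lo)
                )
            )
            assert hist.counts[k] == expected


class TestCompareFloras:
    def _two_flora_data(self):
        records = {}
        smap, sflora, rows = {}, {}, []
        # flora A: taxa P/Q share a haplotype; flora B: distinct sequences
        spec = [
            ("p1", "P a", "A", SEQ_A),
            ("q1", "Q b", "A", SEQ_A),
            ("r1", "R c", "A", SEQ_C),
            ("u1", "U d", "B", SEQ_A),
            ("v1", "V e", "B", SEQ_B),
        ]
        for sid, taxon, flora, seq in spec:
            records.setdefault(
                taxon,
                TaxonRecord(
                    taxon, "species", taxon[0], "F",
                    frozenset({"terrestrial"}), True, frozenset({flora}),
                ),
            )
            smap[sid] = taxon
            sflora[sid] = flora
            rows.append((sid, seq))
        cl = SurveyChecklist(records, smap, sflora)
        return _aln(rows), cl

    def test_floras_scored_independently(self):
        aln, cl = self._two_flora_data()
        reports = compare_floras(aln, cl, min_overlap=1)
        assert reports["A"].failures == {"P a", "Q b"}
        # U d shares SEQ_A with flora A's taxa but flora B is scored alone
        assert reports["B"].failures == set()

    def test_equals_separate_subset_runs(self):
        aln, cl = self._two_flora_data()
        reports = compare_floras(aln, cl, min_overlap=1)
        for flora in ("A", "B"):
            sids = [s for s, f in cl.specimen_flora.items() if f == flora]
            sub = aln.subset(sids)
            direct = min_interspecific_distances(
                build_distance_matrix(sub, min_overlap=1),
                cl,
                restrict_taxa=cl.taxa_in_flora(flora),
            )
            got = reports[flora]
            for taxon, r in direct.per_taxon.items():
                assert got.per_taxon[taxon].min_interspecific == pytest.approx(
                    r.min_interspecific
                )
            assert got.failure_rate == pytest.approx(direct.failure_rate)

    def test_single_taxon_flora_skipped_with_warning(self):
        aln, cl = self._two_flora_data()
        lone = TaxonRecord(
            "L f", "species", "L", "F",
            frozenset({"terrestrial"}), True, frozenset({"C"}),
        )
        records = dict(cl.records, **{"L f": lone})
        smap = dict(cl.specimen_map, l1="L f")
        sflora = dict(cl.specimen_flora, l1="C")
        cl2 = SurveyChecklist(records, smap, sflora)
        aln2 = AlignedSequenceSet(
            aln.specimen_ids + ("l1",), aln.rows + (SEQ_B,)
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            reports = compare_floras(aln2, cl2, min_overlap=1)
        assert "C" not in reports
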