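"""Checklist summary statistics: growth habits, clade split, coverage.

Summarises a simulated survey checklist the way floristic papers tabulate
theirs: counts of terminal taxa per growth habit (multi-label, so the
percentages can sum past 100%), the fern/lycophyte split, and the barcode
coverage (share of taxa with a sequenced specimen).
"""

from pteridosurvey import (
    SimulationConfig,
    richness_per_area,
    simulate_flora,
    summarize_checklist,
)

cfg = SimulationConfig(seed=1)
aln, checklist, _, _ = simulate_flora(cfg)

rep = summarize_checklist(checklist, alignment=aln, area_ha=158.0)
print(
    f"{rep.n_taxa} terminal taxa, {rep.n_species} species, "
    f"{rep.n_genera} genera, {rep.n_families} families, "
    f"{rep.n_specimens} specimens"
)
for habit, count in sorted(rep.habit_counts.items()):
    print(f"  {habit:12s} {count:4d}  ({rep.habit_pct[habit]}%)")
print(
    f"ferns: {rep.clade_species['ferns']} spp ({rep.clade_pct['ferns']}%), "
    f"lycophytes: {rep.clade_species['lycophytes']} spp "
    f"({rep.clade_pct['lycophytes']}%)"
)
print(
    f"barcode coverage: {rep.n_barcoded_taxa}/{rep.n_taxa} taxa "
    f"({rep.barcode_coverage_pct}%)"
)
print(
    f"richness per area at 158 ha: {rep.richness_per_area_ha} spp/ha "
    f"(cf. a large lowland station: {richness_per_area(197, 1533)} spp/ha)"
)
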