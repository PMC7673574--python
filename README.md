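# pteridosurvey

Analytics for molecular floristic surveys of ferns and lycophytes
(pteridophytes): given a single-marker barcode alignment (typically plastid
*rbcL*), a specimen checklist and a per-day species incidence table, the
package evaluates how well the marker separates the species of a flora,
estimates how complete the survey is, screens species monophyly on a
distance tree, and tabulates the checklist the way floristic papers do.
A synthetic-flora generator makes every stage runnable at desk scale with
no downloads.

## What it computes

**Barcode gap.** All pairwise raw (uncorrected) p-distances are computed
with pairwise deletion: for specimens *i*, *j*,
`d_ij = (differing sites) / n_ij` over the `n_ij` columns where both carry
an unambiguous base (gaps, `N`, `?` and IUPAC ambiguity codes are deleted
per pair). For each terminal taxon *s* the minimum interspecific distance
is

```
D_min(s) = min { d_ij : i in s, j in any other taxon, pair defined }
```

and *s* is a **failure** when `D_min(s) = 0` exactly — it shares an
identical barcode haplotype with another taxon and cannot be identified by
the marker. Distances are rationals, so the zero test is exact. The
flora-level failure rate is `failures / taxa scored`. With a combined
multi-flora alignment, minima are re-taken within each flora separately so
failure rates are comparable across sites.

**Survey completeness.** From a binary taxon × collection-day incidence
matrix with `T` days, incidence frequencies `Q_k` (species found on exactly
*k* days) drive the bias-corrected Chao2 asymptotic richness estimate

```
S_hat = S_obs + ((T-1)/T) * Q1^2 / (2 Q2)        (Q2 > 0)
S_hat = S_obs + ((T-1)/T) * Q1 (Q1 - 1) / 2      (Q2 = 0)
```

an exact hypergeometric interpolation (rarefaction) for `t <= T`, and the
standard exponential extrapolation beyond `T` driven by
`Q0_hat = S_hat - S_obs`. Confidence bands come from a percentile bootstrap
over sampling units.

**Monophyly screen.** A Saitou–Nei neighbor-joining tree is built from the
distance matrix (deterministic tie-breaking, negative branch lengths
clamped with the deficit moved to the sister edge), midpoint-rooted, and
each multi-specimen taxon is checked: monophyletic iff the smallest clade
containing all its specimens contains nothing else.

**Checklist statistics.** Terminal-taxon totals, multi-label growth-habit
counts and percentages, the fern/lycophyte split, barcode coverage, and
species-per-hectare ratios.

## Worked example

```python
from pteridosurvey import (SimulationConfig, simulate_flora,
                           build_distance_matrix, min_interspecific_distances,
                           accumulation)

cfg = SimulationConfig(seed=1)            # 176 spp, 1,309 bp, 37 days
aln, checklist, incidence, truth = simulate_flora(cfg)
gap = min_interspecific_distances(build_distance_matrix(aln), checklist)
print(gap.n_failures, round(100 * gap.failure_rate, 1))
acc = accumulation(incidence, B=200, seed=2)
print(acc.S_obs, round(acc.S_hat, 1))
```

prints

```
30 17.1
175 176.0
```

— 30 of 175 scored taxa (17.1%) share an identical haplotype with another
taxon (exactly the 15 designated hybrid pairs in the truth record), the
survey observed 175 of 176 true species, and Chao2 estimates the asymptote
at 176 species. The scripts in `examples/` walk through each capability
(barcode gap, richness curve, monophyly screen, checklist summary,
three-flora comparison) and print annotated output.

A thin CLI mirrors the library: `pteridosurvey run --alignment a.fasta
--checklist c.csv --incidence i.csv --out-dir out` executes every stage and
writes TSV/JSON reports plus a manifest with input checksums; subcommands
`summary`, `distances`, `gap`, `compare-floras`, `richness`, `tree`,
`monophyly` and `simulate` run the stages individually.

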