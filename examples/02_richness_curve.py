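"""Rarefaction/extrapolation of species richness from daily incidences.

Uses the simulated survey's 37 collection days, interpolates the expected
species count at smaller efforts, extrapolates to twice the effort, and
reports the Chao2 asymptote with a bootstrap confidence interval.
"""

from pteridosurvey import SimulationConfig, accumulation, simulate_flora

cfg = SimulationConfig(seed=1)
_, _, incidence, truth = simulate_flora(cfg)

acc = accumulation(incidence, B=200, seed=2)
print(f"T = {acc.T} collection days, S_obs = {acc.S_obs} species")
print(f"uniques Q1 = {acc.Q.get(1, 0)}, duplicates Q2 = {acc.Q.get(2, 0)}")
print(
    f"Chao2 asymptote: {acc.S_hat:.1f} species "
    f"(95% CI {acc.asymptote_ci[0]:.1f}-{acc.asymptote_ci[1]:.1f}); "
    f"true richness in this simulation: {truth['true_richness']}"
)
for point in acc.curve:
    if point.t in (10, acc.T, 2 * acc.T):
        print(
            f"  t={point.t:3d} ({point.method}): "
            f"{point.estimate:.1f} expected species"
        )
# the gap between S_obs and the asymptote estimates how many species the
# survey has not yet detected: more sampling days would keep adding species
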