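"""Generate synthetic per-base depth profiles with known ground truth.

The generator draws each base's depth from an overdispersed count
distribution around its component mean: collapsed (~full depth),
uncollapsed (~half depth) and contaminant (low depth).  The truth sidecar
gives the analytic haploidy the pipeline should recover.
"""

from covhap import SimulationParams, build_histogram, simulate_depths

params = SimulationParams(
    n_bases=500_000,
    collapsed_fraction=0.6,
    uncollapsed_fraction=0.3,
    contaminant_fraction=0.1,
    collapsed_depth=100.0,
    contaminant_depth=10.0,
    dispersion=0.5,
    seed=7,
)
depths, truth = simulate_depths(params)
hist = build_histogram(depths)

print(f"simulated bases     : {truth.n_bases:,}")
print(f"  collapsed         : {truth.collapsed_bases:,}")
print(f"  uncollapsed       : {truth.uncollapsed_bases:,}")
print(f"  contaminant       : {truth.contaminant_bases:,}")
print(f"expected haploidy   : {truth.expected_haploidy:.3f}")
print(f"histogram bins      : {len(hist.counts)} (max coverage {hist.max_coverage}X)")
# expected_haploidy = C/(C + U/2) on the realized component counts; feeding
# the depths to `covhap estimate` should reproduce it within ~0.02.
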