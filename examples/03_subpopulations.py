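"""Detect a highly loaded particle subpopulation with rank-2 NNMF.

Generates two matched membrane-loaded batches — one with a planted 10%
subpopulation carrying 10x cargo and a -3 cm^-1 shifted cargo band
(nanoaggregate-like), one without — and runs the factorization.  The
inter-factor RMSE over the cargo band separates the two cases at the
0.4 decision line; cluster assignment then quantifies the outlier
fraction and its characteristic peak-position shift.
"""

import spartakit as sk
from spartakit.simulate import (
    PopulationSpec,
    et_cargo,
    generate_blanks,
    generate_particle_set,
    polymersome_carrier,
)

config = sk.AnalysisConfig()
grid = sk.WavenumberGrid.default()

for label, outlier_fraction in [("two populations", 0.10), ("one population ", 0.0)]:
    spec = PopulationSpec(
        loading_mode="membrane", loading_strength=0.8,
        outlier_fraction=outlier_fraction, seed=1,
    )
    raw, truth = generate_particle_set(
        spec, polymersome_carrier(), et_cargo(), grid, cargo_window=config.cargo_window
    )
    processed, report = sk.run_preprocess(raw, generate_blanks(grid=grid, seed=2), config)
    result = sk.nnmf_two_factor(processed, config)
    result = sk.order_factors(result, config.carrier_window, config.cargo_window, grid)
    labels = sk.assign_clusters(result)
    rmse = sk.factor_rmse(result, config.cargo_window, grid)
    detected = sk.detect_subpopulations(rmse, config.rmse_threshold)
    print(
        f"{label}:  RMSE={rmse:.3f}  detected={detected}  "
        f"cluster 2 = {sk.cluster_fraction(labels):.1f}% of particles"
    )
    if detected:
        feats = sk.particle_features(processed, config.carrier_window, config.cargo_window)
        stats = sk.cluster_peak_stats(labels, feats).set_index("cluster")
        print(
            f"  cargo band median: cluster 1 at {stats.loc[1, 'median']:.0f} cm^-1, "
            f"cluster 2 at {stats.loc[2, 'median']:.0f} cm^-1 "
            f"(solid-state-like shift of the highly loaded particles)"
        )

print(
    "\nRMSE >= 0.4 between the two factor spectra in the cargo window flags a\n"
    "distinct highly loaded subpopulation; below it the batch is one population."
)
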