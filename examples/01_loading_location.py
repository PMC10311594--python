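"""Classify cargo loading location from per-particle scatter statistics.

Generates one membrane-loaded and one core-loaded polymersome batch
(~300 trapped particles each), runs the preprocessing chain, and fits
the cargo-vs-carrier peak-area scatter.  A steep, tight line (high
gradient, high R^2) means the cargo partitions into the membrane; a
flat, uncorrelated cloud means it sits in the aqueous core.
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

for mode, strength in [("membrane", 1.6), ("core_empirical", 5.0)]:
    spec = PopulationSpec(loading_mode=mode, loading_strength=strength, seed=1)
    raw, truth = generate_particle_set(
        spec, polymersome_carrier(), et_cargo(), grid, cargo_window=config.cargo_window
    )
    blanks = generate_blanks(grid=grid, seed=2)
    processed, report = sk.run_preprocess(raw, blanks, config)
    table = sk.particle_features(processed, config.carrier_window, config.cargo_window)
    fit = sk.fit_scatter(table)
    call = sk.classify_loading(fit, config)
    print(
        f"{mode:15s}  n={fit.n}  gradient={fit.gradient:+.2f}  "
        f"R^2={fit.r2:.2f}  ->  {call.label}"
    )

print(
    "\nGradient is the slope of cargo peak area vs carrier peak area across\n"
    "particles; R^2 its coefficient of determination.  Membrane loading gives\n"
    "a proportional (steep, correlated) scatter, core loading a flat one."
)
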