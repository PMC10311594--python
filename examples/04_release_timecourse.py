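"""Track drug release from liposomes over a 48 h dialysis time course.

Simulates a chloroquine-liposome series whose mean drug band intensity
decays from 0.26 to 0.10 (carrier-normalized units) and a stable
doxorubicin-liposome series, then runs the per-time-point analysis:
drug peak intensity, cargo-vs-carrier fit, and the NNMF population test.
"""

import spartakit as sk
from spartakit.simulate import (
    PopulationSpec,
    chloroquine_cargo,
    doxorubicin_cargo,
    generate_blanks,
    generate_release_series,
    lipid_carrier,
)


def analyze(drug, window_name, initial, final, seed):
    config = sk.AnalysisConfig(
        carrier_window=sk.preset_window("lipid_ch2"),
        cargo_window=sk.preset_window(window_name),
    )
    spec = PopulationSpec(n_particles=200, seed=seed)
    series = generate_release_series(
        spec, lipid_carrier(), drug,
        initial_intensity=initial, final_intensity=final,
        drug_window=config.cargo_window,
    )
    processed = []
    for k, (t, s, _) in enumerate(series):
        batch, _ = sk.run_preprocess(s, generate_blanks(grid=s.grid, seed=seed + 100 + k), config)
        processed.append((t, batch))
    return sk.release_profile(processed, config.carrier_window, config.cargo_window, config)


for name, drug, window, initial, final, seed in [
    ("CQ-liposome ", chloroquine_cargo(), "chloroquine", 0.26, 0.10, 7),
    ("Doxil-like  ", doxorubicin_cargo(), "doxorubicin", 0.30, 0.30, 8),
]:
    profile = analyze(drug, window, initial, final, seed)
    print(f"{name} ({profile.stability_flag}):")
    for r, frac in zip(profile.timepoints, profile.fraction_remaining):
        print(
            f"  t={r.time_h:5.1f} h  drug intensity={r.drug_peak_intensity:.3f}  "
            f"remaining={100 * frac:5.1f}%  R^2={r.fit.r2:.2f}  call={r.call.label}"
        )

print(
    "\nDrug intensity is the drug-band maximum of the batch-mean spectrum in\n"
    "carrier-normalized units; 'remaining' is relative to the first time point.\n"
    "Low R^2 at every time point marks core-loaded drug in both formulations."
)
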