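# spartakit

Population-level analysis of single-particle Raman spectra of drug-loaded
nanovesicles (polymersomes and liposomes).

Single-particle automated Raman trapping (SPARTA) measurements produce one
Raman spectrum per optically trapped particle — typically 200–300 particles
per sample.  This package turns those per-particle spectra into statements
about *where* a drug sits in a nanoformulation and *how uniformly* it is
loaded, questions that bulk techniques (HPLC, absorbance) cannot answer:

- **Loading location.** For each particle the carrier peak area *x* (the
  polymer Si–C band at 708 cm⁻¹ or lipid CH₂ band at 1295 cm⁻¹) and the
  cargo peak area *y* (a dialkyne tag at 2208/2220 cm⁻¹ or a drug band) are
  extracted, and the population is summarized by the OLS fit
  *y = βx + α*.  Membrane-partitioned hydrophobic cargo tracks membrane
  amount (high gradient β, high R²); core-entrapped hydrophilic cargo does
  not (β ≈ 0, R² ≈ 0).  The quadrant rule with defaults R² < 0.3 → core,
  R² ≥ 0.3 and β ≥ 0.5 → membrane classifies the batch.
- **Geometric model.** For a unilamellar vesicle of outer radius *r* and
  membrane thickness *t* (default 14 nm), membrane mass is
  ρ·(4π/3)(r³ − (r−t)³) and core volume (4π/3)(r−t)³.  Expected cargo mass
  is linear in carrier mass for membrane loading and cubic in (r−t) for
  core loading — the two scatter shapes above.
- **Subpopulation detection.** Rank-2 non-negative matrix factorization of
  the particle × wavenumber matrix yields a carrier-like factor W1 and a
  cargo-like factor W2 (multiplicative updates, deterministic SVD-based
  initialization, mean-score-1 scaling).  The RMS difference between the
  factors inside the cargo band window (2184–2235 cm⁻¹ for dialkynes)
  detects a minority of highly loaded, nanoaggregate-carrying particles at
  the 0.4 decision line; cluster assignment by highest score quantifies
  their percentage and peak-position shift.
- **Release kinetics.** The same statistics applied across a dialysis time
  course track the drug band intensity of the batch-mean spectrum and flag
  a formulation as releasing or stable.

Every stage is exercisable on synthetic batches with known ground truth
(per-particle radius, carrier/cargo amounts, outlier flags), generated by
`spartakit.simulate`.

## Worked example

`examples/01_loading_location.py` generates a membrane-loaded and a
core-loaded polymersome batch (300 particles each, realistic noise), runs
the preprocessing chain and prints the scatter statistic:

```
membrane         n=300  gradient=+1.22  R^2=0.85  ->  membrane
core_empirical   n=300  gradient=+0.04  R^2=0.04  ->  core
```

A proportional scatter (gradient 1.22, R² 0.85) identifies membrane
partitioning; the flat, uncorrelated scatter identifies core loading.
`examples/03_subpopulations.py` shows the NNMF test on matched batches
with and without a planted 10 % highly loaded subpopulation:

```
two populations:  RMSE=0.859  detected=True  cluster 2 = 12.3% of particles
  cargo band median: cluster 1 at 2220 cm^-1, cluster 2 at 2218 cm^-1 ...
one population :  RMSE=0.161  detected=False  cluster 2 = 48.0% of particles
```

The inter-factor RMSE falls on opposite sides of the 0.4 line, the
recovered outlier percentage matches the planted 10 %, and the cluster-2
cargo band sits a few cm⁻¹ low — the solid-state-like shift of
nanoaggregated cargo.  (Cluster percentages are only meaningful when the
RMSE gate reports two populations.)  The other examples cover the
geometric model curves and the 48 h release time course.

## Command line

A thin CLI chains the stages on CSV files:

```sh
spartakit simulate --out run/ --n 300 --mode membrane
spartakit preprocess --spectra run/spectra.csv --blanks run/blanks.csv --out run/pre/
spartakit features --spectra run/pre/preprocessed.csv --out run/feat/
spartakit subpop   --spectra run/pre/preprocessed.csv --out run/sub/
spartakit model    --out curves.csv
```

Spectra are wide CSV (wavenumber column + one column per particle); all
parameters live in a YAML config (see `spartakit.AnalysisConfig` for the
documented defaults).

## Layout

- `src/spartakit/` — library: `spectra`, `io`, `config`, `simulate`,
  `preprocess`, `features`, `geometry`, `subpop`, `release`, `cli`
- `examples/` — one narrative script per capability
- `tests/` — unit, property and end-to-end suites
- `docs/methods.md` — models, conventions, parameter choices, limitations
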