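# Methods

This note documents the models, conventions and parameter choices behind
spartakit, and what the synthetic-data tests do and do not demonstrate.

## Data model

A batch is a `SpectrumSet`: a shared, strictly increasing, uniform (to 1 %)
wavenumber grid plus an `(n_particles × n_wavenumbers)` intensity matrix.
The default grid is 400–3200 cm⁻¹ at 2 cm⁻¹ spacing, covering the
fingerprint region, the cell-silent dialkyne region and the CH-stretch
bands.  Particle identity is positional: filtering stages report boolean
masks and never renumber, so any retained particle can be traced to its
raw-input column.  Every operation appends itself to the set's provenance
list.

## Preprocessing chain

Order is fixed: (1) spectral response correction (pointwise multiplication
by an instrument curve, identity if absent); (2) trap filtering;
(3) fractional blank subtraction; (4) Whittaker baseline correction;
(5) Savitzky–Golay smoothing (order 1, frame 7); (6) batch normalization
to the carrier peak.  Skipping a stage requires an explicit `apply_*`
config flag.

**Trap filtering.** Real measurements discard empty traps and aggregates
by eye; here the thresholds are automated and relative to batch medians:
a particle is an empty trap if its carrier-window maximum is below
`trap_min_frac` (default 0.25) of the batch median of that maximum, and an
aggregate if its total integrated intensity exceeds `trap_max_mult`
(default 3.0) times the median total.  Both criteria are applied because
empty traps are best seen in the carrier band while aggregates inflate the
whole spectrum.  On synthetic fixtures with ≥ 4× artifact/true separation
the filter is exact (sensitivity and specificity 1.0 in the suite).

**Background subtraction** removes `background_fraction` (default 0.95) of
the mean blank spectrum.  The sub-unity fraction guards against
over-subtraction when the background drifts between blank and particle
acquisition; the residual is handled by the next stage.

**Baseline correction** is asymmetric least squares (Eilers-style
Whittaker smoothing): minimize Σ wᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)² with weights p for
points above the baseline and 1−p below, iteratively reweighted.  Defaults
λ = 1e5, p = 0.01, 10 iterations were chosen so that Gaussian bands of
width ≲ 30 cm⁻¹ on the default grid survive essentially intact: the suite
verifies that a peak riding a linear ramp keeps its area within 5 %, and
that constant offsets are removed to < 0.1 %.  The pentadiagonal normal
equations are solved in symmetric banded form.

**Smoothing** uses the standard local least-squares polynomial filter;
edges are handled by polynomial fits on the truncated terminal windows.
The order-1/frame-7 default equals a 7-point sliding local linear
regression, which the suite checks against a brute-force implementation.

**Normalization** divides the whole batch by one scalar: the mean over
particles of the maximum intensity inside the carrier window.  A single
batch-level divisor removes between-sample effects (laser power,
alignment) while preserving the per-particle carrier-amount variation that
the scatter statistic depends on — per-particle normalization would
destroy the abscissa of the analysis.  After the chain, the batch-mean
carrier maximum is 1 within 1e-9.

Negative intensities left by subtraction stages are retained through
feature extraction (clipping would bias peak areas) and clipped to zero
only at the NNMF boundary, where nonnegativity is required.

## Peak features and the scatter statistic

Peak area is the trapezoidal integral over a configured window after
subtracting the straight line through the window's two endpoint
intensities.  This endpoint-anchored local baseline makes constant offsets
and linear residual background vanish exactly (peak area is linear in the
spectrum), at the cost of slightly truncating bands that reach the window
edges — acceptable because the same measure is used consistently for
calibration and analysis.  Peak position is the wavenumber of the window
maximum, ties breaking toward the lower wavenumber.

Default windows: carrier 688–728 cm⁻¹ (polymer Si–C) or 1275–1315 cm⁻¹
(lipid CH₂); cargo 2184–2235 cm⁻¹ (dialkyne), 1355–1395 cm⁻¹
(chloroquine), 1188–1262 cm⁻¹ (doxorubicin doublet).  Window centers are
the known band positions; half-widths are package choices, config-exposed.

The population statistic is the OLS fit of cargo area on carrier area.
R² is the coefficient of determination (the squared Pearson correlation
for simple OLS).  Degenerate conventions: zero carrier variance is an
error; zero cargo variance returns gradient 0 with R² defined as 0.
Classification is R²-first: core if R² < `r2_core` (0.3), membrane if
R² ≥ `r2_core` and gradient ≥ `gradient_membrane` (0.5), else
indeterminate.  The R²-first ordering deliberately sends steep but
uncorrelated scatters (e.g. crystalline-core formulations with noisy
gradients up to ~1) to "core".  The thresholds reconcile the published
example calls (core examples with R² ≤ 0.26, membrane examples with
R² ≥ 0.35 and gradient ≥ 1.1) but are reconstructions, not measured
constants, and are config-exposed.

## Geometric loading model

For a unilamellar vesicle of outer radius r and membrane thickness t
(default 14 nm, the midpoint of small-angle-scattering estimates and
consistent with cryo-TEM):

- membrane mass  m = ρ · (4π/3)(r³ − (r−t)³), ρ default 0.97 g/cm³
  (bulk-PDMS-like; affects only absolute scale, never curve shape);
- PDMS-block mass = m × 4.8/6.6 (block-mass fraction of a 0.9–4.8–0.9 kDa
  triblock);
- membrane-loading cargo mass = m × feed mass ratio (g cargo per g
  polymer) — exactly linear in carrier mass at every radius;
- core volume V = (4π/3)(r−t)³; core-loading cargo mass = V × feed
  molarity × molar mass — exactly cubic in (r−t).

Assumptions (encoded, not checked against data): unilamellar vesicles
only, complete partitioning into either membrane or core, spatially even
loading.  The model is compared with measured scatters only qualitatively
(curve shapes); no fitting is performed.  Default curve range 25–300 nm.

## Synthetic-data generator

Each particle draws a radius from a lognormal (median 100 nm, log-sd 0.2,
giving ≈ 40 % spread in shell volume), takes carrier amount proportional
to shell volume r³ − (r−t)³, and a cargo amount per loading law:

- `membrane`: cargo = g_true · carrier · (1 + ε), ε ~ N(0, `loading_cv`);
  the dispersity term (default 20 %) reflects that even a single
  population never loads at a perfectly uniform ratio.  Setting it to 0
  yields exactly collinear scatters for construction oracles.
- `core_geometric`: cargo ∝ (r−t)³ — the model's cubic law.
- `core_empirical`: cargo size-independent, N(mean, 30 % CV) clipped at 0 —
  what measured core-loading scatters look like after partial partitioning
  and multilamellarity wash out the cubic geometry.

Core-mode strengths are stated as batch-mean cargo peak areas and
converted to amounts through the same endpoint-anchored area measure the
analysis uses, so constructions are exact by definition.  Spectra are sums
of Gaussian bands (template peak sets for the polymersome, liposome,
dialkyne cargoes, chloroquine and doxorubicin), scaled so the batch-mean
carrier peak maximum is 1, plus a smooth polynomial baseline (default
0.2 − 0.15x + 0.1x² on the normalized axis, i.e. ~20 % of the carrier
peak), a per-particle multiplicative factor N(1, 20 %) emulating laser
power/trap-position variation, and additive white noise (sd 0.01, i.e. 1 %
of the carrier peak).  The noise magnitudes are package choices validated
against the invariant suite, not measured instrument values.

A highly loaded subpopulation is planted by multiplying cargo amounts of
a Bernoulli-selected fraction (default multiplier 10) and shifting the
cargo band center (default −3 cm⁻¹, the solid-state-like shift of
nanoaggregated cargo).  Release series are generated per time point with
the batch-mean drug band intensity following an exponential decay between
the stated endpoints (defaults 0.26 → 0.10 over 0–48 h, sampled at 0, 2,
4, 9, 24, 48 h) with a stationary carrier distribution.

What the generator does **not** emulate: multilamellar and
vesicle-in-vesicle geometry, cosmic-ray spikes, detector nonlinearity,
wavenumber miscalibration, serum background, and non-Gaussian line shapes
(pseudo-Voigt is a possible extension).  Passing tests therefore
demonstrate correctness of the statistics under the stated generative
model, not robustness to every instrumental artifact.

## NNMF subpopulation test

The clipped-nonnegative intensity matrix X is factorized as X ≈ W·H with
rank 2 by Frobenius multiplicative updates.  Initialization is a
deterministic nonnegative double-SVD (leading pair taken with absolute
values, justified by sign coherence of the Perron eigenvectors; second
pair from the dominant sign block; zeros filled with the matrix mean so
updates cannot lock), making results bit-reproducible without a random
fallback.  Iteration stops when the relative error change drops below
`nnmf_tol` (1e-6) or at `nnmf_max_iter` (500); non-convergence is flagged,
not fatal.  The error sequence is non-increasing (a property the suite
asserts per iteration).

Scale convention: each (factor, score) pair is rescaled so the mean score
over particles is 1.  Factor spectra are then average per-particle
contributions in carrier-normalized intensity units, which is the scale on
which the 0.4 RMSE decision line operates.  Factors are ordered by
cargo-to-carrier peak-area ratio (lower ratio → factor 1, carrier-like);
particles are labeled by their higher score, ties to cluster 1; the RMSE
at exactly the threshold counts as detected.  All three tie/boundary rules
are arbitrary but fixed.

On matched synthetic batches (300 particles, 10 % outliers at 10× cargo)
the inter-factor RMSE separates cleanly: ≈ 0.6–0.9 with the planted
subpopulation versus ≈ 0.01–0.16 without, against the 0.4 line — and the
cluster-2 percentage recovers the planted fraction within a few points.
Over 20 paired seeds the detection true-positive rate is ≥ 0.9 and the
false-positive rate ≤ 0.1 at default settings.  Cluster percentages are
reported unconditionally but are only meaningful when the RMSE gate
detects two populations; on single-population batches the score split is
driven by particle size and hovers near 50 %.

One behavior worth recording: with *zero* loading dispersity a
single-population membrane batch is exactly rank 1, the factorization is
degenerate (the second factor collapses), and the inter-factor RMSE
becomes an artifact of the degeneracy rather than a population contrast.
The default 20 % dispersity gives the factorization genuine rank-2
structure, which is also the realistic regime.

## Release analysis

The primary release metric is the drug-band maximum of the batch-mean
spectrum in carrier-normalized units (peak area is reported alongside);
intensity was chosen as primary because the published endpoint values are
peak intensities.  `fraction_remaining` is relative to the first sampled
time, so it is invariant to any global rescaling of a batch (normalization
cancels).  A series is flagged `releasing` when the final fraction drops
below `stability_cutoff` (default 0.8 — a package convention, not a
published threshold).  When the mean per-particle drug area is below three
standard errors of its spread, the core/membrane call is forced to
`indeterminate`: with no cargo signal the location question is meaningless.

## Numerical and interface choices

- Spectra files are wide CSV (wavenumber first column, one column per
  particle, full float precision); round-trips are lossless to 1e-9
  relative.  One canonical dialect keeps tests exact; vendor binary
  formats are out of scope.
- All randomness flows from integer seeds through named
  `numpy.random.SeedSequence` substreams; identical seeds give identical
  batches, tables and factorizations bit-for-bit.
- Problem sizes in the test and acceptance runs (300 particles per batch,
  200 per release time point, 1401 grid points, 20 detection seeds) match
  the scale of a typical trapping session and keep the full suite around a
  minute of compute.

## Known limitations

- The preprocessing constants of the original processing chain beyond the
  printed ones (95 % subtraction, order-1/frame-7 smoothing) are not
  published; the baseline parameters here are validated only against the
  package's own oracles.
- The NNMF scale convention is package-defined; published absolute RMSE
  values obtained under an unspecified convention need not transfer
  exactly, and the 0.4 line is validated on the synthetic suite.
- The geometric model is a shape statement, not a calibration: absolute
  masses depend on the density and block-fraction defaults.
- No encapsulation-efficiency estimation, no kinetic model fitting beyond
  the generator's exponential, no serum-background deconvolution, no
  multi-peak curve fitting.
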