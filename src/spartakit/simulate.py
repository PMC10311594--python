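"""Synthetic single-particle Raman spectra with known ground truth.

Emulates batches of optically trapped nanovesicle spectra: a few hundred
particles, each the sum of a carrier (polymer or lipid) template and a
cargo template, scaled by per-particle amounts driven by vesicle geometry,
on top of a smooth baseline with additive and per-particle multiplicative
noise.  Each batch comes with a truth table (radius, amounts, outlier
flags, cargo band center) so every downstream statistic can be checked
against construction.

Loading laws
------------
* ``membrane``: cargo partitions into the hydrophobic shell, so the cargo
  amount is strictly proportional to the carrier amount
  (``cargo = g_true * carrier``).
* ``core_geometric``: cargo fills the aqueous lumen, so the cargo amount
  scales with the enclosed core volume ``(r - t)^3``.
* ``core_empirical``: cargo amount independent of vesicle size, drawn from
  a clipped normal — what flat experimental core-loading scatters look
  like once partial partitioning and multilamellarity wash out the cubic
  geometry.
* ``none``: empty particles.

A minority "highly loaded" subpopulation (cargo nanoaggregates) can be
planted by multiplying the cargo amount of a random fraction of particles
and shifting their cargo band center a few cm^-1 toward the solid-state
position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .spectra import PeakWindow, SpectrumSet, WavenumberGrid

__all__ = [
    "PeakTemplate",
    "SpectralTemplate",
    "PopulationSpec",
    "generate_particle_set",
    "generate_blanks",
    "spike_artifacts",
    "generate_release_series",
    "area_per_unit_amount",
    "gradient_conversion",
    "polymersome_carrier",
    "et_cargo",
    "nh2_cargo",
    "lipid_carrier",
    "chloroquine_cargo",
    "doxorubicin_cargo",
]

TRUTH_COLUMNS = ["radius_nm", "carrier_amount", "cargo_amount", "is_outlier", "cargo_center_cm1"]


@dataclass(frozen=True)
class PeakTemplate:
    """One Gaussian Raman band: center (cm^-1), width sigma (cm^-1), amplitude."""

    center: float
    width: float
    relative_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be > 0")
        if self.relative_amplitude < 0:
            raise ValueError("relative_amplitude must be >= 0")


@dataclass(frozen=True)
class SpectralTemplate:
    """Named set of Gaussian bands for a carrier or cargo species."""

    name: str
    peaks: tuple[PeakTemplate, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"template {self.name!r} needs at least one peak")

    @property
    def primary(self) -> PeakTemplate:
        """The quantification band: the strongest peak (first on ties)."""
        return max(self.peaks, key=lambda p: p.relative_amplitude)

    def profile(self, grid: WavenumberGrid, primary_shift: float = 0.0) -> np.ndarray:
        """Unit-amount intensity profile on ``grid``.

        ``primary_shift`` moves the quantification band center (used for
        the nanoaggregate subpopulation's solid-state-like shift).
        """
        w = grid.values
        out = np.zeros_like(w)
        primary = self.primary
        for pk in self.peaks:
            center = pk.center + (primary_shift if pk is primary else 0.0)
            out += pk.relative_amplitude * np.exp(-0.5 * ((w - center) / pk.width) ** 2)
        return out


def polymersome_carrier() -> SpectralTemplate:
    """PMOXA-b-PDMS-b-PMOXA polymersome: Si-C 708, CH2/CH3 def. ~1430, CH stretch."""
    return SpectralTemplate(
        "polymersome",
        (
            PeakTemplate(708.0, 8.0, 1.0),
            PeakTemplate(1424.0, 12.0, 0.6),
            PeakTemplate(2905.0, 30.0, 0.7),
        ),
    )


def et_cargo() -> SpectralTemplate:
    """Hydrophobic dialkyne model cargo: C#C-C#C 2220, aromatic ring 1601."""
    return SpectralTemplate(
        "Et",
        (
            PeakTemplate(2220.0, 10.0, 1.0),
            PeakTemplate(1601.0, 8.0, 0.4),
        ),
    )


def nh2_cargo() -> SpectralTemplate:
    """Amine dialkyne cargo: band shifted down to 2208 cm^-1."""
    return SpectralTemplate(
        "NH2",
        (
            PeakTemplate(2208.0, 10.0, 1.0),
            PeakTemplate(1601.0, 8.0, 0.4),
        ),
    )


def lipid_carrier() -> SpectralTemplate:
    """DPPC:cholesterol liposome: CH2 twist 1295, CH2 def. 1440, CH stretch."""
    return SpectralTemplate(
        "liposome",
        (
            PeakTemplate(1295.0, 8.0, 1.0),
            PeakTemplate(1440.0, 10.0, 0.7),
            PeakTemplate(2880.0, 30.0, 0.8),
        ),
    )


def chloroquine_cargo() -> SpectralTemplate:
    """Chloroquine: overlapping C=C/N-H/C-H band at 1375 cm^-1."""
    return SpectralTemplate("chloroquine", (PeakTemplate(1375.0, 9.0, 1.0),))


def doxorubicin_cargo() -> SpectralTemplate:
    """Doxorubicin: C-O / C-O-H / C-H doublet at 1208 and 1242 cm^-1."""
    return SpectralTemplate(
        "doxorubicin",
        (
            PeakTemplate(1208.0, 8.0, 1.0),
            PeakTemplate(1242.0, 8.0, 0.9),
        ),
    )


def area_per_unit_amount(
    template: SpectralTemplate, grid: WavenumberGrid, window: PeakWindow
) -> float:
    """Window peak area contributed by one unit of template amount.

    Measured with the same endpoint-anchored trapezoidal integral used for
    feature extraction, so calibrations based on it are exact by
    construction rather than relying on the full-line Gaussian area.
    """
    from .features import peak_area

    return peak_area(template.profile(grid), grid, window)


def gradient_conversion(
    carrier: SpectralTemplate,
    cargo: SpectralTemplate,
    grid: WavenumberGrid,
    carrier_window: PeakWindow,
    cargo_window: PeakWindow,
) -> float:
    """Factor mapping the amount-space proportionality ``g_true`` to the
    peak-area-space gradient the scatter fit estimates:
    ``gradient = g_true * gradient_conversion(...)``.
    """
    a_cargo = area_per_unit_amount(cargo, grid, cargo_window)
    a_carrier = area_per_unit_amount(carrier, grid, carrier_window)
    if a_carrier <= 0:
        raise ValueError("carrier template has no area in the carrier window")
    return a_cargo / a_carrier


LOADING_MODES = ("membrane", "core_geometric", "core_empirical", "none")


@dataclass
class PopulationSpec:
    """Generator parameters for one particle batch.

    ``loading_strength`` is the true cargo:carrier amount proportionality
    for ``membrane`` mode, and the batch-mean cargo peak area (in
    carrier-normalized units) for the two core modes.  ``loading_cv`` is
    the per-particle dispersity of the membrane loading ratio (set to 0
    for exactly collinear scatters); ``core_cv`` is the relative spread of
    the size-independent ``core_empirical`` cargo amounts.
    """

    n_particles: int = 300
    radius_median_nm: float = 100.0
    radius_logsd: float = 0.2
    membrane_thickness_nm: float = 14.0
    loading_mode: str = "membrane"
    loading_strength: float = 0.8
    loading_cv: float = 0.2
    core_cv: float = 0.3
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 10.0
    outlier_center_shift: float = -3.0
    noise_additive_sd: float = 0.01
    noise_multiplicative_cv: float = 0.2
    baseline_coeffs: tuple[float, ...] = (0.2, -0.15, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.radius_median_nm <= self.membrane_thickness_nm:
            raise ValueError("radius_median_nm must exceed membrane_thickness_nm")
        if self.membrane_thickness_nm <= 0:
            raise ValueError("membrane_thickness_nm must be > 0")
        if self.loading_mode not in LOADING_MODES:
            raise ValueError(f"loading_mode must be one of {LOADING_MODES}")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.outlier_multiplier < 1.0:
            raise ValueError("outlier_multiplier must be >= 1")
        if self.loading_mode == "none" and self.outlier_fraction > 0:
            raise ValueError("loading_mode 'none' cannot have outliers")
        for name in (
            "loading_strength",
            "loading_cv",
            "core_cv",
            "noise_additive_sd",
            "noise_multiplicative_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _baseline(grid: WavenumberGrid, coeffs) -> np.ndarray:
    """Smooth polynomial baseline on the normalized axis x in [0, 1]."""
    w = grid.values
    x = (w - w[0]) / (w[-1] - w[0])
    out = np.zeros_like(x)
    for k, c in enumerate(coeffs):
        out += c * x**k
    return out


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def generate_particle_set(
    spec: PopulationSpec,
    carrier: SpectralTemplate,
    cargo: SpectralTemplate,
    grid: WavenumberGrid | None = None,
    cargo_window: PeakWindow | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Generate one particle batch and its aligned truth table.

    Per particle: radius ~ lognormal(median, logsd); carrier amount
    proportional to shell volume ``r^3 - (r - t)^3``; cargo amount per the
    loading law; spectrum = amounts x templates + baseline + noise.  The
    batch is scaled so the mean noise-free carrier peak maximum is 1,
    matching the carrier normalization applied during preprocessing.

    ``cargo_window`` defaults to +-3 sigma around the cargo quantification
    band and is only used to express core-mode loading strengths as peak
    areas.
    """
    if grid is None:
        grid = WavenumberGrid.default()
    if cargo_window is None:
        pk = cargo.primary
        cargo_window = PeakWindow("cargo_quant", pk.center - 3 * pk.width, pk.center + 3 * pk.width)
    rng = _streams(spec.seed, ("radius", "cargo", "outlier", "mult", "additive"))

    n = spec.n_particles
    t = spec.membrane_thickness_nm
    radius = spec.radius_median_nm * np.exp(spec.radius_logsd * rng["radius"].standard_normal(n))
    radius = np.maximum(radius, t * 1.001)
    shell_volume = radius**3 - (radius - t)**3
    core_volume = (radius - t) ** 3

    carrier_profile = carrier.profile(grid)
    # scale so the batch-mean carrier peak maximum is exactly 1 (noise-free)
    carrier_amount = shell_volume / (shell_volume.mean() * carrier_profile.max())

    a_unit = area_per_unit_amount(cargo, grid, cargo_window)
    if spec.loading_mode == "membrane":
        # per-particle loading dispersity: even one population never loads
        # with a perfectly uniform cargo:carrier ratio
        g_i = spec.loading_strength * np.clip(
            1.0 + spec.loading_cv * rng["cargo"].standard_normal(n), 0.1, None
        )
        cargo_amount = g_i * carrier_amount
    elif spec.loading_mode == "core_geometric":
        mean_amount = spec.loading_strength / a_unit
        cargo_amount = core_volume / core_volume.mean() * mean_amount
    elif spec.loading_mode == "core_empirical":
        mean_amount = spec.loading_strength / a_unit
        draws = rng["cargo"].normal(mean_amount, spec.core_cv * mean_amount, size=n)
        cargo_amount = np.clip(draws, 0.0, None)
    else:  # none
        cargo_amount = np.zeros(n)

    is_outlier = rng["outlier"].random(n) < spec.outlier_fraction
    cargo_amount = np.where(is_outlier, cargo_amount * spec.outlier_multiplier, cargo_amount)
    cargo_center = np.full(n, cargo.primary.center)
    cargo_center[is_outlier] += spec.outlier_center_shift

    cargo_profile = cargo.profile(grid)
    signal = np.outer(carrier_amount, carrier_profile)
    if spec.loading_mode != "none":
        if is_outlier.any():
            shifted = cargo.profile(grid, primary_shift=spec.outlier_center_shift)
            signal[~is_outlier] += np.outer(cargo_amount[~is_outlier], cargo_profile)
            signal[is_outlier] += np.outer(cargo_amount[is_outlier], shifted)
        else:
            signal += np.outer(cargo_amount, cargo_profile)

    baseline = _baseline(grid, spec.baseline_coeffs)
    mult = 1.0
    if spec.noise_multiplicative_cv > 0:
        mult = np.clip(
            rng["mult"].normal(1.0, spec.noise_multiplicative_cv, size=n), 0.1, None
        )[:, None]
    intensities = (signal + baseline) * mult
    if spec.noise_additive_sd > 0:
        intensities = intensities + rng["additive"].normal(
            0.0, spec.noise_additive_sd, size=intensities.shape
        )

    truth = pd.DataFrame(
        {
            "radius_nm": radius,
            "carrier_amount": carrier_amount,
            "cargo_amount": cargo_amount,
            "is_outlier": is_outlier,
            "cargo_center_cm1": cargo_center,
        }
    )
    spectra = SpectrumSet(
        grid=grid,
        intensities=intensities,
        sample_id=f"sim:{carrier.name}+{cargo.name}:{spec.loading_mode}",
        provenance=[f"generate_particle_set(seed={spec.seed}, mode={spec.loading_mode})"],
    )
    return spectra, truth


def generate_blanks(
    n: int = 20,
    grid: WavenumberGrid | None = None,
    baseline_coeffs: tuple[float, ...] = (0.2, -0.15, 0.1),
    noise_sd: float = 0.01,
    seed: int = 0,
) -> SpectrumSet:
    """Blank buffer spectra: baseline plus additive noise, no particle bands.

    The default count of 20 mirrors typical blank-acquisition practice for
    background subtraction.
    """
    if n < 1:
        raise ValueError("need at least one blank spectrum")
    if grid is None:
        grid = WavenumberGrid.default()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    baseline = _baseline(grid, baseline_coeffs)
    intensities = np.tile(baseline, (n, 1))
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=intensities.shape)
    return SpectrumSet(
        grid=grid,
        intensities=intensities,
        sample_id="blanks",
        provenance=[f"generate_blanks(n={n}, seed={seed})"],
    )


def spike_artifacts(
    s: SpectrumSet,
    n_empty: int = 0,
    n_aggregate: int = 0,
    aggregate_scale: float = 10.0,
    baseline_coeffs: tuple[float, ...] = (0.2, -0.15, 0.1),
    noise_sd: float = 0.01,
    seed: int = 1,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Append trap artifacts to a batch: empty traps and aggregates.

    Empty traps are blank-like spectra (baseline + noise, no carrier band);
    aggregates are randomly chosen existing particles multiplied by
    ``aggregate_scale``.  Artifacts are appended, never interleaved, so the
    truth alignment of the original rows is untouched.  Returns the spiked
    batch and a flag table (``is_empty``, ``is_aggregate``) covering all rows.
    """
    if n_empty < 0 or n_aggregate < 0:
        raise ValueError("artifact counts must be >= 0")
    if n_aggregate > 0 and aggregate_scale <= 1:
        raise ValueError("aggregate_scale must be > 1")
    blocks = [s.intensities]
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if n_empty > 0:
        baseline = _baseline(s.grid, baseline_coeffs)
        empties = np.tile(baseline, (n_empty, 1))
        if noise_sd > 0:
            empties = empties + rng.normal(0.0, noise_sd, size=empties.shape)
        blocks.append(empties)
    if n_aggregate > 0:
        picks = rng.integers(0, s.n_particles, size=n_aggregate)
        blocks.append(s.intensities[picks] * aggregate_scale)
    intensities = np.vstack(blocks)
    n_total = intensities.shape[0]
    flags = pd.DataFrame(
        {
            "is_empty": np.zeros(n_total, dtype=bool),
            "is_aggregate": np.zeros(n_total, dtype=bool),
        }
    )
    flags.loc[s.n_particles : s.n_particles + n_empty - 1, "is_empty"] = True
    flags.loc[s.n_particles + n_empty :, "is_aggregate"] = True
    spiked = SpectrumSet(
        grid=s.grid,
        intensities=intensities,
        sample_id=s.sample_id,
        feed_mM=s.feed_mM,
        acquisition_s=s.acquisition_s,
        provenance=[*s.provenance, f"spike_artifacts(n_empty={n_empty}, n_aggregate={n_aggregate})"],
    )
    return spiked, flags


def _strength_for_mean_height(
    template: SpectralTemplate,
    grid: WavenumberGrid,
    window: PeakWindow,
    height: float,
) -> float:
    """Loading strength (mean peak area) that yields a target mean peak height."""
    profile = template.profile(grid)
    idx = grid.window_indices(window)
    unit_height = profile[idx].max()
    if unit_height <= 0:
        raise ValueError("template has no intensity in the drug window")
    a_unit = area_per_unit_amount(template, grid, window)
    return height / unit_height * a_unit


def generate_release_series(
    spec: PopulationSpec,
    carrier: SpectralTemplate,
    drug: SpectralTemplate,
    timepoints_h: tuple[float, ...] = (0.0, 2.0, 4.0, 9.0, 24.0, 48.0),
    initial_intensity: float = 0.26,
    final_intensity: float = 0.10,
    drug_window: PeakWindow | None = None,
) -> list[tuple[float, SpectrumSet, pd.DataFrame]]:
    """Simulate a dialysis release time course.

    The batch-mean drug peak intensity (in carrier-normalized units)
    decays exponentially from ``initial_intensity`` at the first sampled
    time to ``final_intensity`` at the last; the carrier signal
    distribution is stationary.  ``initial == final`` gives a flat,
    stable-formulation series.  Cargo is core-loaded (size-independent,
    ``core_empirical``) matching passively loaded liposomal drugs.
    """
    timepoints = tuple(float(t) for t in timepoints_h)
    if len(timepoints) < 2:
        raise ValueError("need at least two timepoints")
    if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError("timepoints must be strictly increasing")
    if initial_intensity <= 0 or final_intensity <= 0:
        raise ValueError("intensities must be > 0")
    if final_intensity > initial_intensity:
        raise ValueError("release only: final_intensity must be <= initial_intensity")
    grid = WavenumberGrid.default()
    if drug_window is None:
        pk = drug.primary
        drug_window = PeakWindow("drug_quant", pk.center - 3 * pk.width, pk.center + 3 * pk.width)

    t0, t_end = timepoints[0], timepoints[-1]
    ratio = final_intensity / initial_intensity
    children = np.random.SeedSequence(spec.seed).spawn(len(timepoints))
    series = []
    for t, child in zip(timepoints, children):
        tau = (t - t0) / (t_end - t0)
        intensity_t = initial_intensity * ratio**tau
        strength = _strength_for_mean_height(drug, grid, drug_window, intensity_t)
        child_seed = int(child.generate_state(1)[0] % (2**31))
        spec_t = replace(
            spec,
            loading_mode="core_empirical",
            loading_strength=strength,
            outlier_fraction=0.0,
            seed=child_seed,
        )
        spectra, truth = generate_particle_set(
            spec_t, carrier, drug, grid, cargo_window=drug_window
        )
        spectra.provenance.append(f"release_timepoint(t={t}h, target_intensity={intensity_t:.4f})")
        series.append((t, spectra, truth))
    return series
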