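"""Spectral preprocessing chain for trapped-particle Raman batches.

Stage order is fixed: instrument response correction, trap filtering
(empty traps and aggregates), fractional blank subtraction, Whittaker
(asymmetric least squares) baseline correction, Savitzky-Golay smoothing,
and batch normalization to the mean carrier-peak intensity.  Each stage
can be switched off only through an explicit configuration flag, and each
records itself in the SpectrumSet provenance.

Negative intensities arising from background/baseline subtraction are
retained: clipping happens only at the non-negative factorization
boundary, keeping peak areas unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .config import AnalysisConfig
from .spectra import PeakWindow, SpectrumSet

__all__ = [
    "PreprocessReport",
    "apply_response_correction",
    "filter_traps",
    "subtract_background",
    "whittaker_baseline",
    "savgol_smooth",
    "normalize_to_carrier",
    "run_preprocess",
]


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing run."""

    n_input: int
    n_removed_low: int
    n_removed_high: int
    mask: np.ndarray  # True = retained, aligned with raw input particles
    normalization_divisor: float

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_low + self.n_removed_high + self.n_retained:
            raise ValueError("preprocess report counts are inconsistent")


def apply_response_correction(s: SpectrumSet, curve: np.ndarray) -> SpectrumSet:
    """Multiply every spectrum pointwise by a spectral response curve.

    The curve is the relative intensity correction measured on a
    fluorescence standard; it must be strictly positive and defined on the
    same grid.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (s.n_wavenumbers,):
        raise ValueError(
            f"response curve has {curve.size} points, grid has {s.n_wavenumbers}"
        )
    if np.any(curve <= 0):
        raise ValueError("response curve must be strictly positive")
    return s.with_intensities(s.intensities * curve, "response_correction")


def filter_traps(
    s: SpectrumSet,
    carrier_window: PeakWindow,
    min_frac: float = 0.25,
    max_mult: float = 3.0,
) -> tuple[SpectrumSet, PreprocessReport]:
    """Remove empty traps and aggregates by relative thresholding.

    Empty traps: carrier-window peak maximum below ``min_frac`` times the
    batch median of that maximum.  Aggregates: total integrated intensity
    above ``max_mult`` times the batch median total.  Both thresholds are
    relative to batch medians, automating what is done by eye on real
    measurements.
    """
    if not 0.0 < min_frac < 1.0:
        raise ValueError("min_frac must be in (0, 1)")
    if max_mult <= 1.0:
        raise ValueError("max_mult must be > 1")
    if s.n_particles < 3:
        raise ValueError("trap filtering needs >= 3 particles for a stable median")
    idx = s.grid.window_indices(carrier_window)
    carrier_max = s.intensities[:, idx].max(axis=1)
    totals = s.intensities.sum(axis=1)
    low = carrier_max < min_frac * np.median(carrier_max)
    high = (totals > max_mult * np.median(totals)) & ~low
    mask = ~(low | high)
    if not mask.any():
        raise ValueError("no particles survive filtering")
    report = PreprocessReport(
        n_input=s.n_particles,
        n_removed_low=int(low.sum()),
        n_removed_high=int(high.sum()),
        mask=mask,
        normalization_divisor=1.0,
    )
    return s.select(mask, f"filter_traps(min_frac={min_frac}, max_mult={max_mult})"), report


def subtract_background(s: SpectrumSet, blanks: SpectrumSet, fraction: float = 0.95) -> SpectrumSet:
    """Subtract ``fraction`` times the mean blank spectrum from every particle.

    The sub-unity fraction avoids over-subtraction when the blank level
    drifts between acquisition of blanks and particles; residual
    background is handled by the baseline correction stage.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if blanks.grid != s.grid:
        raise ValueError("blank spectra are on a different wavenumber grid")
    mean_blank = blanks.intensities.mean(axis=0)
    return s.with_intensities(
        s.intensities - fraction * mean_blank, f"subtract_background(fraction={fraction})"
    )


def _als_baseline(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    """Asymmetric least squares baseline of a single spectrum.

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` with
    asymmetric weights ``w_i = p`` above the baseline and ``1 - p`` below,
    iteratively reweighted.  The normal equations are pentadiagonal and
    solved in banded form.
    """
    n = y.size
    # upper banded form of lam * D2'D2 (D2 = second-difference operator):
    # pentadiagonal with diagonal [1, 5, 6, ..., 6, 5, 1], first
    # off-diagonal [-2, -4, ..., -4, -2], second off-diagonal all ones.
    penalty = np.zeros((3, n))
    penalty[0, 2:] = lam
    penalty[1, 1] = penalty[1, -1] = -2.0 * lam
    penalty[1, 2:-1] = -4.0 * lam
    penalty[2, :] = 6.0 * lam
    penalty[2, 0] = penalty[2, -1] = 1.0 * lam
    penalty[2, 1] = penalty[2, -2] = 5.0 * lam
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        ab = penalty.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.all(w_new == w):
            break
        w = w_new
    if not np.any(w):
        raise RuntimeError("baseline weights collapsed to zero")
    return z


def whittaker_baseline(
    s: SpectrumSet, lam: float = 1e5, p: float = 0.01, n_iter: int = 10
) -> SpectrumSet:
    """Subtract an asymmetric-least-squares (Whittaker) baseline per spectrum.

    Defaults (lam=1e5, p=0.01, 10 reweighting iterations) leave Gaussian
    bands of width up to ~30 cm^-1 essentially intact on the default
    2 cm^-1 grid while removing slowly varying fluorescence background.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if lam <= 0 or not 0.0 < p < 1.0:
        raise ValueError("require lam > 0 and 0 < p < 1")
    corrected = np.empty_like(s.intensities)
    for i in range(s.n_particles):
        corrected[i] = s.intensities[i] - _als_baseline(s.intensities[i], lam, p, n_iter)
    return s.with_intensities(corrected, f"whittaker_baseline(lam={lam}, p={p})")


def savgol_smooth(s: SpectrumSet, order: int = 1, frame: int = 7) -> SpectrumSet:
    """Savitzky-Golay smoothing of each spectrum.

    Local least-squares polynomial of the stated order over a sliding
    window of ``frame`` points; edges are handled by fitting the
    polynomial on the truncated terminal windows.
    """
    if frame % 2 == 0 or frame < 3:
        raise ValueError("frame must be odd and >= 3")
    if order >= frame:
        raise ValueError("order must be < frame")
    if frame > s.n_wavenumbers:
        raise ValueError("frame exceeds number of grid points")
    smoothed = savgol_filter(s.intensities, frame, order, axis=1, mode="interp")
    return s.with_intensities(smoothed, f"savgol(order={order}, frame={frame})")


def normalize_to_carrier(
    s: SpectrumSet, carrier_window: PeakWindow
) -> tuple[SpectrumSet, float]:
    """Divide the batch by the mean carrier-peak maximum.

    One scalar divisor per batch — the mean over particles of the maximum
    intensity inside the carrier window — so that between-sample effects
    (laser power, alignment) cancel while the per-particle carrier-amount
    variation that drives the scatter analysis is preserved.
    """
    idx = s.grid.window_indices(carrier_window)
    divisor = float(s.intensities[:, idx].max(axis=1).mean())
    if divisor <= 0:
        raise ValueError("no carrier signal: batch-mean carrier peak maximum <= 0")
    return (
        s.with_intensities(s.intensities / divisor, f"normalize_to_carrier(divisor={divisor:.6g})"),
        divisor,
    )


def run_preprocess(
    raw: SpectrumSet,
    blanks: SpectrumSet,
    config: AnalysisConfig,
    response_curve: np.ndarray | None = None,
) -> tuple[SpectrumSet, PreprocessReport]:
    """Full preprocessing chain in canonical order.

    response correction -> trap filter -> background subtraction ->
    baseline correction -> smoothing -> carrier normalization.  Stages are
    individually gated by the explicit ``apply_*`` config flags.
    """
    s = raw
    if config.apply_response_correction and response_curve is not None:
        s = apply_response_correction(s, response_curve)
    if config.apply_trap_filter:
        s, report = filter_traps(
            s, config.carrier_window, config.trap_min_frac, config.trap_max_mult
        )
    else:
        report = PreprocessReport(
            n_input=raw.n_particles,
            n_removed_low=0,
            n_removed_high=0,
            mask=np.ones(raw.n_particles, dtype=bool),
            normalization_divisor=1.0,
        )
    if config.apply_background:
        s = subtract_background(s, blanks, config.background_fraction)
    if config.apply_baseline:
        s = whittaker_baseline(
            s, config.baseline_lambda, config.baseline_p, config.baseline_niter
        )
    if config.apply_smoothing:
        s = savgol_smooth(s, config.savgol_order, config.savgol_frame)
    if config.apply_normalization:
        s, divisor = normalize_to_carrier(s, config.carrier_window)
        report.normalization_divisor = divisor
    return s, report
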