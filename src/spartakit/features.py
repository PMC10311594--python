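"""Per-particle peak features and the carrier-cargo scatter statistic.

The loading-location test works on two numbers per particle: the carrier
peak area (membrane amount) and the cargo peak area.  An ordinary
least-squares fit of cargo on carrier across the batch summarizes the
population: membrane-partitioned cargo tracks the carrier amount (high
gradient, high R^2), core-loaded cargo does not (low gradient, low R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .spectra import PeakWindow, SpectrumSet

__all__ = [
    "LinearFit",
    "LoadingCall",
    "peak_area",
    "peak_position",
    "particle_features",
    "fit_scatter",
    "classify_loading",
    "mean_spectrum",
]

FEATURE_COLUMNS = ["carrier_area", "cargo_area", "carrier_position_cm1", "cargo_position_cm1"]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of cargo peak area on carrier peak area."""

    gradient: float
    intercept: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("linear fit needs n >= 2")
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")


@dataclass(frozen=True)
class LoadingCall:
    """Loading-location classification with the thresholds that produced it."""

    label: str  # {"core", "membrane", "indeterminate"}
    r2_core: float
    gradient_membrane: float


def peak_area(spectrum: np.ndarray, grid, window: PeakWindow) -> float:
    """Trapezoidal peak area above a local endpoint-anchored baseline.

    A straight line through the window's two endpoint intensities is
    subtracted before integrating, so constant offsets and linear residual
    background contribute nothing.  Can be negative for noise-only windows.
    """
    idx = grid.window_indices(window)
    if idx.size < 3:
        raise ValueError(f"window {window.name!r} covers fewer than 3 grid points")
    w = grid.values[idx]
    y = np.asarray(spectrum, dtype=float)[idx]
    chord = y[0] + (y[-1] - y[0]) * (w - w[0]) / (w[-1] - w[0])
    return float(np.trapezoid(y - chord, w))


def peak_position(spectrum: np.ndarray, grid, window: PeakWindow) -> float:
    """Wavenumber of the maximum intensity inside the window.

    Ties break toward the lower wavenumber (first maximum).
    """
    idx = grid.window_indices(window)
    if idx.size == 0:
        raise ValueError(f"window {window.name!r} contains no grid points")
    y = np.asarray(spectrum, dtype=float)[idx]
    return float(grid.values[idx][int(np.argmax(y))])


def particle_features(
    s: SpectrumSet, carrier_window: PeakWindow, cargo_window: PeakWindow
) -> pd.DataFrame:
    """Peak area and position for both windows, one row per particle.

    Row order matches the particle order of the input batch.
    """
    rows = np.empty((s.n_particles, 4))
    for i in range(s.n_particles):
        y = s.intensities[i]
        rows[i] = (
            peak_area(y, s.grid, carrier_window),
            peak_area(y, s.grid, cargo_window),
            peak_position(y, s.grid, carrier_window),
            peak_position(y, s.grid, cargo_window),
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def fit_scatter(features: pd.DataFrame) -> LinearFit:
    """OLS of cargo area on carrier area; R^2 is the coefficient of determination.

    Degenerate conventions: zero carrier variance is an error (no abscissa
    spread to fit against); zero cargo variance returns gradient 0 with
    R^2 defined as 0.
    """
    x = features["carrier_area"].to_numpy(dtype=float)
    y = features["cargo_area"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("fit_scatter needs at least 3 particles")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in carrier peak area")
    if np.ptp(y) == 0:
        return LinearFit(gradient=0.0, intercept=float(y[0]), r2=0.0, n=x.size)
    res = stats.linregress(x, y)
    return LinearFit(
        gradient=float(res.slope),
        intercept=float(res.intercept),
        r2=min(float(res.rvalue**2), 1.0),
        n=x.size,
    )


def classify_loading(fit: LinearFit, config: AnalysisConfig) -> LoadingCall:
    """Quadrant rule for loading location.

    ``core`` if R^2 < r2_core; ``membrane`` if R^2 >= r2_core and
    gradient >= gradient_membrane; otherwise ``indeterminate``.  The
    R^2-first ordering means a noisy-but-steep scatter with no correlation
    is still called core.
    """
    if fit.r2 < config.r2_core:
        label = "core"
    elif fit.gradient >= config.gradient_membrane:
        label = "membrane"
    else:
        label = "indeterminate"
    return LoadingCall(label=label, r2_core=config.r2_core, gradient_membrane=config.gradient_membrane)


def mean_spectrum(s: SpectrumSet) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample standard deviation across particles."""
    mean = s.intensities.mean(axis=0)
    if s.n_particles == 1:
        return mean, np.zeros_like(mean)
    return mean, s.intensities.std(axis=0, ddof=1)
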