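"""Core containers for single-particle Raman spectra.

A batch of optically trapped particles is represented as a
:class:`SpectrumSet`: one shared wavenumber grid plus a matrix with one
row per particle.  Particle identity is positional (row order); filtering
stages report boolean masks rather than renumbering, so every retained
particle can be traced back to its raw-input column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["WavenumberGrid", "PeakWindow", "SpectrumSet"]


@dataclass(frozen=True)
class PeakWindow:
    """Closed wavenumber interval ``[lo, hi]`` used for peak quantification."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(
                f"peak window {self.name!r}: lo ({self.lo}) must be < hi ({self.hi})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


class WavenumberGrid:
    """Strictly increasing, (near-)uniform Raman-shift axis in cm^-1."""

    #: maximum relative deviation of point spacing from the mean spacing
    UNIFORMITY_RTOL = 0.01

    def __init__(self, values) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavenumber grid must be a 1-D array with >= 2 points")
        diffs = np.diff(values)
        if not np.all(diffs > 0):
            raise ValueError("non-monotone grid: wavenumbers must be strictly increasing")
        mean_step = diffs.mean()
        if np.any(np.abs(diffs - mean_step) > self.UNIFORMITY_RTOL * mean_step):
            raise ValueError("grid spacing is not uniform to within 1% relative tolerance")
        self.values = values
        self.values.setflags(write=False)

    @property
    def spacing(self) -> float:
        return float(np.diff(self.values).mean())

    @property
    def n_points(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0, atol=1e-9
        )

    def contains(self, window: PeakWindow) -> bool:
        return self.values[0] <= window.lo and window.hi <= self.values[-1]

    def window_indices(self, window: PeakWindow) -> np.ndarray:
        """Indices of grid points falling inside ``window`` (inclusive)."""
        if not self.contains(window):
            raise ValueError(
                f"window {window.name!r} [{window.lo}, {window.hi}] outside grid "
                f"range [{self.values[0]}, {self.values[-1]}]"
            )
        return np.flatnonzero((self.values >= window.lo) & (self.values <= window.hi))

    @classmethod
    def default(cls, lo: float = 400.0, hi: float = 3200.0, step: float = 2.0) -> "WavenumberGrid":
        """Default acquisition axis: 400-3200 cm^-1 at 2 cm^-1 spacing.

        Covers the fingerprint region plus the cell-silent region where
        dialkyne tags scatter, with headroom for CH-stretch bands.
        """
        n = int(round((hi - lo) / step)) + 1
        return cls(lo + step * np.arange(n))


@dataclass
class SpectrumSet:
    """Wavenumber grid plus per-particle intensity matrix with metadata.

    ``intensities`` has shape ``(n_particles, n_wavenumbers)``.  The
    ``provenance`` list records, in order, every operation that produced
    this object (generator, preprocessing stages, ...).
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    sample_id: str = ""
    feed_mM: float | None = None
    acquisition_s: float | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != len(self.grid):
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} columns but grid "
                f"has {len(self.grid)} points"
            )
        if self.intensities.shape[0] < 1:
            raise ValueError("SpectrumSet needs at least one particle")
        if not np.all(np.isfinite(self.intensities)):
            bad = np.flatnonzero(~np.isfinite(self.intensities).all(axis=1))
            raise ValueError(f"non-finite intensities in particle(s) {bad.tolist()}")
        if self.feed_mM is not None and self.feed_mM < 0:
            raise ValueError("feed_mM must be nonnegative")
        if self.acquisition_s is not None and self.acquisition_s <= 0:
            raise ValueError("acquisition_s must be positive")

    @property
    def n_particles(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.intensities.shape[1]

    def with_intensities(self, intensities: np.ndarray, step: str) -> "SpectrumSet":
        """New SpectrumSet with replaced intensities and ``step`` appended to provenance."""
        return replace(
            self,
            intensities=intensities,
            provenance=[*self.provenance, step],
        )

    def select(self, mask: np.ndarray, step: str) -> "SpectrumSet":
        """Subset of particles given a boolean mask; order preserved."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_particles,):
            raise ValueError("mask length must equal n_particles")
        if not mask.any():
            raise ValueError("no particles survive filtering")
        return self.with_intensities(self.intensities[mask], step)
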