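"""Reading and writing spectra and result tables as delimited text.

The canonical spectra dialect is a wide CSV: first column the wavenumber
axis, one further column per particle, with a header row of particle
identifiers.  Values are written at full float precision so a write/read
round trip is lossless to 1e-9 relative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectra import SpectrumSet, WavenumberGrid

__all__ = ["read_spectra", "write_spectra"]

WAVENUMBER_COLUMN = "wavenumber_cm1"


def read_spectra(path) -> SpectrumSet:
    """Read a wide-CSV spectra file into a :class:`SpectrumSet`.

    The first column must parse as a strictly increasing wavenumber axis;
    every further column is one particle, in file order.
    """
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise FileNotFoundError(f"spectra file not found: {path}") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spectra file {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ValueError(
            f"spectra file {path}: need a wavenumber column plus >=1 intensity column"
        )
    for col in frame.columns:
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int(np.flatnonzero(bad | frame[col].isna())[0])
            raise ValueError(
                f"spectra file {path}: non-numeric or missing value at "
                f"row {row + 2}, column {col!r}"
            )
    wn = frame.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wn) <= 0):
        raise ValueError(f"spectra file {path}: non-monotone grid in first column")
    grid = WavenumberGrid(wn)
    intensities = frame.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectrumSet(
        grid=grid,
        intensities=intensities,
        provenance=[f"read_spectra({path})"],
    )


def write_spectra(s: SpectrumSet, path) -> str:
    """Write a :class:`SpectrumSet` as a wide CSV; returns the path written.

    Refuses to write non-finite values, naming the offending particle.
    """
    if not np.all(np.isfinite(s.intensities)):
        bad = np.flatnonzero(~np.isfinite(s.intensities).all(axis=1))
        raise ValueError(f"refusing to write non-finite intensities for particle(s) {bad.tolist()}")
    columns = {WAVENUMBER_COLUMN: s.grid.values}
    for i in range(s.n_particles):
        columns[f"p{i:04d}"] = s.intensities[i]
    frame = pd.DataFrame(columns)
    frame.to_csv(path, index=False, float_format="%.17g")
    return str(path)
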