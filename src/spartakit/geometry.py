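"""Geometric core-vs-membrane loading model for unilamellar vesicles.

Relates the carrier (membrane polymer) mass of a vesicle to the cargo
mass expected under the two loading scenarios:

* membrane loading — hydrophobic cargo partitions completely into the
  shell, so cargo mass is the membrane mass times the feed mass ratio
  (linear in carrier mass for every radius);
* core loading — hydrophilic cargo is entrapped at the feed concentration
  in the aqueous lumen, so cargo mass scales with the core volume
  ``(r - t)^3`` (cubic in the inner radius, much flatter against carrier
  mass at small radii).

Model assumptions: only unilamellar vesicles, complete partitioning into
either membrane or core, and spatially even loading (no nanodomains or
aggregates).  Masses are absolute (grams per particle) but only the curve
shapes matter for comparison with peak-area scatters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VesicleGeometry",
    "ModelParams",
    "membrane_mass",
    "pdms_mass",
    "core_volume",
    "membrane_cargo_mass",
    "core_cargo_mass",
    "model_curves",
]

NM3_TO_CM3 = 1e-21
NM3_TO_L = 1e-24


@dataclass(frozen=True)
class VesicleGeometry:
    """Outer radius and membrane thickness of a unilamellar vesicle, in nm."""

    radius: float
    thickness: float = 14.0

    def __post_init__(self) -> None:
        if not self.radius > self.thickness > 0:
            raise ValueError(
                f"need radius > thickness > 0, got radius={self.radius}, "
                f"thickness={self.thickness}"
            )


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the loading model.

    ``pdms_mass_fraction`` defaults to the PDMS share of a 0.9-4.8-0.9 kDa
    PMOXA-b-PDMS-b-PMOXA triblock (4.8/6.6).  ``feed_mass_ratio`` is grams
    of cargo offered per gram of polymer; ``cargo_concentration`` is the
    feed molarity seen by the aqueous core.
    """

    polymer_density: float = 0.97  # g/cm^3, bulk PDMS-like
    pdms_mass_fraction: float = 4.8 / 6.6
    feed_mass_ratio: float = 0.1  # g cargo per g polymer
    cargo_concentration: float = 1e-3  # mol/L
    cargo_molar_mass: float = 300.0  # g/mol

    def __post_init__(self) -> None:
        if self.polymer_density <= 0:
            raise ValueError("polymer_density must be > 0")
        if not 0.0 < self.pdms_mass_fraction <= 1.0:
            raise ValueError("pdms_mass_fraction must be in (0, 1]")
        if self.feed_mass_ratio < 0 or self.cargo_concentration < 0:
            raise ValueError("feed_mass_ratio and cargo_concentration must be >= 0")
        if self.cargo_molar_mass <= 0:
            raise ValueError("cargo_molar_mass must be > 0")


def feed_mass_ratio_from(cargo_umol: float, polymer_mg: float, molar_mass: float) -> float:
    """Feed mass ratio (g cargo / g polymer) from a typical formulation recipe,
    e.g. micromoles of cargo co-dissolved with milligrams of polymer."""
    if polymer_mg <= 0:
        raise ValueError("polymer_mg must be > 0")
    return cargo_umol * 1e-6 * molar_mass / (polymer_mg * 1e-3)


def membrane_mass(g: VesicleGeometry, p: ModelParams) -> float:
    """Total membrane (polymer) mass in grams: density x shell volume."""
    shell_nm3 = 4.0 / 3.0 * np.pi * (g.radius**3 - (g.radius - g.thickness) ** 3)
    return p.polymer_density * shell_nm3 * NM3_TO_CM3


def pdms_mass(g: VesicleGeometry, p: ModelParams) -> float:
    """Mass of the hydrophobic PDMS block only (membrane mass x block fraction)."""
    return membrane_mass(g, p) * p.pdms_mass_fraction


def core_volume(g: VesicleGeometry) -> float:
    """Aqueous core volume in liters; 0 (with a warning) if r <= t."""
    inner = g.radius - g.thickness
    if inner <= 0:  # pragma: no cover - VesicleGeometry forbids this
        warnings.warn("radius <= thickness: no aqueous core", stacklevel=2)
        return 0.0
    return 4.0 / 3.0 * np.pi * inner**3 * NM3_TO_L


def membrane_cargo_mass(g: VesicleGeometry, p: ModelParams) -> float:
    """Expected cargo mass (g) under membrane loading: feed ratio x membrane mass."""
    return membrane_mass(g, p) * p.feed_mass_ratio


def core_cargo_mass(g: VesicleGeometry, p: ModelParams) -> float:
    """Expected cargo mass (g) under core loading: entrapped volume x feed molarity."""
    return core_volume(g) * p.cargo_concentration * p.cargo_molar_mass


def model_curves(
    r_min: float = 25.0,
    r_max: float = 300.0,
    n_points: int = 100,
    params: ModelParams | None = None,
    thickness: float = 14.0,
) -> pd.DataFrame:
    """Evaluate the model on a uniform radius grid (default 25-300 nm).

    Returns a table with columns ``radius_nm``, ``pdms_mass_g``,
    ``membrane_cargo_mass_g``, ``core_cargo_mass_g``.  The membrane-cargo
    column is exactly proportional to PDMS mass; the core-cargo column is
    exactly cubic in ``r - t``.
    """
    if not 0 < r_min < r_max:
        raise ValueError("need 0 < r_min < r_max")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if r_min <= thickness:
        raise ValueError("r_min must exceed the membrane thickness")
    if params is None:
        params = ModelParams()
    radii = np.linspace(r_min, r_max, n_points)
    rows = []
    for r in radii:
        g = VesicleGeometry(radius=float(r), thickness=thickness)
        rows.append(
            (
                r,
                pdms_mass(g, params),
                membrane_cargo_mass(g, params),
                core_cargo_mass(g, params),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["radius_nm", "pdms_mass_g", "membrane_cargo_mass_g", "core_cargo_mass_g"],
    )
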