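"""Analysis configuration: peak windows, preprocessing parameters, thresholds.

All tunable constants of the pipeline live here so that a single YAML
document reproduces a full analysis.  Defaults follow the published
processing chain for trapped-vesicle spectra: 95% blank subtraction,
asymmetric-least-squares (Whittaker) baseline removal, Savitzky-Golay
smoothing of order 1 with frame 7, batch normalization to the mean
carrier-peak intensity, and the 0.4 inter-factor RMSE decision line for
subpopulation detection.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field

import yaml

from .spectra import PeakWindow

logger = logging.getLogger("spartakit")

__all__ = ["AnalysisConfig", "load_config", "WINDOW_PRESETS"]

#: Quantification windows used throughout: carrier Si-C 708 cm^-1 band for
#: polymersomes, lipid CH2 twist 1295 cm^-1 band for liposomes, the printed
#: dialkyne cargo window, and drug windows covering the chloroquine 1375 cm^-1
#: band and the doxorubicin 1208/1242 cm^-1 doublet.
WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "polymer_si_c": (688.0, 728.0),
    "lipid_ch2": (1275.0, 1315.0),
    "dialkyne": (2184.0, 2235.0),
    "chloroquine": (1355.0, 1395.0),
    "doxorubicin": (1188.0, 1262.0),
}


def preset_window(name: str) -> PeakWindow:
    lo, hi = WINDOW_PRESETS[name]
    return PeakWindow(name, lo, hi)


@dataclass
class AnalysisConfig:
    """Every tunable parameter of the analysis pipeline."""

    # quantification windows
    carrier_window: PeakWindow = field(default_factory=lambda: preset_window("polymer_si_c"))
    cargo_window: PeakWindow = field(default_factory=lambda: preset_window("dialkyne"))

    # preprocessing
    background_fraction: float = 0.95
    baseline_lambda: float = 1e5
    baseline_p: float = 0.01
    baseline_niter: int = 10
    savgol_order: int = 1
    savgol_frame: int = 7
    trap_min_frac: float = 0.25
    trap_max_mult: float = 3.0

    # explicit stage switches; skipping a stage must be deliberate
    apply_response_correction: bool = True
    apply_trap_filter: bool = True
    apply_background: bool = True
    apply_baseline: bool = True
    apply_smoothing: bool = True
    apply_normalization: bool = True

    # loading-location classification thresholds
    r2_core: float = 0.3
    gradient_membrane: float = 0.5

    # subpopulation detection
    rmse_threshold: float = 0.4
    nnmf_max_iter: int = 500
    nnmf_tol: float = 1e-6

    # release analysis
    stability_cutoff: float = 0.8

    # master random seed; every stochastic operation derives a substream
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.baseline_lambda <= 0:
            raise ValueError("baseline_lambda must be > 0")
        if not 0.0 < self.baseline_p < 1.0:
            raise ValueError("baseline_p must be in (0, 1)")
        if self.baseline_niter < 1:
            raise ValueError("baseline_niter must be >= 1")
        if self.savgol_frame < 3 or self.savgol_frame % 2 == 0:
            raise ValueError("savgol_frame must be odd and >= 3")
        if self.savgol_order >= self.savgol_frame:
            raise ValueError("savgol_order must be < savgol_frame")
        if not 0.0 < self.trap_min_frac < 1.0:
            raise ValueError("trap_min_frac must be in (0, 1)")
        if self.trap_max_mult <= 1.0:
            raise ValueError("trap_max_mult must be > 1")
        for name in ("r2_core", "gradient_membrane", "rmse_threshold", "stability_cutoff"):
            v = getattr(self, name)
            if not (v == v and abs(v) < float("inf")):
                raise ValueError(f"{name} must be finite")


_WINDOW_KEYS = {"carrier_window", "cargo_window"}


def _parse_window(name: str, value) -> PeakWindow:
    if isinstance(value, str):
        if value not in WINDOW_PRESETS:
            raise ValueError(
                f"config key {name!r}: unknown window preset {value!r}; "
                f"choose one of {sorted(WINDOW_PRESETS)}"
            )
        return preset_window(value)
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return PeakWindow(name, float(value[0]), float(value[1]))
    raise ValueError(f"config key {name!r}: expected a preset name or a [lo, hi] pair")


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML key-value document.

    Missing keys take the documented defaults; unknown keys warn and are
    ignored; invalid values raise with the offending key name.  The
    effective configuration is echoed to the package logger.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path}: expected a key-value mapping")

    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            warnings.warn(f"unknown config key {key!r} ignored", stacklevel=2)
            continue
        if key in _WINDOW_KEYS:
            kwargs[key] = _parse_window(key, value)
        else:
            try:
                kwargs[key] = value
            except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
                raise ValueError(f"config key {key!r}: {exc}") from exc
    try:
        cfg = AnalysisConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration in {path}: {exc}") from exc
    logger.info("effective configuration: %s", cfg)
    return cfg
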