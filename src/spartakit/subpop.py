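"""Subpopulation detection by rank-2 non-negative matrix factorization.

The particle-by-wavenumber intensity matrix is factorized into two
nonnegative factor spectra (one carrier-like, one cargo-like) and two
nonnegative scores per particle.  Each particle is assigned to the
cluster of its higher-scoring factor.  The decision statistic for the
presence of a highly loaded subpopulation is the root-mean-square
difference between the two factor spectra restricted to the cargo band
window: when all particles share one composition the factors converge to
near-identical spectra (small RMSE), whereas a minority of highly loaded
particles pulls the second factor toward the cargo spectrum (large RMSE).

Scale convention: each (factor, score) pair is rescaled so that the mean
score over particles is 1, putting factor spectra on the scale of an
average per-particle contribution in normalized intensity units.  The
default decision line of 0.4 RMSE refers to this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .features import peak_area
from .spectra import PeakWindow, SpectrumSet

__all__ = [
    "NNMFResult",
    "nnmf_two_factor",
    "order_factors",
    "assign_clusters",
    "factor_rmse",
    "detect_subpopulations",
    "cluster_fraction",
    "cluster_peak_stats",
]

_EPS = 1e-12


@dataclass
class NNMFResult:
    """Rank-2 factorization of a particle batch.

    ``factor_spectra`` has shape (2, n_wavenumbers) with factor 1 the
    carrier-like component after :func:`order_factors`; ``scores`` has
    shape (n_particles, 2) with mean 1 per column.
    """

    factor_spectra: np.ndarray
    scores: np.ndarray
    labels: np.ndarray | None
    n_iter: int
    converged: bool
    reconstruction_error: float
    error_history: np.ndarray | None = None  # relative error after each update

    def __post_init__(self) -> None:
        if np.any(self.factor_spectra < 0) or np.any(self.scores < 0):
            raise ValueError("NNMF factors and scores must be nonnegative")


def _nndsvd_init(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic rank-2 initialization from the truncated SVD.

    Nonnegative double SVD: each singular pair contributes whichever of
    its (positive-part, positive-part) / (negative-part, negative-part)
    outer products carries more energy.  Zeros are replaced by the matrix
    mean so multiplicative updates cannot lock at exact zeros.
    """
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    w = np.zeros((x.shape[0], 2))
    h = np.zeros((2, x.shape[1]))
    # leading factor: the leading singular vectors of a nonnegative matrix
    # are already sign-coherent (Perron-Frobenius)
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0] = np.sqrt(s[0]) * np.abs(vt[0])
    up, un = np.clip(u[:, 1], 0, None), np.clip(-u[:, 1], 0, None)
    vp, vn = np.clip(vt[1], 0, None), np.clip(-vt[1], 0, None)
    pos_energy = np.linalg.norm(up) * np.linalg.norm(vp)
    neg_energy = np.linalg.norm(un) * np.linalg.norm(vn)
    if pos_energy >= neg_energy and pos_energy > 0:
        w[:, 1] = np.sqrt(s[1] * pos_energy) * up / (np.linalg.norm(up) + _EPS)
        h[1] = np.sqrt(s[1] * pos_energy) * vp / (np.linalg.norm(vp) + _EPS)
    elif neg_energy > 0:
        w[:, 1] = np.sqrt(s[1] * neg_energy) * un / (np.linalg.norm(un) + _EPS)
        h[1] = np.sqrt(s[1] * neg_energy) * vn / (np.linalg.norm(vn) + _EPS)
    fill = x.mean()
    w[w <= 0] = fill
    h[h <= 0] = fill
    return w, h


def nnmf_two_factor(
    s: SpectrumSet, config: AnalysisConfig | None = None
) -> NNMFResult:
    """Rank-2 NNMF of the (clipped-nonnegative) intensity matrix.

    Frobenius-norm multiplicative updates from a deterministic SVD-based
    initialization; stops when the relative change of the reconstruction
    error drops below ``config.nnmf_tol`` or after ``config.nnmf_max_iter``
    iterations (then flagged ``converged=False``, not fatal).  Negative
    intensities (left over from background subtraction) are clipped to
    zero at entry — the only place in the pipeline where clipping occurs.
    """
    if config is None:
        config = AnalysisConfig()
    if s.n_particles < 4:
        raise ValueError("NNMF needs at least 4 particles")
    x = np.clip(s.intensities, 0.0, None)
    if not np.any(x > 0):
        raise ValueError("all-zero intensity matrix")
    w, h = _nndsvd_init(x)
    norm_x = np.linalg.norm(x)
    err_prev = np.linalg.norm(x - w @ h) / norm_x
    history = []
    converged = False
    it = 0
    for it in range(1, config.nnmf_max_iter + 1):
        h *= (w.T @ x) / (w.T @ w @ h + _EPS)
        w *= (x @ h.T) / (w @ (h @ h.T) + _EPS)
        err = np.linalg.norm(x - w @ h) / norm_x
        history.append(err)
        if abs(err_prev - err) < config.nnmf_tol * max(err_prev, _EPS):
            converged = True
            err_prev = err
            break
        err_prev = err
    # mean-score-1 convention: factor spectra become average per-particle
    # contributions in data-intensity units
    for k in range(2):
        mean_score = w[:, k].mean()
        if mean_score > 0:
            w[:, k] /= mean_score
            h[k] *= mean_score
    return NNMFResult(
        factor_spectra=h,
        scores=w,
        labels=None,
        n_iter=it,
        converged=converged,
        reconstruction_error=float(err_prev),
        error_history=np.asarray(history),
    )


def order_factors(
    result: NNMFResult, carrier_window: PeakWindow, cargo_window: PeakWindow, grid
) -> NNMFResult:
    """Order factors so factor 1 is carrier-like, factor 2 cargo-like.

    The factor with the lower cargo-to-carrier peak-area ratio becomes
    factor 1.  Equal ratios keep the input order.  Idempotent.
    """
    ratios = []
    for k in range(2):
        carrier_a = peak_area(result.factor_spectra[k], grid, carrier_window)
        cargo_a = peak_area(result.factor_spectra[k], grid, cargo_window)
        ratios.append(cargo_a / carrier_a if carrier_a > 0 else np.inf)
    if ratios[1] < ratios[0]:
        return replace(
            result,
            factor_spectra=result.factor_spectra[::-1].copy(),
            scores=result.scores[:, ::-1].copy(),
            labels=None,
        )
    return result


def assign_clusters(result: NNMFResult) -> np.ndarray:
    """Label each particle 1 or 2 by its higher score; ties go to cluster 1."""
    labels = np.where(result.scores[:, 1] > result.scores[:, 0], 2, 1)
    result.labels = labels
    return labels


def factor_rmse(result: NNMFResult, window: PeakWindow, grid) -> float:
    """RMS difference between the two factor spectra inside ``window``."""
    idx = grid.window_indices(window)
    diff = result.factor_spectra[0, idx] - result.factor_spectra[1, idx]
    return float(np.sqrt(np.mean(diff**2)))


def detect_subpopulations(rmse: float, threshold: float = 0.4) -> bool:
    """True iff the inter-factor RMSE reaches the decision line (inclusive)."""
    if rmse < 0:
        raise ValueError("rmse must be >= 0")
    return rmse >= threshold


def cluster_fraction(labels: np.ndarray) -> float:
    """Percentage of particles assigned to the (cargo-like) cluster 2."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    return 100.0 * float(np.mean(labels == 2))


def cluster_peak_stats(labels: np.ndarray, features: pd.DataFrame) -> pd.DataFrame:
    """Box-plot statistics of cargo peak positions per cluster.

    Median, quartiles and whiskers at the most extreme observations within
    1.5 IQR of the box.  Empty clusters are omitted with a warning.
    """
    import warnings

    labels = np.asarray(labels)
    if labels.shape[0] != len(features):
        raise ValueError("labels and feature table are misaligned")
    rows = []
    for cluster in (1, 2):
        pos = features.loc[labels == cluster, "cargo_position_cm1"].to_numpy()
        if pos.size == 0:
            warnings.warn(f"cluster {cluster} is empty; stats omitted", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(pos, [25, 50, 75])
        iqr = q3 - q1
        in_fence = pos[(pos >= q1 - 1.5 * iqr) & (pos <= q3 + 1.5 * iqr)]
        rows.append(
            {
                "cluster": cluster,
                "n": pos.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_lo": in_fence.min(),
                "whisker_hi": in_fence.max(),
            }
        )
    return pd.DataFrame(rows)
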