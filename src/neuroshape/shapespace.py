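"""PCA shape spaces over SH coefficients.

The SH coefficient table (one row per shape, 2178 columns at the
default degree) is reduced by PCA: eight components for cells, four
for nuclei.  Scores divided by their per-component standard deviation
are "shape modes" — a unit along a mode is one population standard
deviation.  Because PCA is linear the mapping is bidirectional: any
point in mode space maps back to SH coefficients and hence to a 3D
mesh, enabling reconstructions of hypothetical cells (the mean cell,
a cell two standard deviations out along one mode, an idealized mean
cell of one class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy import stats
from sklearn.decomposition import PCA

from .shparam import SHCoefficients, sh_reconstruct

__all__ = [
    "ShapeSpaceModel",
    "fit_shape_space",
    "to_shape_modes",
    "modes_to_coeffs",
    "modes_to_mesh",
    "bin_cells_by_mode",
    "correlate_modes_features",
]

BIN_CENTERS = (-2, -1, 0, 1, 2)


@dataclass
class ShapeSpaceModel:
    """A fitted linear shape space.

    ``loadings`` rows are orthonormal principal directions in
    coefficient space; ``component_sd`` are the score standard
    deviations over the fitted population (the z-scoring denominators);
    ``explained_variance_ratio`` is non-increasing.
    """

    mean_vector: np.ndarray
    loadings: np.ndarray
    component_sd: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    lmax: int

    def __post_init__(self) -> None:
        if np.any(self.component_sd <= 0):
            raise ValueError("component_sd must be positive")
        if np.any(np.diff(self.explained_variance_ratio) > 1e-12):
            raise ValueError("explained_variance_ratio must be non-increasing")


def fit_shape_space(
    coefficients: np.ndarray | pd.DataFrame,
    n_components: int = 8,
    lmax: int | None = None,
) -> ShapeSpaceModel:
    """Fit a PCA shape space on mean-centred SH coefficients.

    Component signs follow a fixed convention — the largest-magnitude
    loading entry of each component is positive — so mode semantics are
    reproducible across fits.  Rank-deficient input (fewer informative
    directions than requested components) is rejected.
    """
    x = np.asarray(coefficients, dtype=float)
    if x.ndim != 2:
        raise ValueError("coefficient table must be 2D")
    n, p = x.shape
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} shapes, got {n}")
    if lmax is None:
        lmax_f = np.sqrt(p / 2.0) - 1
        lmax = int(round(lmax_f))
        if 2 * (lmax + 1) ** 2 != p:
            raise ValueError("column count is not 2*(lmax+1)^2; pass lmax")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    if pca.explained_variance_[-1] < 1e-12:
        raise ValueError("input is rank-deficient below n_components")
    loadings = pca.components_.copy()
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    sd = scores.std(axis=0, ddof=1)
    return ShapeSpaceModel(
        mean_vector=pca.mean_.copy(),
        loadings=loadings,
        component_sd=sd,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        n_components=n_components,
        lmax=lmax,
    )


def to_shape_modes(
    coefficients: np.ndarray, model: ShapeSpaceModel
) -> np.ndarray:
    """Project coefficient vectors to z-scored shape-mode scores."""
    x = np.atleast_2d(np.asarray(coefficients, dtype=float))
    scores = (x - model.mean_vector) @ model.loadings.T
    return scores / model.component_sd


def modes_to_coeffs(modes: np.ndarray, model: ShapeSpaceModel) -> np.ndarray:
    """Map shape-mode points back to SH coefficient vectors."""
    m = np.atleast_2d(np.asarray(modes, dtype=float))
    return model.mean_vector + (m * model.component_sd) @ model.loadings


def modes_to_mesh(
    modes: np.ndarray, model: ShapeSpaceModel, n_theta: int = 65, n_phi: int = 128
) -> trimesh.Trimesh:
    """Reconstruct the 3D surface of one shape-mode point.

    The origin reconstructs the population mean shape; points along one
    mode visualize that mode's geometry at a chosen number of standard
    deviations.
    """
    vec = modes_to_coeffs(modes, model)[0]
    coeffs = SHCoefficients.from_vector(vec, model.lmax)
    return sh_reconstruct(coeffs, n_theta=n_theta, n_phi=n_phi)


def bin_cells_by_mode(scores: np.ndarray, mode_index: int = 0) -> np.ndarray:
    """Assign cells to mode bins centred at -2..2 standard deviations.

    Bins have half-width 0.5; the end bins are open-ended (<= -1.5 and
    >= 1.5).  A score exactly on a boundary goes to the bin with the
    larger centre.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))[:, mode_index]
    return np.clip(np.floor(s + 0.5), BIN_CENTERS[0], BIN_CENTERS[-1]).astype(int)


def correlate_modes_features(
    scores: np.ndarray | pd.DataFrame,
    features: pd.DataFrame,
    mode_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each shape mode against each feature.

    Returns a long table (mode, feature, r, p, n); zero-variance
    features yield missing correlations.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    if len(s) != len(features):
        raise ValueError("scores and features must have matching rows")
    if mode_names is None:
        mode_names = [f"mode{i + 1}" for i in range(s.shape[1])]
    rows = []
    for i, mname in enumerate(mode_names):
        for col in features.columns:
            f = np.asarray(features[col], dtype=float)
            ok = np.isfinite(f) & np.isfinite(s[:, i])
            n = int(ok.sum())
            if n < 3 or np.std(f[ok]) < 1e-15 or np.std(s[ok, i]) < 1e-15:
                rows.append({"mode": mname, "feature": col, "r": np.nan,
                             "p": np.nan, "n": n})
                continue
            r, p = stats.pearsonr(s[ok, i], f[ok])
            rows.append({"mode": mname, "feature": col, "r": float(r),
                         "p": float(p), "n": n})
    return pd.DataFrame(rows)
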