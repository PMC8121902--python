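"""Principal component morphospaces and functional contour surfaces.

Shape morphospace is a PCA of the Procrustes-aligned coordinates
(covariance PCA: centring only).  Functional morphospace is a PCA of the
z-scored character table, which is equivalent to a correlation-matrix
PCA of the raw characters.  Character contributions to an axis are the
squared loadings normalised to percentages; functional characters are
painted over shape morphospace by piecewise-linear interpolation on a
Delaunay triangulation of the score points (nodes outside the convex
hull of the data are left missing).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

__all__ = ["OrdinationResult", "pca", "pc_contributions", "contour_interpolate"]


@dataclasses.dataclass
class OrdinationResult:
    scores: pd.DataFrame          # rows × PC columns
    variance_fractions: np.ndarray
    loadings: pd.DataFrame        # variable × PC
    centered_means: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def pca(matrix: pd.DataFrame | np.ndarray) -> OrdinationResult:
    """Mean-centred PCA via singular value decomposition.

    The input is centred (shape coordinates) or arrives pre-z-scored
    (functional SFMD); no further scaling happens here.  Eigenvector
    signs are fixed by making each axis' largest-magnitude loading
    positive so plots are reproducible across runs.
    """
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        columns = list(matrix.columns)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(len(x))
        columns = [f"v{j}" for j in range(x.shape[1])]
    if np.isnan(x).any():
        raise ValueError("input contains missing cells")
    if x.shape[0] < 2:
        raise ValueError("need at least two rows")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if not np.any(s > 1e-12 * max(s[0], 1.0)):
        raise ValueError("matrix has rank 0 after centring")
    keep = s > 1e-12 * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # sign convention: largest-|loading| element of each axis positive
    for j in range(len(s)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    scores = u * s
    eig = s ** 2
    fractions = eig / eig.sum()
    pc_names = [f"PC{j + 1}" for j in range(len(s))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=index, columns=pc_names),
        variance_fractions=fractions,
        loadings=pd.DataFrame(vt.T, index=columns, columns=pc_names),
        centered_means=mean,
    )


def pc_contributions(result: OrdinationResult, axis: int) -> pd.Series:
    """Percentage contribution of each variable to one axis (sums to 100).

    ``axis`` is 0-based; contribution_j = 100 · loading_j² / Σ loading².
    """
    if not 0 <= axis < result.n_axes:
        raise IndexError(f"axis {axis} out of range 0..{result.n_axes - 1}")
    v = result.loadings.iloc[:, axis].to_numpy()
    return pd.Series(100.0 * v ** 2 / (v ** 2).sum(), index=result.loadings.index)


def contour_interpolate(
    scores: np.ndarray,
    values: np.ndarray,
    grid: int = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate a character over occupied morphospace.

    Returns ``(gx, gy, z)`` where ``z`` is a ``grid × grid`` array over
    the bounding box of the scores; nodes outside the convex hull are
    NaN.  All-collinear score points are an error (no triangulation).
    """
    pts = np.asarray(scores, dtype=float)
    vals = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    if len(pts) < 3:
        raise ValueError("need at least three points")
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-12) < 2:
        raise ValueError("all score points are collinear; cannot triangulate")
    gx = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid)
    gy = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid)
    mx, my = np.meshgrid(gx, gy)
    z = griddata(pts, vals, (mx, my), method="linear")
    return gx, gy, z
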