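"""Principal-curve fitting, projection, density and overlay profiles.

A principal curve is a smooth one-dimensional curve through the middle of a
point cloud; cells are ordered by the arc-length of their projection onto it.
The fit follows the classic alternating scheme: initialize at the first
principal component, then repeat (i) project points onto the current polyline,
(ii) smooth each coordinate against arc-length with a local-linear (lowess)
smoother, until the fitted points stop moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError, ValidationError

__all__ = [
    "PrincipalCurve",
    "CurveProjection",
    "fit_principal_curve",
    "project_with_overlays",
    "project_to_polyline",
]


@dataclass
class PrincipalCurve:
    vertices: np.ndarray  # ordered polyline vertices (m x d)
    arc_length: np.ndarray  # cumulative arc-length at each vertex, strictly increasing
    span: float
    iterations: int
    converged: bool
    arc_length_history: list[float] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class CurveProjection:
    positions: pd.Series  # per-cell arc-length position in [0, total]
    distances: pd.Series  # per-cell Euclidean distance to the curve
    density_grid: np.ndarray
    density: np.ndarray
    overlay_profiles: dict[str, pd.DataFrame]  # name -> (grid, mean)
    flipped: bool


def project_to_polyline(points: np.ndarray, vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-point projection of each point onto an ordered polyline.

    Returns (arc-length positions, distances)."""
    seg_start = vertices[:-1]
    seg_vec = vertices[1:] - seg_start
    seg_len2 = (seg_vec**2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(np.sqrt((seg_vec**2).sum(axis=1)))])
    diff = points[:, None, :] - seg_start[None, :, :]
    t = np.clip((diff * seg_vec[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = seg_start[None, :, :] + t[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    rows = np.arange(len(points))
    positions = cum[best] + t[rows, best] * np.sqrt(seg_len2[best])
    return positions, np.sqrt(d2[rows, best])


def _polyline_from_fit(lam: np.ndarray, fitted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(lam, kind="stable")
    verts = fitted[order]
    # drop consecutive duplicates so arc-length stays strictly increasing
    keep = np.concatenate([[True], (np.diff(verts, axis=0) ** 2).sum(axis=1) > 0])
    verts = verts[keep]
    arc = np.concatenate([[0.0], np.cumsum(np.sqrt((np.diff(verts, axis=0) ** 2).sum(axis=1)))])
    return verts, arc


def fit_principal_curve(
    points, span: float = 0.5, max_iter: int = 50, tol: float = 1e-4
) -> PrincipalCurve:
    """Fit a principal curve to an embedding (cells x dimensions >= 2).

    ``span`` is the lowess fraction; iteration stops when the mean squared
    displacement of the fitted points falls below ``tol``.
    """
    x = np.asarray(getattr(points, "scores", points), dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ConfigurationError("fit_principal_curve: need a 2-d embedding with >= 2 dimensions")
    if x.shape[0] < 10:
        raise ConfigurationError(f"fit_principal_curve: need >= 10 cells, got {x.shape[0]}")
    center = x.mean(axis=0)
    xc = x - center
    if np.allclose(xc, 0):
        raise ValidationError("fit_principal_curve: all points identical")
    # initialization: projection onto the first principal component
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    lam = xc @ vt[0]
    fitted = center + np.outer(lam, vt[0])
    lam = lam - lam.min()
    verts, arc = _polyline_from_fit(lam, fitted)
    history = [float(arc[-1])]
    converged = False
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        new_fitted = np.empty_like(fitted)
        for j in range(x.shape[1]):
            new_fitted[:, j] = lowess(
                x[:, j], lam, frac=span, it=1, return_sorted=False
            )
        displacement = float(((new_fitted - fitted) ** 2).sum(axis=1).mean())
        fitted = new_fitted
        verts, arc = _polyline_from_fit(lam, fitted)
        if arc[-1] <= 0:
            raise ValidationError("fit_principal_curve: curve collapsed to a point")
        history.append(float(arc[-1]))
        lam, _ = project_to_polyline(x, verts)
        if displacement < tol:
            converged = True
            break
    return PrincipalCurve(
        vertices=verts,
        arc_length=arc,
        span=span,
        iterations=iterations,
        converged=converged,
        arc_length_history=history,
    )


def project_with_overlays(
    curve: PrincipalCurve,
    points,
    overlays: dict | None = None,
    bandwidth=None,
    cell_ids=None,
    n_grid: int = 100,
    window_fraction: float = 0.10,
    orient_by: str | None = None,
) -> CurveProjection:
    """Project cells onto the curve; compute a Gaussian kernel density of the
    positions and a sliding-window mean profile for each overlay.

    Windows span ``window_fraction`` of the total arc-length. When
    ``orient_by`` names an overlay, positions are flipped so the curve starts
    at the lower-mean end of that overlay, making plots comparable across runs.
    """
    x = np.asarray(getattr(points, "scores", points), dtype=float)
    overlays = dict(overlays or {})
    for name, vals in overlays.items():
        vals = np.asarray(getattr(vals, "values", vals), dtype=float)
        if vals.shape[0] != x.shape[0]:
            raise ValidationError(f"project_with_overlays: overlay {name!r} length mismatch")
        overlays[name] = vals
    if orient_by is not None and orient_by not in overlays:
        raise ConfigurationError(f"project_with_overlays: no overlay named {orient_by!r}")
    positions, distances = project_to_polyline(x, curve.vertices)
    total = curve.total_length
    flipped = False
    if orient_by is not None:
        vals = overlays[orient_by]
        first = vals[positions <= total / 2]
        second = vals[positions > total / 2]
        if first.size and second.size and first.mean() > second.mean():
            positions = total - positions
            flipped = True
    index = pd.Index(cell_ids, name="cell_id") if cell_ids is not None else pd.RangeIndex(len(x))
    grid = np.linspace(0.0, total, n_grid)
    if np.std(positions) > 0:
        kde = stats.gaussian_kde(positions, bw_method=bandwidth or "silverman")
        density = kde(grid)
    else:
        density = np.full(n_grid, np.nan)
    half = window_fraction * total / 2.0
    profiles = {}
    for name, vals in overlays.items():
        means = np.full(n_grid, np.nan)
        for i, g in enumerate(grid):
            sel = np.abs(positions - g) <= half
            if sel.any():
                means[i] = vals[sel].mean()
        profiles[name] = pd.DataFrame({"position": grid, "mean": means})
    return CurveProjection(
        positions=pd.Series(positions, index=index, name="arc_length"),
        distances=pd.Series(distances, index=index, name="distance"),
        density_grid=grid,
        density=density,
        overlay_profiles=profiles,
        flipped=flipped,
    )
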