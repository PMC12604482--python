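"""Mouse-tumor attrition estimation from fragment clouds.

When treated tumors are too fragmented to segment as one mass, the original
tumor boundary is estimated by fitting a bivariate polynomial surface
z = P(x, y) to the fragment centroids.  The degree (2-10) is chosen
empirically by 5-fold cross-validated RMSE with a one-standard-error
tie-break toward the lower degree (in-sample RMSE alone would always pick the
largest degree).  Fragments are projected onto the fitted surface and
attrition is the percentage of the surface domain not covered by the
projected fragment footprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Delaunay, cKDTree

from .synthetic import n_poly_coeffs, polynomial_basis


@dataclass
class SurfaceFit:
    degree: int
    coefficients: np.ndarray
    rmse: float                      # full-fit residual RMSE, um
    selection_scores: dict           # degree -> (cv_rmse, cv_se)
    x_scale: tuple                   # (center, half-width) for x
    y_scale: tuple
    attrition_pct: Optional[float] = None
    occupancy_grid: Optional[np.ndarray] = None
    grid_cell_um: Optional[float] = None
    notes: list = field(default_factory=list)

    def predict(self, x, y):
        sx = (np.asarray(x) - self.x_scale[0]) / self.x_scale[1]
        sy = (np.asarray(y) - self.y_scale[0]) / self.y_scale[1]
        return polynomial_basis(sx, sy, self.degree) @ self.coefficients


def extract_centroids(labels: np.ndarray, spacing) -> pd.DataFrame:
    """Per-label centroid (um) and voxel count, ordered by label."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("empty label mask")
    coms = ndi.center_of_mass(np.ones_like(labels, dtype=np.uint8), labels, ids)
    sizes = ndi.sum_labels(np.ones_like(labels, dtype=np.uint8), labels, ids)
    axis_names = ("z", "y", "x")[-labels.ndim:]
    rows = []
    for lab, com, size in zip(ids, coms, sizes):
        entry = {"label": int(lab), "voxels": int(size)}
        for name, c, s in zip(axis_names, com, spacing):
            entry[name] = float(c * s)
        rows.append(entry)
    df = pd.DataFrame(rows)
    # equivalent-sphere radius of each fragment, for projection footprints
    vox_vol = float(np.prod(spacing))
    df["radius"] = (3.0 * df["voxels"] * vox_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
    return df


def _fit_one(sx, sy, z, degree):
    A = polynomial_basis(sx, sy, degree)
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design at degree {degree}: collinear (x, y) coordinates"
        )
    resid = z - A @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def fit_surface(centroids: pd.DataFrame, degrees: Sequence[int] = range(2, 11),
                n_folds: int = 5, seed: int = 0) -> SurfaceFit:
    """Least-squares polynomial surface with cross-validated degree selection.

    Coordinates are affinely rescaled to [-1, 1] for conditioning.  Candidate
    degrees whose coefficient count exceeds the sample size are dropped (and
    noted).  The selected degree is the smallest one whose CV RMSE is within
    one standard error (with a small absolute floor, so noiseless polynomial
    data resolves to the true minimal degree) of the best score.
    """
    x = centroids["x"].to_numpy(dtype=float)
    y = centroids["y"].to_numpy(dtype=float)
    z = centroids["z"].to_numpy(dtype=float)
    n = len(x)
    xc, xh = (x.max() + x.min()) / 2, max((x.max() - x.min()) / 2, 1e-12)
    yc, yh = (y.max() + y.min()) / 2, max((y.max() - y.min()) / 2, 1e-12)
    sx, sy = (x - xc) / xh, (y - yc) / yh

    notes = []
    usable = [d for d in degrees if n_poly_coeffs(d) <= n]
    if len(usable) < len(list(degrees)):
        notes.append(f"degrees truncated to {usable} for n={n}")
    if not usable:
        raise ValueError("too few centroids for any candidate degree")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, min(n_folds, n))
    scores = {}
    for d in usable:
        errs = []
        for hold in folds:
            train = np.setdiff1d(order, hold, assume_unique=False)
            if len(train) < n_poly_coeffs(d):
                errs = None
                break
            coef, _ = _fit_one(sx[train], sy[train], z[train], d)
            pred = polynomial_basis(sx[hold], sy[hold], d) @ coef
            errs.append(np.sqrt(np.mean((z[hold] - pred) ** 2)))
        if errs is None:
            notes.append(f"degree {d} skipped in CV (fold too small)")
            continue
        errs = np.asarray(errs)
        scores[d] = (float(errs.mean()), float(errs.std(ddof=1) / np.sqrt(len(errs))))
    best_d = min(scores, key=lambda d: scores[d][0])
    best_rmse, best_se = scores[best_d]
    z_scale = max(np.std(z), 1e-12)
    tol = best_rmse + max(best_se, 1e-9 * z_scale)
    chosen = min(d for d in scores if scores[d][0] <= tol)

    coef, rmse = _fit_one(sx, sy, z, chosen)
    return SurfaceFit(degree=chosen, coefficients=coef, rmse=rmse,
                      selection_scores=scores, x_scale=(xc, xh), y_scale=(yc, yh),
                      notes=notes)


def attrition_from_projection(fit: SurfaceFit, centroids: pd.DataFrame,
                              grid_cell: float = 10.0,
                              footprint: str = "disk") -> SurfaceFit:
    """Percent of the fitted surface domain not covered by projected fragments.

    The (x, y) domain is the convex hull of the fragment centroids,
    discretized into ``grid_cell`` um cells; a cell is occupied when any
    fragment footprint (a disk of that fragment's equivalent radius around its
    (x, y), or the bare centroid when footprint="point") covers the cell
    center.  Returns the fit with attrition fields populated.
    """
    if grid_cell <= 0:
        raise ValueError("grid_cell must be positive")
    if len(centroids) == 0:
        raise ValueError("empty centroid set")
    pts = centroids[["x", "y"]].to_numpy(dtype=float)
    radii = centroids["radius"].to_numpy(dtype=float) if "radius" in centroids else \
        np.zeros(len(centroids))
    hull = Delaunay(pts)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    gx = np.arange(x0, x1 + grid_cell, grid_cell) + grid_cell / 2
    gy = np.arange(y0, y1 + grid_cell, grid_cell) + grid_cell / 2
    cx, cy = np.meshgrid(gx, gy, indexing="ij")
    centers = np.column_stack([cx.ravel(), cy.ravel()])
    inside = hull.find_simplex(centers) >= 0
    occupied = np.zeros(len(centers), dtype=bool)
    if footprint == "disk":
        tree = cKDTree(centers)
        for p, r in zip(pts, radii):
            if r > 0:
                for j in tree.query_ball_point(p, r):
                    occupied[j] = True
            else:
                occupied[np.argmin(np.sum((centers - p) ** 2, axis=1))] = True
    elif footprint == "point":
        ix = np.floor((pts[:, 0] - x0) / grid_cell).astype(int)
        iy = np.floor((pts[:, 1] - y0) / grid_cell).astype(int)
        flat = ix * len(gy) + iy
        flat = flat[(ix >= 0) & (ix < len(gx)) & (iy >= 0) & (iy < len(gy))]
        occupied[flat] = True
    else:
        raise ValueError(f"unknown footprint {footprint!r}")
    n_total = int(inside.sum())
    n_unocc = int((inside & ~occupied).sum())
    fit.attrition_pct = 100.0 * n_unocc / n_total if n_total else None
    fit.occupancy_grid = (occupied & inside).reshape(len(gx), len(gy))
    fit.grid_cell_um = grid_cell
    fit.notes.append(f"projection footprint: {footprint}")
    return fit
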