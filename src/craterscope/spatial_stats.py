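"""Region-conditioned immune-cell statistics for the 3D niche pipeline.

Cells are assigned to exactly one region (crater / tumor / outside) from
exact Euclidean distance transforms; densities are reported per region
surface area in mm^2, with surface areas measured on a marching-cubes
isosurface of the solid (tumor with craters refilled) and triangles
attributed to the crater lining or the free tumor surface by proximity to
crater voxels.  Coverage is the crater share of the projected top surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage import measure

from ._morphology import distance_to
from .core_io import RegionMaskSet


@dataclass
class RegionStatsReport:
    crater_area_mm2: float
    tumor_area_mm2: float
    coverage_pct: Optional[float] = None
    density_crater: Optional[float] = None    # cells / mm^2
    density_tumor: Optional[float] = None
    affinity_ratio: Optional[float] = None    # density_crater / density_tumor
    crater_diameters_um: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)


def _voxel_index(coords_um, spacing, shape):
    idx = tuple(int(np.clip(round(c / s), 0, n - 1))
                for c, s, n in zip(coords_um, spacing, shape))
    return idx


def assign_cell_regions(cells: pd.DataFrame, masks: RegionMaskSet,
                        contact_dist: float = 0.0) -> pd.DataFrame:
    """Label each cell crater / tumor / outside and record region distances.

    A cell is "crater" if its centroid lies in, or within ``contact_dist`` um
    of, a crater voxel; otherwise "tumor" under the same rule; otherwise
    "outside".  The 5 um near/far convention of the study is exposed as the
    extra boolean column ``near_tumor_5um``.
    """
    cells = cells.copy()
    shape = masks.tumor.shape
    spacing = masks.spacing
    axis_names = ("z", "y", "x")[-len(shape):]
    have_craters = bool((masks.craters > 0).any())
    d_crater = distance_to(masks.craters > 0, spacing) if have_craters else None
    d_tumor = distance_to(masks.tumor, spacing) if masks.tumor.any() else None
    if d_tumor is None:
        raise ValueError("empty tumor mask")
    d_vessel = None
    if masks.vessels is not None and masks.vessels.any():
        d_vessel = distance_to(masks.vessels, spacing)

    regions, dc_list, dt_list, dv_list = [], [], [], []
    for _, row in cells.iterrows():
        idx = _voxel_index([row[a] for a in axis_names], spacing, shape)
        dc = float(d_crater[idx]) if d_crater is not None else np.inf
        dt = float(d_tumor[idx])
        dc_list.append(dc if np.isfinite(dc) else np.nan)
        dt_list.append(dt)
        dv_list.append(float(d_vessel[idx]) if d_vessel is not None else np.nan)
        if dc <= contact_dist:
            regions.append("crater")
        elif dt <= contact_dist:
            regions.append("tumor")
        else:
            regions.append("outside")
    cells["region"] = regions
    cells["dist_to_crater"] = dc_list
    cells["dist_to_tumor"] = dt_list
    cells["dist_to_vessel"] = dv_list
    cells["near_tumor_5um"] = np.asarray(dt_list) < 5.0
    cells.attrs["units"] = {"dist_to_crater": "um", "dist_to_tumor": "um",
                            "dist_to_vessel": "um"}
    return cells


def _triangle_areas(verts, faces):
    tri = verts[faces]
    a = tri[:, 1] - tri[:, 0]
    b = tri[:, 2] - tri[:, 0]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def surface_areas(masks: RegionMaskSet) -> tuple:
    """(crater, tumor) surface areas in mm^2 from a marching-cubes isosurface.

    The mesh is built on the tumor mask, whose surface includes the pocket
    linings; each triangle is attributed to the crater lining when its
    centroid lies within one voxel of a crater voxel, otherwise to the free
    tumor surface.
    """
    solid = masks.tumor
    spacing = masks.spacing
    verts, faces, _, _ = measure.marching_cubes(solid.astype(np.uint8), level=0.5,
                                                spacing=spacing)
    areas = _triangle_areas(verts, faces)
    if (masks.craters > 0).any():
        d_crater = distance_to(masks.craters > 0, spacing)
        centroids = verts[faces].mean(axis=1)
        coords = [centroids[:, k] / spacing[k] for k in range(solid.ndim)]
        d_at = ndi.map_coordinates(d_crater, coords, order=1, mode="nearest")
        near = d_at <= 0.99 * max(spacing)
        a_crater = float(areas[near].sum())
        a_tumor = float(areas[~near].sum())
    else:
        a_crater, a_tumor = 0.0, float(areas.sum())
    return a_crater / 1e6, a_tumor / 1e6


def region_densities(cells: pd.DataFrame, masks: RegionMaskSet) -> RegionStatsReport:
    """Cells per mm^2 of crater and tumor surface, and their affinity ratio."""
    if "region" not in cells.columns:
        raise ValueError("assign_cell_regions must run first")
    a_crater, a_tumor = surface_areas(masks)
    n_crater = int((cells["region"] == "crater").sum())
    n_tumor = int((cells["region"] == "tumor").sum())
    dens_c = n_crater / a_crater if a_crater > 0 else None
    dens_t = n_tumor / a_tumor if a_tumor > 0 else None
    if a_crater == 0 or a_tumor == 0:
        warnings.warn("zero-area region: density reported as null")
    affinity = None
    if dens_c is not None and dens_t is not None and dens_t > 0:
        affinity = dens_c / dens_t
    coverage, diam = coverage_and_sizes(masks)
    return RegionStatsReport(
        crater_area_mm2=a_crater, tumor_area_mm2=a_tumor, coverage_pct=coverage,
        density_crater=dens_c, density_tumor=dens_t, affinity_ratio=affinity,
        crater_diameters_um=diam,
        counts={"crater": n_crater, "tumor": n_tumor,
                "outside": int((cells["region"] == "outside").sum())},
    )


def coverage_and_sizes(masks: RegionMaskSet, projection_axis: int = 0) -> tuple:
    """Crater coverage (%) of the projected tumor surface and crater diameters.

    Coverage = crater footprint area / (tumor + crater footprint area) x 100,
    measured on the projection along the imaging axis; the denominator
    includes the crater area itself.  Per-crater diameter is the
    equivalent-circle diameter of its projected footprint, in um.
    """
    craters = masks.craters
    solid_fp = (masks.tumor | (craters > 0)).any(axis=projection_axis)
    if not solid_fp.any():
        return 0.0, []
    crater_fp = (craters > 0).any(axis=projection_axis)
    coverage = 100.0 * crater_fp.sum() / solid_fp.sum()
    plane_spacing = [s for k, s in enumerate(masks.spacing) if k != projection_axis]
    px_area = float(np.prod(plane_spacing))
    diameters = []
    for lab in masks.crater_labels:
        fp = (craters == lab).any(axis=projection_axis)
        area = fp.sum() * px_area
        diameters.append(float(2.0 * np.sqrt(area / np.pi)))
    return float(coverage), diameters


def distance_profile(points_um: np.ndarray, reference: np.ndarray, spacing,
                     bins: Sequence[float]) -> dict:
    """Histogram of object counts per distance bin from a reference mask.

    Distances beyond the last edge are counted in an explicit overflow bin.
    """
    reference = np.asarray(reference, dtype=bool)
    if not reference.any():
        raise ValueError("empty reference mask")
    d = distance_to(reference, spacing)
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    dists = np.array([
        d[_voxel_index(p, spacing, reference.shape)] for p in pts
    ]) if len(pts) else np.array([])
    edges = np.asarray(list(bins), dtype=float)
    counts, _ = np.histogram(dists, bins=edges)
    overflow = int((dists > edges[-1]).sum())
    return {"edges": edges.tolist(), "counts": counts.tolist(), "overflow": overflow,
            "distances_um": dists.tolist()}


def tumor_area_foldchange(area_t0: float, area_t1: float) -> float:
    """area_t1 / area_t0; areas must be strictly positive."""
    if area_t0 <= 0 or area_t1 <= 0:
        raise ValueError("areas must be positive")
    return area_t1 / area_t0


def group_test(sample_a, sample_b, kind: str = "mwu",
               alternative: str = "two-sided") -> dict:
    """Two-sided group comparison: Mann-Whitney U, unpaired or paired t.

    The Mann-Whitney branch uses exact enumeration for n <= 8 per group and
    the normal approximation with tie correction otherwise.  Degenerate
    inputs are handled explicitly: an all-tied MWU input returns p = 1 with a
    warning; a zero-variance t comparison with separated means reports the
    exact-separation limit (|t| = inf, p = 0) and flags it.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    flags = []
    if kind == "mwu":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn("all observations tied; Mann-Whitney p set to 1")
            return {"statistic": len(a) * len(b) / 2.0, "p": 1.0,
                    "method": "mwu-degenerate", "flags": ["all_tied"]}
        method = "exact" if max(len(a), len(b)) <= 8 and _no_ties(a, b) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
        return {"statistic": float(res.statistic), "p": float(res.pvalue),
                "method": f"mwu-{method}", "flags": flags}
    if kind == "t_unpaired":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return {"statistic": 0.0, "p": 1.0, "method": "t_unpaired",
                        "flags": ["zero_variance"]}
            sign = 1.0 if a.mean() > b.mean() else -1.0
            return {"statistic": sign * np.inf, "p": 0.0, "method": "t_unpaired",
                    "flags": ["exact_separation"]}
        res = stats.ttest_ind(a, b, alternative=alternative)
    elif kind == "t_paired":
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired test needs equal-length samples, n >= 2")
        diff = a - b
        if diff.std(ddof=1) == 0:
            if np.all(diff == 0):
                return {"statistic": 0.0, "p": 1.0, "method": "t_paired",
                        "flags": ["identical_pairs"]}
            sign = 1.0 if diff.mean() > 0 else -1.0
            return {"statistic": sign * np.inf, "p": 0.0, "method": "t_paired",
                    "flags": ["exact_separation"]}
        res = stats.ttest_rel(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "method": kind, "flags": flags}


def _no_ties(a, b) -> bool:
    allv = np.concatenate([a, b])
    return len(np.unique(allv)) == len(allv)
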