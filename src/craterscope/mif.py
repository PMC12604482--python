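"""Human multiplexed-immunofluorescence quantification.

Channel preprocessing (99th-percentile normalization, rolling-ball background
subtraction), per-cell feature extraction from a provided cell label mask,
tumor / margin / perivascular region logic, the rule-based crater classifier
(location on a stromal-melanocytic boundary, 20-50 um size, at most two
collagen fibers, low nuclear density, no vessels, no aSMA pericytes), and the
crater linear-density readout (count per cm of perivascular-melanocytic
boundary, PMB).

Cell segmentation itself is an input: the pipeline consumes a label mask.
Phenotyping replaces the study's manually corrected clustering with a
deterministic marker-gating table (an import path for external cluster labels
is provided).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from shapely.geometry import LineString, Point, Polygon
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize
from skimage.restoration import rolling_ball

from ._morphology import binary_closing_disk, binary_opening_disk, distance_to
from .core_io import CalibratedImage
from .spatial_stats import group_test


@dataclass
class MifParams:
    norm_percentile: float = 99.0
    bg_radius: int = 50                    # pixels
    crater_size_range: tuple = (20.0, 50.0)  # um, equivalent diameter
    max_collagen_fibers: int = 2
    boundary_smoothing: float = 5.0        # um, contour stabilization
    margin_width: float = 40.0             # um, outer border band
    min_hole_area: float = 2000.0          # um^2, perivascular hole filter
    cd31_mean_min: float = 10.0            # mean CD31 above this marks a vessel hole
    nuclear_density_quantile: float = 0.5  # crater nuclei < q * perivascular density
    boundary_tol: float = 15.0             # um, "on boundary" distance tolerance
    marker_positive_frac: float = 0.02     # channel-positive area fraction for overlap rules
    pmb_opening_radius: float = 25.0       # um; spans crater mouths (< max crater size)

    def __post_init__(self):
        if not (0 < self.norm_percentile <= 100):
            raise ValueError("norm_percentile must be in (0, 100]")
        lo, hi = self.crater_size_range
        if not (0 < lo < hi):
            raise ValueError("crater size range must be positive and ordered")


@dataclass
class CraterCandidate:
    polygon: Polygon
    equivalent_diameter: float            # um
    on_boundary: bool = False
    collagen_fiber_count: int = 0
    nuclear_density: float = 0.0          # nuclei / um^2
    vessel_overlap: bool = False
    asma_overlap: bool = False
    contained_cells: list = field(default_factory=list)
    source: str = "annotation"

    def __post_init__(self):
        if not self.polygon.is_valid:
            raise ValueError("candidate polygon is not simple")


@dataclass
class MifRegions:
    tumor: np.ndarray
    margin: np.ndarray
    perivascular: np.ndarray              # int labels
    spacing: tuple
    craters: Optional[np.ndarray] = None  # int labels, set after classification
    pmb_length_cm: float = 0.0
    outer_length_cm: float = 0.0
    pmb_contours: list = field(default_factory=list)   # LineStrings in um
    outer_contours: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_channels(img: CalibratedImage, membrane_channels: Sequence[str],
                        nuclear_channel: str,
                        percentile: float = 99.0) -> CalibratedImage:
    """Normalize each channel to its Nth percentile (clipped at 1) and sum
    the membrane channels into one composite; the nuclear channel is
    normalized separately.

    The percentile is the empirical order statistic (no interpolation), which
    makes the normalization exactly idempotent: renormalizing an already
    normalized channel divides by precisely 1.
    """
    comp = None
    for name in membrane_channels:
        ch = np.asarray(img.channel(name), dtype=float)
        p = np.percentile(ch, percentile, method="lower")
        if p <= 0:
            raise ValueError(f"channel {name!r} has {percentile}th percentile = 0")
        norm = np.clip(ch / p, 0, 1)
        comp = norm if comp is None else comp + norm
    nuc = np.asarray(img.channel(nuclear_channel), dtype=float)
    p = np.percentile(nuc, percentile, method="lower")
    if p <= 0:
        raise ValueError(f"channel {nuclear_channel!r} has {percentile}th percentile = 0")
    nuc = np.clip(nuc / p, 0, 1)
    return CalibratedImage(data=np.stack([comp, nuc]), spacing=img.spacing,
                           channels=["membrane_composite", "nucleus"])


def subtract_background(channel: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction; output is >= 0 and <= input."""
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("expected a single 2D channel")
    if radius >= min(channel.shape):
        raise ValueError("rolling-ball radius must be smaller than the image")
    bg = rolling_ball(channel, radius=radius)
    return np.clip(channel - bg, 0, None)


def extract_cell_features(img: CalibratedImage, cell_labels: np.ndarray) -> pd.DataFrame:
    """Mean intensity per cell per channel plus centroid in um."""
    cell_labels = np.asarray(cell_labels)
    ids = np.unique(cell_labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("empty cell label mask")
    sy, sx = img.spacing
    coms = ndi.center_of_mass(np.ones_like(cell_labels, dtype=np.uint8), cell_labels, ids)
    df = pd.DataFrame({"id": ids.astype(int),
                       "y": [c[0] * sy for c in coms],
                       "x": [c[1] * sx for c in coms]})
    for name in (img.channels or []):
        ch = np.asarray(img.channel(name), dtype=float)
        df[name] = ndi.mean(ch, labels=cell_labels, index=ids)
    df.attrs["units"] = {"y": "um", "x": "um"}
    return df


DEFAULT_GATES = [
    # (type, {channel: min_mean}), evaluated in priority order
    ("Treg", {"CD4": 50.0, "FOXP3": 50.0}),
    ("CD8 T", {"CD8a": 50.0}),
    ("DC", {"CD163": 50.0, "CD11c": 50.0}),
    ("CD4 T", {"CD4": 50.0}),
    ("tumor", {"SOX10": 50.0}),
]


def classify_cells(cells: pd.DataFrame, gates: Optional[list] = None,
                   labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Threshold gating on marker means, or passthrough of provided labels.

    Gates are evaluated in priority order (Treg before CD4 T, so a
    CD4+FOXP3+ cell is a Treg); a cell also matching a later gate is flagged
    in ``multi_gate``.  Cells matching nothing are "other".
    """
    cells = cells.copy()
    if labels is not None:
        if len(labels) != len(cells):
            raise ValueError("label list length mismatch")
        cells["cell_type"] = list(labels)
        cells["multi_gate"] = False
        return cells
    gates = gates if gates is not None else DEFAULT_GATES
    for _, rule in gates:
        for ch in rule:
            if ch not in cells.columns:
                raise KeyError(f"gating table references missing channel {ch!r}")
    types, multi = [], []
    for _, row in cells.iterrows():
        hits = [t for t, rule in gates
                if all(row[ch] >= thr for ch, thr in rule.items())]
        types.append(hits[0] if hits else "other")
        multi.append(len(hits) > 1)
    cells["cell_type"] = types
    cells["multi_gate"] = multi
    return cells


# ---------------------------------------------------------------------------
# region segmentation

def _contour_length_um(mask: np.ndarray, spacing, smoothing_um: float) -> tuple:
    """Smoothed sub-pixel contour(s) of a binary mask; total length in um."""
    sy, sx = spacing
    sig = (smoothing_um / sy, smoothing_um / sx)
    smooth = ndi.gaussian_filter(mask.astype(float), sigma=sig)
    contours = measure.find_contours(smooth, 0.5)
    lines, total = [], 0.0
    for c in contours:
        pts = np.column_stack([c[:, 0] * sy, c[:, 1] * sx])
        if len(pts) < 3:
            continue
        line = LineString(pts)
        lines.append(line)
        total += line.length
    return lines, total


def segment_tumor_regions(img: CalibratedImage, tumor_channel: str,
                          vessel_channel: str,
                          params: MifParams = None) -> MifRegions:
    """Otsu tumor mask + margin band + perivascular hole labeling + PMB length.

    Holes fully enclosed by the tumor are filtered by area and CD31 content to
    identify perivascular areas.  The PMB reference curve of each perivascular
    area is its boundary after a morphological opening at the maximum crater
    scale, so crater notches do not inflate the boundary length; contours are
    measured sub-pixel after Gaussian smoothing.
    """
    params = params or MifParams()
    sy, sx = img.spacing
    ch = np.asarray(img.channel(tumor_channel), dtype=float)
    if np.ptp(ch) == 0:
        raise ValueError("empty tumor: constant channel")
    sm = ndi.gaussian_filter(ch, sigma=(2.0 / sy, 2.0 / sx))
    tumor = sm > threshold_otsu(sm)
    tumor = binary_closing_disk(tumor, 3.0 / max(sy, sx))
    tumor = binary_opening_disk(tumor, 2.0 / max(sy, sx))
    if not tumor.any():
        raise ValueError("empty tumor segmentation")

    filled = ndi.binary_fill_holes(tumor)
    holes = filled & ~tumor
    hole_lbl, n_holes = ndi.label(holes)
    px_area = sy * sx
    vessel = np.asarray(img.channel(vessel_channel), dtype=float)
    peri = np.zeros_like(hole_lbl)
    next_id = 0
    contours_all, pmb_total = [], 0.0
    for lab in range(1, n_holes + 1):
        m = hole_lbl == lab
        area = m.sum() * px_area
        if area < params.min_hole_area:
            continue
        if float(vessel[m].mean()) < params.cd31_mean_min:
            continue
        next_id += 1
        peri[m] = next_id
        opened = binary_opening_disk(m, params.pmb_opening_radius / max(sy, sx))
        ref = opened if opened.any() else m
        lines, length = _contour_length_um(ref, (sy, sx), params.boundary_smoothing)
        contours_all.extend(lines)
        pmb_total += length

    d_out = distance_to(filled, (sy, sx))
    margin = (d_out > 0) & (d_out <= params.margin_width)
    outer_ref = binary_closing_disk(filled, params.pmb_opening_radius / max(sy, sx))
    outer_lines, outer_len = _contour_length_um(outer_ref, (sy, sx),
                                                params.boundary_smoothing)

    return MifRegions(tumor=tumor, margin=margin, perivascular=peri,
                      spacing=(sy, sx), pmb_length_cm=pmb_total / 1e4,
                      outer_length_cm=outer_len / 1e4, pmb_contours=contours_all,
                      outer_contours=outer_lines)


# ---------------------------------------------------------------------------
# crater candidates and the rule classifier

def _positive_mask(channel: np.ndarray) -> np.ndarray:
    ch = np.asarray(channel, dtype=float)
    if np.ptp(ch) == 0:
        return np.zeros(ch.shape, dtype=bool)
    thr = max(threshold_otsu(ch), ch.mean() + 3 * ch.std())
    return ch > thr


def _polygon_mask(poly: Polygon, shape, spacing) -> np.ndarray:
    sy, sx = spacing
    miny, minx, maxy, maxx = poly.bounds
    y0 = max(int(miny / sy) - 1, 0)
    y1 = min(int(maxy / sy) + 2, shape[0])
    x0 = max(int(minx / sx) - 1, 0)
    x1 = min(int(maxx / sx) + 2, shape[1])
    out = np.zeros(shape, dtype=bool)
    if y1 <= y0 or x1 <= x0:
        return out
    yy = (np.arange(y0, y1) + 0.0) * sy
    xx = (np.arange(x0, x1) + 0.0) * sx
    gy, gx = np.meshgrid(yy, xx, indexing="ij")
    inside = shapely.contains_xy(poly, gy, gx)
    out[y0:y1, x0:x1] = inside
    return out


def build_crater_candidates(polygons: Sequence[Polygon], img: CalibratedImage,
                            regions: MifRegions, nuclei_points: np.ndarray,
                            collagen_channel: str = "collagen",
                            vessel_channels: Sequence[str] = ("CD31",),
                            asma_channel: str = "aSMA",
                            params: MifParams = None) -> list:
    """Compute the rule features of each candidate polygon from the image.

    ``nuclei_points`` is an (n, 2) array of nuclear centroids in um (from the
    nuclear channel or the cell mask).  Polygons are in um coordinates.
    """
    params = params or MifParams()
    spacing = regions.spacing
    shape = regions.tumor.shape
    collagen_pos = _positive_mask(img.channel(collagen_channel))
    skel = skeletonize(collagen_pos)
    skel_lbl, _ = ndi.label(skel, structure=np.ones((3, 3), dtype=int))
    vessel_pos = np.zeros(shape, dtype=bool)
    for vc in vessel_channels:
        vessel_pos |= _positive_mask(img.channel(vc))
    asma_pos = _positive_mask(img.channel(asma_channel))
    boundaries = list(regions.pmb_contours) + list(regions.outer_contours)
    nuclei = np.atleast_2d(np.asarray(nuclei_points, dtype=float)) if len(nuclei_points) \
        else np.empty((0, 2))

    out = []
    for poly in polygons:
        area = poly.area
        diam = 2.0 * math.sqrt(area / math.pi)
        dist_b = min((b.distance(poly) for b in boundaries), default=np.inf)
        on_boundary = dist_b <= params.boundary_tol
        pmask = _polygon_mask(poly, shape, spacing)
        fibers = np.unique(skel_lbl[pmask & (skel_lbl > 0)])
        n_px = max(pmask.sum(), 1)
        vessel_overlap = (vessel_pos & pmask).sum() / n_px > params.marker_positive_frac
        asma_overlap = (asma_pos & pmask).sum() / n_px > params.marker_positive_frac
        if len(nuclei):
            inside = np.array([poly.contains(Point(p[0], p[1])) for p in nuclei])
            n_nuc = int(inside.sum())
        else:
            n_nuc = 0
        out.append(CraterCandidate(
            polygon=poly, equivalent_diameter=diam, on_boundary=bool(on_boundary),
            collagen_fiber_count=int(len(fibers)),
            nuclear_density=n_nuc / area if area > 0 else 0.0,
            vessel_overlap=bool(vessel_overlap), asma_overlap=bool(asma_overlap),
        ))
    return out


def perivascular_nuclear_density(regions: MifRegions, nuclei_points: np.ndarray) -> float:
    """Nuclei per um^2 of perivascular stroma (reference for the density rule)."""
    sy, sx = regions.spacing
    peri = regions.perivascular > 0
    area = peri.sum() * sy * sx
    if area == 0:
        return 0.0
    nuclei = np.atleast_2d(np.asarray(nuclei_points, dtype=float))
    if nuclei.size == 0:
        return 0.0
    iy = np.clip(np.round(nuclei[:, 0] / sy).astype(int), 0, peri.shape[0] - 1)
    ix = np.clip(np.round(nuclei[:, 1] / sx).astype(int), 0, peri.shape[1] - 1)
    return float(peri[iy, ix].sum()) / area


def classify_crater_candidates(candidates: Sequence[CraterCandidate],
                               params: MifParams = None,
                               perivascular_density: float = 0.0) -> tuple:
    """Apply the rule set; returns (accepted, rejections).

    accept iff on a stromal-melanocytic boundary AND equivalent diameter in
    the size range AND at most ``max_collagen_fibers`` fibers AND nuclear
    density below ``nuclear_density_quantile`` x the perivascular density AND
    no vessel (CD31/CD105) overlap AND no aSMA overlap.  ``rejections`` maps
    candidate index to the list of failed rules.
    """
    params = params or MifParams()
    lo, hi = params.crater_size_range
    nd_thr = params.nuclear_density_quantile * perivascular_density
    accepted, rejections = [], {}
    for i, c in enumerate(candidates):
        failed = []
        if not c.on_boundary:
            failed.append("on_boundary")
        if not (lo <= c.equivalent_diameter <= hi):
            failed.append("size")
        if c.collagen_fiber_count > params.max_collagen_fibers:
            failed.append("collagen_fibers")
        if perivascular_density > 0 and c.nuclear_density >= nd_thr:
            failed.append("nuclear_density")
        if c.vessel_overlap:
            failed.append("vessel_overlap")
        if c.asma_overlap:
            failed.append("asma_overlap")
        if failed:
            rejections[i] = failed
        else:
            accepted.append(c)
    return accepted, rejections


def rasterize_craters(accepted: Sequence[CraterCandidate], shape, spacing) -> np.ndarray:
    lbl = np.zeros(shape, dtype=np.int32)
    for i, c in enumerate(accepted, start=1):
        lbl[_polygon_mask(c.polygon, shape, spacing)] = i
    return lbl


# ---------------------------------------------------------------------------
# region assignment and readouts

def assign_cells_to_regions(cells: pd.DataFrame, regions: MifRegions) -> pd.DataFrame:
    """Priority crater > border > tumor > outside, sampled at the centroid.

    A cell overlapping the border but not a crater is a border cell; a tumor
    cell overlaps the tumor segmentation without overlapping craters or the
    border.
    """
    cells = cells.copy()
    sy, sx = regions.spacing
    craters = regions.craters if regions.craters is not None else \
        np.zeros_like(regions.tumor, dtype=np.int32)
    out = []
    for _, row in cells.iterrows():
        iy = int(np.clip(round(row["y"] / sy), 0, regions.tumor.shape[0] - 1))
        ix = int(np.clip(round(row["x"] / sx), 0, regions.tumor.shape[1] - 1))
        if craters[iy, ix] > 0:
            out.append("crater")
        elif regions.margin[iy, ix]:
            out.append("border")
        elif regions.tumor[iy, ix]:
            out.append("tumor")
        else:
            out.append("outside")
    cells["region"] = out
    return cells


def region_type_densities(cells: pd.DataFrame, regions: MifRegions) -> pd.DataFrame:
    """Cells per mm^2 for each (region, cell type)."""
    sy, sx = regions.spacing
    px_mm2 = sy * sx / 1e6
    craters = regions.craters if regions.craters is not None else \
        np.zeros_like(regions.tumor, dtype=np.int32)
    areas = {
        "crater": (craters > 0).sum() * px_mm2,
        "border": regions.margin.sum() * px_mm2,
        "tumor": (regions.tumor & ~(craters > 0) & ~regions.margin).sum() * px_mm2,
    }
    rows = []
    for (region, ctype), grp in cells.groupby(["region", "cell_type"]):
        if region not in areas or areas[region] == 0:
            continue
        rows.append({"region": region, "cell_type": ctype, "n": len(grp),
                     "area_mm2": areas[region],
                     "density_per_mm2": len(grp) / areas[region]})
    df = pd.DataFrame(rows, columns=["region", "cell_type", "n", "area_mm2",
                                     "density_per_mm2"])
    df.attrs["units"] = {"area_mm2": "mm^2", "density_per_mm2": "cells/mm^2"}
    return df


def crater_linear_density(n_craters: int, pmb_length_cm: float,
                          excluded_length_cm: float = 0.0) -> float:
    """Craters per linear cm of boundary; fibrotic segments may be excluded."""
    usable = pmb_length_cm - excluded_length_cm
    if usable <= 0:
        raise ValueError("zero-length boundary")
    return n_craters / usable


def marker_region_comparison(cells: pd.DataFrame, marker: str,
                             in_crater: Sequence[bool]) -> dict:
    """Marker intensity in-crater vs elsewhere, with a two-sided MWU test."""
    in_crater = np.asarray(in_crater, dtype=bool)
    inside = cells.loc[in_crater, marker].to_numpy(dtype=float)
    outside = cells.loc[~in_crater, marker].to_numpy(dtype=float)
    if len(inside) < 2 or len(outside) < 2:
        warnings.warn("empty or singleton group; reporting null comparison")
        return {"in": inside.tolist(), "out": outside.tolist(),
                "statistic": None, "p": None}
    res = group_test(inside, outside, kind="mwu")
    return {"in": inside.tolist(), "out": outside.tolist(),
            "statistic": res["statistic"], "p": res["p"]}
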