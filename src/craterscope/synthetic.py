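"""Synthetic microscopy phantoms with analytic ground-truth manifests.

Every generator is a pure function of its parameters and a seed: two calls
with the same arguments produce bit-identical output.  Manifest quantities are
computed analytically or by direct counting on the planted geometry, never by
the analysis code under test.

The phantoms emulate the imaging regimes of the niche-quantification study:

* 3D zebrafish melanoma stacks — a tumor slab whose upper surface carries
  hemispherical pockets (the CRATER niches, ~50 um diameter in fish), bright
  spherical CD8-like cells with configurable region affinity, and tubular
  vessels;
* RNAscope-style clustered foci point clouds with uniform noise;
* fragmented mouse-tumor blob clouds sampled from a known polynomial surface
  with a planted unoccupied (attrition) fraction;
* paired annotator instance masks with controlled Jaccard overlap;
* 2D multiplexed-immunofluorescence fields with perivascular holes, boundary
  crater notches (20-50 um, the human size rule) and class-coded cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import CalibratedImage, RegionMaskSet


@dataclass
class PhantomSpec:
    """Parameters of the 3D tumor phantom.

    Defaults emulate the reported fish niches: pocket diameters centred on
    ~50 um, pocket depth half the diameter (hemispherical caps), T-cell-scale
    bright cells (10 um diameter).
    """

    shape: tuple = (64, 192, 192)           # (z, y, x) voxels
    spacing: tuple = (1.0, 1.0, 1.0)        # um per voxel
    pocket_count: int = 8
    pocket_diameter_mean: float = 50.0      # um
    pocket_diameter_sd: float = 8.0
    pocket_depth_ratio: float = 0.5         # depth = ratio * diameter
    cell_counts: dict = field(default_factory=lambda: {"crater": 40, "surface": 40, "embedded": 10})
    cell_radius: float = 5.0                # um
    vessel_count: int = 1
    vessel_radius: float = 6.0              # um
    background: float = 10.0
    noise_sd: float = 2.0
    tumor_intensity: float = 100.0
    cell_intensity: float = 100.0
    slab_fraction: float = 0.6              # tumor fills z < slab_fraction * nz
    density_ratio: Optional[float] = None   # crater:tumor planted density ratio
    base_density: float = 0.002             # cells per um^2 of tumor surface
    seed: int = 0


@dataclass
class TruthManifest:
    """Ground truth of a phantom, computed from the planted geometry."""

    pockets: list = field(default_factory=list)
    coverage_pct: Optional[float] = None
    cells: Optional[pd.DataFrame] = None
    vessels: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def _add_noise(rng, arr, background, sd):
    return arr + background + rng.normal(0.0, sd, size=arr.shape)


def _carve_pockets(rng, spec: PhantomSpec):
    """Place non-overlapping hemispherical pockets on the slab top face."""
    nz, ny, nx = spec.shape
    z_top = int(round(spec.slab_fraction * nz))       # tumor occupies z < z_top
    sy, sx = spec.spacing[1], spec.spacing[2]
    pockets = []
    attempts = 0
    while len(pockets) < spec.pocket_count:
        attempts += 1
        if attempts > 200 * max(spec.pocket_count, 1):
            raise RuntimeError("could not place non-overlapping pockets; reduce count/diameter")
        if spec.pocket_diameter_sd > 0:
            d = rng.normal(spec.pocket_diameter_mean, spec.pocket_diameter_sd)
        else:
            d = spec.pocket_diameter_mean
        d = float(np.clip(d, 8.0, min(ny * sy, nx * sx) / 2))
        r = d / 2.0
        margin_y, margin_x = r / sy + 4, r / sx + 4
        cy = rng.uniform(margin_y, ny - margin_y)
        cx = rng.uniform(margin_x, nx - margin_x)
        ok = all(
            math.hypot((cy - p["cy"]) * sy, (cx - p["cx"]) * sx) > r + p["radius_um"] + 4
            for p in pockets
        )
        if ok:
            pockets.append({"cy": cy, "cx": cx, "radius_um": r, "diameter_um": d})
    return z_top, pockets


def make_tumor_phantom(spec: PhantomSpec):
    """Build a 3-channel 3D stack (tumor, cells, vessels) plus ground truth.

    Returns ``(image, masks, manifest)`` where ``masks`` holds the planted
    tumor and crater-volume masks (truth, independent of any segmentation).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    z_top, pockets = _carve_pockets(rng, spec)

    zz = np.arange(nz)[:, None, None] * sz
    yy = np.arange(ny)[None, :, None] * sy
    xx = np.arange(nx)[None, None, :] * sx

    tumor = np.zeros(spec.shape, dtype=bool)
    tumor[:z_top] = True
    crater_labels = np.zeros(spec.shape, dtype=np.int32)
    z_top_um = z_top * sz

    for i, p in enumerate(pockets, start=1):
        r = p["radius_um"]
        depth = spec.pocket_depth_ratio * p["diameter_um"]
        # hemispherical cap centred on the top face, carved downward to `depth`
        d2 = (zz - z_top_um) ** 2 + (yy - p["cy"] * sy) ** 2 + (xx - p["cx"] * sx) ** 2
        carve = (d2 <= r**2) & (zz < z_top_um) & (zz >= z_top_um - depth)
        carved = carve & tumor
        tumor[carved] = False
        crater_labels[carved] = i
        p["voxels"] = int(carved.sum())
        zc, yc, xc = np.nonzero(carved)
        if len(zc):
            p["centroid_um"] = (float(zc.mean() * sz), float(yc.mean() * sy), float(xc.mean() * sx))

    # coverage by direct voxel counting on the carved mask footprint
    carved_fp = (crater_labels > 0).any(axis=0)
    coverage_pct = 100.0 * carved_fp.sum() / (ny * nx)

    # analytic surface areas (hemisphere lining 2*pi*r^2; flat top minus disks)
    a_crater_um2 = sum(2 * math.pi * p["radius_um"] ** 2 for p in pockets)
    a_tumor_um2 = ny * sy * nx * sx - sum(math.pi * p["radius_um"] ** 2 for p in pockets)

    counts = dict(spec.cell_counts)
    if spec.density_ratio is not None:
        # surface-density phantom: only surface-contact cells, counts set from
        # the analytic areas so the planted density ratio is exact
        counts["surface"] = max(int(round(spec.base_density * a_tumor_um2)), 4)
        counts["crater"] = max(int(round(spec.density_ratio * spec.base_density * a_crater_um2)), 1)
        counts["embedded"] = 0

    cells = []
    # crater cells: centroid inside the carved volume
    carved_idx = np.argwhere(crater_labels > 0)
    n_crater = counts.get("crater", 0) if len(carved_idx) else 0
    if n_crater:
        pick = rng.choice(len(carved_idx), size=n_crater, replace=True)
        for j in pick:
            z, y, x = carved_idx[j]
            cells.append({"z": z * sz, "y": y * sy, "x": x * sx, "region": "crater"})
    # surface cells: just beneath the flat top, away from pocket rims
    n_surface = counts.get("surface", 0)
    placed = 0
    guard = 0
    keepout = carved_fp.copy()
    for p in pockets:  # widen keep-out by the cell radius so labels stay unambiguous
        r_px = (p["radius_um"] + 2 * spec.cell_radius) / sy
        yg, xg = np.ogrid[:ny, :nx]
        keepout |= ((yg - p["cy"]) ** 2 + (xg - p["cx"]) ** 2) <= r_px**2
    free = np.argwhere(~keepout)
    if n_surface and len(free):
        pick = rng.choice(len(free), size=n_surface, replace=True)
        for j in pick:
            y, x = free[j]
            cells.append({"z": (z_top - 1) * sz, "y": y * sy, "x": x * sx, "region": "surface"})
    del placed, guard
    # embedded cells: well below the surface, resampled out of carved pockets
    n_embed = counts.get("embedded", 0)
    z_max_embed = max(int(z_top - 2 * spec.cell_radius / sz), 1)
    placed_embed = 0
    while placed_embed < n_embed:
        z = rng.integers(0, z_max_embed)
        y, x = rng.integers(0, ny), rng.integers(0, nx)
        if not tumor[z, y, x]:
            continue
        cells.append({"z": z * sz, "y": y * sy, "x": x * sx, "region": "embedded"})
        placed_embed += 1
    cell_df = pd.DataFrame(cells, columns=["z", "y", "x", "region"])
    cell_df.insert(0, "id", np.arange(len(cell_df)))

    vessels = []
    for _ in range(spec.vessel_count):
        vz = (z_top + 3) * sz
        vy = rng.uniform(0.2, 0.8) * ny * sy
        vessels.append({"axis": "x", "z_um": vz, "y_um": vy, "radius_um": spec.vessel_radius})

    # render channels
    tumor_ch = np.where(tumor, spec.tumor_intensity, 0.0)
    cell_ch = np.zeros(spec.shape, dtype=float)
    sig = spec.cell_radius / 2.0
    for c in cells:
        # gaussian blob, rendered in a local window for speed
        wz = int(3 * sig / sz) + 1
        wy = int(3 * sig / sy) + 1
        wx = int(3 * sig / sx) + 1
        iz, iy, ix = int(round(c["z"] / sz)), int(round(c["y"] / sy)), int(round(c["x"] / sx))
        z0, z1 = max(iz - wz, 0), min(iz + wz + 1, nz)
        y0, y1 = max(iy - wy, 0), min(iy + wy + 1, ny)
        x0, x1 = max(ix - wx, 0), min(ix + wx + 1, nx)
        lz = (np.arange(z0, z1) * sz - c["z"])[:, None, None]
        ly = (np.arange(y0, y1) * sy - c["y"])[None, :, None]
        lx = (np.arange(x0, x1) * sx - c["x"])[None, None, :]
        cell_ch[z0:z1, y0:y1, x0:x1] += spec.cell_intensity * np.exp(
            -(lz**2 + ly**2 + lx**2) / (2 * sig**2)
        )
    vessel_ch = np.zeros(spec.shape, dtype=float)
    for v in vessels:
        d2 = (zz - v["z_um"]) ** 2 + (yy - v["y_um"]) ** 2
        vessel_ch += np.where(np.broadcast_to(d2, spec.shape) <= v["radius_um"] ** 2, 80.0, 0.0)

    data = np.stack([
        _add_noise(rng, tumor_ch, spec.background, spec.noise_sd),
        _add_noise(rng, cell_ch, spec.background, spec.noise_sd),
        _add_noise(rng, vessel_ch, spec.background, spec.noise_sd),
    ])
    img = CalibratedImage(data=data, spacing=spec.spacing, channels=["tumor", "cells", "vessels"])
    masks = RegionMaskSet(tumor=tumor, craters=crater_labels, spacing=spec.spacing)
    manifest = TruthManifest(
        pockets=pockets,
        coverage_pct=float(coverage_pct),
        cells=cell_df,
        vessels=vessels,
        extras={
            "z_top": z_top,
            "crater_surface_um2": a_crater_um2,
            "tumor_surface_um2": a_tumor_um2,
            "density_ratio": spec.density_ratio,
        },
    )
    return img, masks, manifest


# ---------------------------------------------------------------------------
# RNAscope-like foci clouds

def make_foci_phantom(n_clusters: int, cluster_sigma: float, foci_per_cluster: int,
                      n_noise: int, extent: Sequence[float] = (400.0, 400.0),
                      seed: int = 0, min_separation: float = 100.0):
    """Clustered 2D foci (one cluster per planted cell) plus uniform noise.

    Coordinates in um.  Cluster centres are at least ``min_separation`` apart
    and at least 4 sigma plus 10 um from the field edge.
    """
    rng = np.random.default_rng(seed)
    ey, ex = extent
    centers = []
    attempts = 0
    margin = 4 * cluster_sigma + 10.0
    while len(centers) < n_clusters:
        attempts += 1
        if attempts > 5000:
            raise RuntimeError("cannot place cluster centres at requested separation")
        c = (rng.uniform(margin, ey - margin), rng.uniform(margin, ex - margin))
        if all(math.hypot(c[0] - o[0], c[1] - o[1]) >= min_separation for o in centers):
            centers.append(c)
    rows = []
    for k, (cy, cx) in enumerate(centers):
        pts = rng.normal([cy, cx], cluster_sigma, size=(foci_per_cluster, 2))
        pts = np.clip(pts, 0, [ey - 1e-6, ex - 1e-6])
        for y, x in pts:
            rows.append({"y": y, "x": x, "cluster": k})
    for _ in range(n_noise):
        rows.append({"y": rng.uniform(0, ey), "x": rng.uniform(0, ex), "cluster": -1})
    df = pd.DataFrame(rows, columns=["y", "x", "cluster"])
    manifest = TruthManifest(extras={"centers": centers, "extent": tuple(extent),
                                     "cluster_sigma": cluster_sigma})
    return df, manifest


# ---------------------------------------------------------------------------
# polynomial-surface fragment clouds (mouse attrition)

def polynomial_basis(x, y, degree: int) -> np.ndarray:
    """Design matrix of bivariate monomials x^i * y^j with i + j <= degree."""
    cols = [np.power(x, i) * np.power(y, j)
            for d in range(degree + 1) for i in range(d + 1) for j in [d - i]]
    return np.stack(cols, axis=-1)


def n_poly_coeffs(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


def make_surface_phantom(degree: int, coeffs: Optional[np.ndarray] = None,
                         n_blobs: int = 8000, occupied_fraction: float = 0.6,
                         noise_sd: float = 1.0, seed: int = 0,
                         domain: float = 1000.0, blob_radius: float = 12.0):
    """Fragment centroids on z = P(x, y) with a planted unoccupied disk.

    The (x, y) domain is [0, domain]^2 um; the polynomial is evaluated in
    coordinates scaled to [-1, 1].  The unoccupied region is a disk of area
    (1 - occupied_fraction) * domain^2 placed strictly inside the domain, so
    the convex hull of the occupied points still spans the field.  Fragments
    lie wholly in the occupied region: centres keep ``blob_radius`` clear of
    the ablated boundary so footprints do not cross it.
    """
    if not (2 <= degree <= 10):
        raise ValueError("degree must be in [2, 10]")
    if not (0.0 <= occupied_fraction <= 1.0):
        raise ValueError("occupied_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_coef = n_poly_coeffs(degree)
    if coeffs is None:
        coeffs = rng.normal(0.0, 5.0, size=n_coef)
        # force the top-order terms to carry signal well above the noise floor
        top = slice(n_coef - (degree + 1), n_coef)
        mag = rng.uniform(3.0, 8.0, size=degree + 1)
        coeffs[top] = np.sign(coeffs[top]) * mag
    coeffs = np.asarray(coeffs, dtype=float)
    if len(coeffs) != n_coef:
        raise ValueError(f"degree {degree} needs {n_coef} coefficients, got {len(coeffs)}")
    degenerate = bool(np.allclose(coeffs[n_coef - (degree + 1):], 0.0))

    hole_frac = 1.0 - occupied_fraction
    hole_r = domain * math.sqrt(hole_frac / math.pi) if hole_frac > 0 else 0.0
    if hole_r > 0:
        lo, hi = hole_r + 0.02 * domain, domain - hole_r - 0.02 * domain
        if lo >= hi:
            raise ValueError("occupied_fraction too small for an interior unoccupied disk")
        hole_c = (rng.uniform(lo, hi), rng.uniform(lo, hi))
    else:
        hole_c = None

    pts = []
    while len(pts) < n_blobs:
        cand = rng.uniform(0.0, domain, size=(n_blobs, 2))
        if hole_c is not None:
            clearance = hole_r + blob_radius
            keep = (cand[:, 0] - hole_c[0]) ** 2 + (cand[:, 1] - hole_c[1]) ** 2 > clearance**2
            cand = cand[keep]
        pts.extend(map(tuple, cand))
    pts = np.asarray(pts[:n_blobs])
    xs, ys = pts[:, 0], pts[:, 1]
    sx_, sy_ = 2 * xs / domain - 1, 2 * ys / domain - 1
    z = polynomial_basis(sx_, sy_, degree) @ coeffs
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=z.shape)
    radii = np.full(n_blobs, blob_radius)
    df = pd.DataFrame({"x": xs, "y": ys, "z": z, "radius": radii})
    manifest = TruthManifest(extras={
        "degree": degree, "coeffs": coeffs, "true_attrition_pct": 100.0 * hole_frac,
        "hole_center": hole_c, "hole_radius": hole_r, "domain": domain,
        "degenerate": degenerate, "noise_sd": noise_sd,
    })
    return df, manifest


# ---------------------------------------------------------------------------
# paired annotator instance masks with planted Jaccard overlap

def make_annotator_masks(planted_ji: Sequence[float], extra_a: int = 0, extra_b: int = 0,
                         seed: int = 0, obj_w: int = 60, obj_h: int = 30,
                         ji_threshold: float = 0.4, shape: Optional[tuple] = None):
    """Two instance masks whose object pairs overlap at the requested JI.

    Each planted pair is a pair of ``obj_h x obj_w`` rectangles shifted
    horizontally so that their Jaccard index matches the request to within the
    integer-pixel granularity (tolerance recorded in the manifest).  Extras are
    disjoint rectangles present in only one mask.
    """
    rng = np.random.default_rng(seed)
    n_pairs = len(planted_ji)
    n_slots = n_pairs + extra_a + extra_b
    cell = 2 * obj_w + 20
    per_row = max(int(math.ceil(math.sqrt(n_slots))), 1)
    rows = int(math.ceil(n_slots / per_row)) if n_slots else 1
    if shape is None:
        shape = (rows * (obj_h + 20) + 20, per_row * cell + 20)
    mask_a = np.zeros(shape, dtype=np.int32)
    mask_b = np.zeros(shape, dtype=np.int32)
    achieved = []
    slot = 0

    def slot_origin(s):
        r, c = divmod(s, per_row)
        return 10 + r * (obj_h + 20), 10 + c * cell

    for ji in planted_ji:
        if not (0.0 <= ji <= 1.0):
            raise ValueError(f"planted JI {ji} outside [0, 1]")
        o = int(round(2 * obj_w * ji / (1 + ji)))
        got = o / (2 * obj_w - o) if o else 0.0
        if abs(got - ji) > 0.02:
            raise ValueError(f"JI {ji} not achievable within 0.02 for {obj_w}px objects")
        y0, x0 = slot_origin(slot)
        slot += 1
        la, lb = slot, slot  # same running id per pair keeps masks readable
        mask_a[y0:y0 + obj_h, x0:x0 + obj_w] = la
        xb = x0 + (obj_w - o)
        mask_b[y0:y0 + obj_h, xb:xb + obj_w] = lb
        achieved.append(got)
    for _ in range(extra_a):
        y0, x0 = slot_origin(slot)
        slot += 1
        mask_a[y0:y0 + obj_h, x0:x0 + obj_w] = slot
    for _ in range(extra_b):
        y0, x0 = slot_origin(slot)
        slot += 1
        mask_b[y0:y0 + obj_h, x0:x0 + obj_w] = slot
    del rng
    tp = sum(1 for j in achieved if j > ji_threshold)
    unmatched = n_pairs - tp
    manifest = TruthManifest(extras={
        "achieved_ji": achieved, "ji_tolerance": 0.02, "threshold": ji_threshold,
        "tp": tp, "fp": unmatched + extra_a, "fn": unmatched + extra_b,
    })
    return mask_a, mask_b, manifest


# ---------------------------------------------------------------------------
# 2D multiplexed-immunofluorescence phantom

MIF_CHANNELS = ["S100", "CD31", "aSMA", "collagen", "nucleus",
                "CD8a", "CD4", "CD163", "CD11c", "FOXP3", "SOX10"]


@dataclass
class MifLayout:
    shape: tuple = (600, 600)          # pixels
    pixel_um: float = 2.0
    tumor_radius_um: float = 480.0
    hole_radius_um: float = 60.0
    n_holes: int = 3
    hole_orbit_um: float = 260.0       # distance of hole centres from tumor centre
    craters_per_hole: int = 2
    crater_diam_range: tuple = (26.0, 44.0)   # inside the 20-50 um rule
    stroma_nuclei_density: float = 0.004      # nuclei per um^2 in perivascular stroma
    cells_per_region: dict = field(default_factory=lambda: {
        ("CD8 T", "crater"): 3, ("CD8 T", "tumor"): 20, ("DC", "crater"): 1,
        ("CD4 T", "border"): 6, ("tumor", "tumor"): 60,
    })
    cell_radius_px: int = 3
    intensity: float = 150.0
    noise_sd: float = 3.0
    decoys: tuple = ("large", "vessel", "fibers", "nuclei", "interior", "asma")


def make_mif_phantom(layout: MifLayout = None, seed: int = 0):
    """2D multichannel mIF field with planted crater candidates and truth.

    Plants ``craters_per_hole`` rule-satisfying crater notches on each
    perivascular boundary plus one decoy per requested rule violation.  The
    manifest records every candidate with the rules it breaks (empty list =
    genuine crater), the analytic perivascular boundary length, the planted
    linear density, and the per-cell class/region table.
    """
    layout = layout or MifLayout()
    rng = np.random.default_rng(seed)
    ny, nx = layout.shape
    px = layout.pixel_um
    cy0, cx0 = ny * px / 2, nx * px / 2

    yy = (np.arange(ny) * px)[:, None]
    xx = (np.arange(nx) * px)[None, :]

    def disk(cy, cx, r):
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    tumor = disk(cy0, cx0, layout.tumor_radius_um)
    holes = []
    for k in range(layout.n_holes):
        ang = 2 * math.pi * k / layout.n_holes + 0.3
        hc = (cy0 + layout.hole_orbit_um * math.sin(ang),
              cx0 + layout.hole_orbit_um * math.cos(ang))
        holes.append(hc)
        tumor &= ~disk(hc[0], hc[1], layout.hole_radius_um)

    candidates = []  # dicts: center, diameter, violations, hole index

    def add_candidate(center, diam, violations, carve=True):
        if carve:
            tumor[:] = tumor & ~disk(center[0], center[1], diam / 2)
        candidates.append({"cy": center[0], "cx": center[1], "diameter_um": diam,
                           "violations": list(violations)})

    # genuine craters: notches centred on the perivascular boundary circles
    ang_step = 2 * math.pi / max(layout.craters_per_hole, 1)
    for hi, hc in enumerate(holes):
        for j in range(layout.craters_per_hole):
            ang = j * ang_step + 0.7 + 0.25 * hi
            d = rng.uniform(*layout.crater_diam_range)
            c = (hc[0] + layout.hole_radius_um * math.sin(ang),
                 hc[1] + layout.hole_radius_um * math.cos(ang))
            add_candidate(c, d, [])

    # decoys, each violating exactly one rule: the oversized gap sits on the
    # outer tumor border (a legitimate location), the others on a hole
    # boundary; the location decoy is a gap deep inside the tumor mass
    decoy_specs = {
        "large": dict(diam=80.0, violations=["size"]),
        "vessel": dict(diam=34.0, violations=["vessel_overlap"]),
        "fibers": dict(diam=34.0, violations=["collagen_fibers"]),
        "nuclei": dict(diam=34.0, violations=["nuclear_density"]),
        "asma": dict(diam=34.0, violations=["asma_overlap"]),
        "interior": dict(diam=34.0, violations=["on_boundary"]),
    }
    decoy_angles = iter(np.linspace(0.15, 2 * math.pi - 0.6, len(layout.decoys), endpoint=False))
    for name in layout.decoys:
        spec_d = decoy_specs[name]
        ang = float(next(decoy_angles)) + math.pi / 7
        if name == "interior":
            c = (cy0, cx0)  # tumor centre: far from every boundary
        elif name == "large":
            c = (cy0 + layout.tumor_radius_um * math.sin(ang),
                 cx0 + layout.tumor_radius_um * math.cos(ang))
        else:
            hc = holes[1 % len(holes)]
            c = (hc[0] + layout.hole_radius_um * math.sin(ang),
                 hc[1] + layout.hole_radius_um * math.cos(ang))
        add_candidate(c, spec_d["diam"], spec_d["violations"])

    # keep only candidates that do not collide with one another
    pruned = []
    for c in candidates:
        if all(math.hypot(c["cy"] - o["cy"], c["cx"] - o["cx"])
               > (c["diameter_um"] + o["diameter_um"]) / 2 + 6 for o in pruned):
            pruned.append(c)
    candidates = pruned

    chans = {name: np.zeros((ny, nx), dtype=float) for name in MIF_CHANNELS}
    chans["S100"][tumor] = layout.intensity
    chans["SOX10"][tumor] = layout.intensity * 0.6

    # CD31 vessel core in every perivascular hole
    for hc in holes:
        chans["CD31"][disk(hc[0], hc[1], 16.0)] = layout.intensity

    # stroma nuclei inside holes, kept out of every candidate gap so only the
    # planted high-density decoy violates the nuclear rule
    nuclei_pts = []
    hole_area = math.pi * layout.hole_radius_um**2
    n_nuc = int(round(layout.stroma_nuclei_density * hole_area))

    def in_any_candidate(p):
        return any(math.hypot(p[0] - c["cy"], p[1] - c["cx"]) <= c["diameter_um"] / 2 + 4
                   for c in candidates)

    for hc in holes:
        placed = 0
        while placed < n_nuc:
            rr = layout.hole_radius_um * math.sqrt(rng.uniform())
            aa = rng.uniform(0, 2 * math.pi)
            p = (hc[0] + rr * math.sin(aa), hc[1] + rr * math.cos(aa))
            if in_any_candidate(p):
                continue
            nuclei_pts.append(p)
            placed += 1

    # decoy payloads
    for c in candidates:
        v = c["violations"]
        r = c["diameter_um"] / 2
        if "vessel_overlap" in v:
            chans["CD31"][disk(c["cy"], c["cx"], r * 0.5)] = layout.intensity
        if "asma_overlap" in v:
            chans["aSMA"][disk(c["cy"], c["cx"], r * 0.5)] = layout.intensity
        if "collagen_fibers" in v:
            for k in range(4):
                off = (k - 1.5) * 8.0
                y_px = int(round((c["cy"] + off) / px))
                x0_px = int(round((c["cx"] - r - 20) / px))
                x1_px = int(round((c["cx"] + r + 20) / px))
                chans["collagen"][y_px:y_px + 1, max(x0_px, 0):x1_px] = layout.intensity
        if "nuclear_density" in v:
            n_extra = int(round(3.0 * layout.stroma_nuclei_density * math.pi * r**2))
            for _ in range(n_extra):
                rr = r * math.sqrt(rng.uniform())
                aa = rng.uniform(0, 2 * math.pi)
                nuclei_pts.append((c["cy"] + rr * math.sin(aa), c["cx"] + rr * math.cos(aa)))
        if not v:
            # genuine craters: one faint collagen fiber through half of them
            if rng.uniform() < 0.5:
                y_px = int(round(c["cy"] / px))
                x0_px = int(round((c["cx"] - r - 10) / px))
                x1_px = int(round((c["cx"] + r + 10) / px))
                chans["collagen"][y_px:y_px + 1, max(x0_px, 0):x1_px] = layout.intensity

    for (py, pxu) in nuclei_pts:
        chans["nucleus"][disk(py, pxu, 3.0)] = layout.intensity

    # cells: round label blobs with class-specific marker channels
    class_channels = {
        "CD8 T": ["CD8a"], "CD4 T": ["CD4"], "Treg": ["CD4", "FOXP3"],
        "DC": ["CD163", "CD11c"], "tumor": ["SOX10"],
    }
    genuine = [c for c in candidates if not c["violations"]]
    margin_band_r = (layout.tumor_radius_um, layout.tumor_radius_um + 40.0)
    cell_mask = np.zeros((ny, nx), dtype=np.int32)
    cell_rows = []
    cid = 0

    def sample_point(region):
        for _ in range(400):
            if region == "crater" and genuine:
                c = genuine[rng.integers(len(genuine))]
                rr = 0.4 * c["diameter_um"] / 2 * math.sqrt(rng.uniform())
                aa = rng.uniform(0, 2 * math.pi)
                return c["cy"] + rr * math.sin(aa), c["cx"] + rr * math.cos(aa)
            if region == "tumor":
                rr = rng.uniform(0.1, 0.82) * layout.tumor_radius_um
                aa = rng.uniform(0, 2 * math.pi)
                p = (cy0 + rr * math.sin(aa), cx0 + rr * math.cos(aa))
                iy, ix = int(p[0] / px), int(p[1] / px)
                if 0 <= iy < ny and 0 <= ix < nx and tumor[iy, ix]:
                    return p
                continue
            if region == "border":
                rr = rng.uniform(margin_band_r[0] + 5, margin_band_r[1] - 5)
                aa = rng.uniform(0, 2 * math.pi)
                return cy0 + rr * math.sin(aa), cx0 + rr * math.cos(aa)
        raise RuntimeError(f"cannot place cell in region {region}")

    for (ctype, region), n in layout.cells_per_region.items():
        for _ in range(n):
            p = sample_point(region)
            iy, ix = int(round(p[0] / px)), int(round(p[1] / px))
            if not (0 <= iy < ny and 0 <= ix < nx):
                continue
            cid += 1
            m = disk(p[0], p[1], layout.cell_radius_px * px)
            m &= cell_mask == 0
            cell_mask[m] = cid
            for ch in class_channels[ctype]:
                chans[ch][m] = layout.intensity
            chans["nucleus"][disk(p[0], p[1], 2.0)] = layout.intensity
            cell_rows.append({"id": cid, "y": p[0], "x": p[1], "cell_type": ctype,
                              "region": region})

    data = np.stack([chans[n] + rng.normal(0.0, layout.noise_sd, (ny, nx)) + 5.0
                     for n in MIF_CHANNELS])
    img = CalibratedImage(data=data, spacing=(px, px), channels=list(MIF_CHANNELS))

    pmb_len_um = layout.n_holes * 2 * math.pi * layout.hole_radius_um
    pmb_len_cm = pmb_len_um / 1e4
    n_true = len(genuine)
    manifest = TruthManifest(
        cells=pd.DataFrame(cell_rows),
        extras={
            "candidates": candidates,
            "n_true_craters": n_true,
            "pmb_length_cm": pmb_len_cm,
            "linear_density_per_cm": n_true / pmb_len_cm,
            "holes": holes,
            "hole_radius_um": layout.hole_radius_um,
            "tumor_radius_um": layout.tumor_radius_um,
            "tumor_center_um": (cy0, cx0),
            "stroma_nuclei_density": layout.stroma_nuclei_density,
            "nuclei": nuclei_pts,
        },
    )
    return img, cell_mask, manifest
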