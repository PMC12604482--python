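"""3D niche segmentation: tumor mask, bright-cell exclusion, black top-hat
crater extraction and blob-based cell detection.

The crater step is a black top-hat transform of the binary tumor segment:
morphological closing with a 40-voxel cube kernel, subtraction of the tumor
segment, then a 2-voxel opening to remove residue caused by the mismatch
between tumor morphology and the cube kernel.  Kernels are specified in
voxels; the volume is padded with background before closing so image borders
cannot generate phantom craters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import blob_log
from skimage.filters import threshold_otsu

from ._morphology import black_tophat, cube_opening
from .core_io import CalibratedImage


@dataclass
class Seg3DParams:
    gaussian_sigma: float = 2.0          # um
    closing_kernel: int = 40             # voxels (cube)
    opening_kernel: int = 2              # voxels (cube)
    min_crater_volume: int = 27          # voxels; discard smaller instances
    blob_min_sigma: float = 3.0          # um (T-cell radius scale)
    blob_max_sigma: float = 8.0          # um
    blob_num_sigma: int = 5
    blob_threshold: float = 0.05
    bright_cell_percentile: float = 99.0
    bright_cell_min_zscore: float = 8.0  # robust z of a blob centre vs background

    def __post_init__(self):
        if not (self.closing_kernel > self.opening_kernel >= 1):
            raise ValueError("require closing_kernel > opening_kernel >= 1")


@dataclass
class CraterSegmentation:
    labels: np.ndarray                   # int32, 0 = background
    border_labels: list = field(default_factory=list)
    params: Seg3DParams = None

    @property
    def n_craters(self) -> int:
        return int(self.labels.max())


def _sigma_voxels(sigma_um: float, spacing) -> tuple:
    return tuple(sigma_um / s for s in spacing)


def segment_tumor(img: CalibratedImage, channel: str, params: Seg3DParams = None,
                  exclude_mask: np.ndarray = None) -> np.ndarray:
    """Gaussian smoothing + Otsu threshold + largest connected component.

    Voxels covered by ``exclude_mask`` (bright-cell punctae) are removed from
    the thresholded foreground before the component analysis.
    """
    params = params or Seg3DParams()
    if not img.is_3d:
        raise ValueError("segment_tumor expects a 3D image")
    ch = np.asarray(img.channel(channel), dtype=float)
    if np.ptp(ch) == 0:
        raise ValueError("no foreground: channel is constant")
    sm = ndi.gaussian_filter(ch, sigma=_sigma_voxels(params.gaussian_sigma, img.spacing))
    thr = threshold_otsu(sm)
    fg = sm > thr
    if exclude_mask is not None:
        fg &= ~np.asarray(exclude_mask, dtype=bool)
    if not fg.any():
        raise ValueError("no foreground after thresholding")
    lbl, n = ndi.label(fg)
    if n > 1:
        sizes = np.bincount(lbl.ravel())
        sizes[0] = 0
        fg = lbl == int(np.argmax(sizes))
    return fg


def exclude_bright_cells(img: CalibratedImage, channel: str,
                         params: Seg3DParams = None) -> tuple:
    """Blob-detect bright punctae to exclude from tumor segmentation.

    Returns ``(mask, detections)``; ``detections`` is a DataFrame with
    centroids in um, radii, and a ``truncated`` flag for blobs whose support
    reaches the image border.  Blobs whose raw centre intensity is not well
    above background (robust z-score below ``bright_cell_min_zscore``) are
    discarded, so a channel with no bright population yields an empty mask.
    """
    params = params or Seg3DParams()
    ch = np.asarray(img.channel(channel), dtype=float)
    # percentile rescaling stands in for the acquisition software's
    # "Normalization" enhancement (exact operator unpublished)
    hi = np.percentile(ch, params.bright_cell_percentile)
    lo = np.percentile(ch, 1.0)
    if hi <= lo:
        return np.zeros(ch.shape, dtype=bool), _empty_cells()
    norm = np.clip((ch - lo) / (hi - lo), 0, 1)
    cells = detect_cells(
        CalibratedImage(norm[None], img.spacing, channels=[channel]), channel, params
    )
    if len(cells):
        med = np.median(ch)
        mad_sigma = 1.4826 * np.median(np.abs(ch - med)) + 1e-12
        keep = []
        for _, row in cells.iterrows():
            idx = tuple(int(np.clip(round(row[ax] / s), 0, n - 1))
                        for ax, s, n in zip(("z", "y", "x"), img.spacing, ch.shape))
            keep.append((ch[idx] - med) / mad_sigma >= params.bright_cell_min_zscore)
        cells = cells.loc[keep].reset_index(drop=True)
    mask = np.zeros(ch.shape, dtype=bool)
    if len(cells):
        coords = [np.arange(n) * s for n, s in zip(ch.shape, img.spacing)]
        grids = np.meshgrid(*coords, indexing="ij", sparse=True)
        for _, row in cells.iterrows():
            r = max(row["radius_um"], min(img.spacing))
            d2 = sum((g - row[ax]) ** 2 for g, ax in zip(grids, ("z", "y", "x")))
            mask |= d2 <= r**2
    return mask, cells


def _empty_cells() -> pd.DataFrame:
    df = pd.DataFrame(columns=["id", "z", "y", "x", "radius_um", "truncated"])
    df.attrs["units"] = {"z": "um", "y": "um", "x": "um", "radius_um": "um"}
    return df


def detect_cells(img: CalibratedImage, channel: str,
                 params: Seg3DParams = None) -> pd.DataFrame:
    """Multiscale Laplacian-of-Gaussian cell detection on a smoothed channel.

    Scales are given in um and converted per axis through the voxel spacing,
    so detection is anisotropy-aware.  Two cells closer than the blob scale
    merge into a single detection (documented contract).
    """
    params = params or Seg3DParams()
    ch = np.asarray(img.channel(channel), dtype=float)
    spacing = img.spacing
    rng_int = np.ptp(ch)
    if rng_int == 0:
        return _empty_cells()
    norm = (ch - ch.min()) / rng_int
    min_sigma = [params.blob_min_sigma / 1.414 / s for s in spacing]
    max_sigma = [params.blob_max_sigma / 1.414 / s for s in spacing]
    blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma,
                     num_sigma=params.blob_num_sigma, threshold=params.blob_threshold)
    rows = []
    ndim = ch.ndim
    axis_names = ("z", "y", "x")[-ndim:]
    for i, b in enumerate(blobs):
        pos = b[:ndim]
        sigma = b[ndim:]
        centroid = {ax: float(p * s) for ax, p, s in zip(axis_names, pos, spacing)}
        radius = float(np.mean([sg * s for sg, s in zip(sigma, spacing)]) * np.sqrt(ndim))
        truncated = any(p * s < radius or (n - 1 - p) * s < radius
                        for p, s, n in zip(pos, spacing, ch.shape))
        rows.append({"id": i, **centroid, "radius_um": radius, "truncated": truncated})
    df = pd.DataFrame(rows) if rows else _empty_cells()
    if ndim == 2 and len(df):
        df.insert(1, "z", 0.0)
    df.attrs["units"] = {"z": "um", "y": "um", "x": "um", "radius_um": "um"}
    return df


def segment_craters(tumor: np.ndarray, params: Seg3DParams = None) -> CraterSegmentation:
    """Black top-hat crater extraction with residue cleanup.

    craters = open(close(tumor, K_closing) - tumor, K_opening), connected
    components labeled; instances below ``min_crater_volume`` voxels are
    discarded and components touching the volume border are flagged.
    """
    params = params or Seg3DParams()
    tumor = np.asarray(tumor, dtype=bool)
    if not tumor.any():
        raise ValueError("empty tumor mask")
    bth = black_tophat(tumor, params.closing_kernel)
    cleaned = cube_opening(bth, params.opening_kernel)
    lbl, n = ndi.label(cleaned)
    if n and params.min_crater_volume > 1:
        sizes = np.bincount(lbl.ravel())
        keep = np.flatnonzero(sizes >= params.min_crater_volume)
        keep = keep[keep > 0]
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, len(keep) + 1)
        lbl = relabel[lbl]
    lbl = lbl.astype(np.int32)
    border_labels = set()
    for axis in range(lbl.ndim):
        for idx in (0, -1):
            face = np.take(lbl, idx, axis=axis)
            border_labels.update(np.unique(face[face > 0]).tolist())
    return CraterSegmentation(labels=lbl, border_labels=sorted(int(b) for b in border_labels),
                              params=params)
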