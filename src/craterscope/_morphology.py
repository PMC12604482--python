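"""Shared binary/grayscale morphology primitives.

Cube-kernel closing/opening are implemented with separable max/min filters so
that the 40-voxel kernels of the 3D niche pipeline stay tractable.  Even-sized
kernels are centered at floor(k/2): a k-cube structuring element covers offsets
[-floor(k/2), k-1-floor(k/2)] on each axis, and the paired erosion uses the
reflected element so that closing/opening satisfy their lattice properties
(extensivity / anti-extensivity) bit-exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def _reflected(filtered: np.ndarray, k: int) -> np.ndarray:
    """Shift a centered k-window filter result so it uses the reflected window.

    An even k-window covers offsets [-k/2, k/2 - 1]; its reflection covers
    [-k/2 + 1, k/2], i.e. the same filter evaluated one voxel later on every
    axis.  Only valid well inside a padded volume (callers pad by >= k).
    Odd windows are symmetric and returned unchanged.
    """
    if k % 2 == 1:
        return filtered
    out = filtered
    for ax in range(filtered.ndim):
        out = np.roll(out, -1, axis=ax)
    return out


def cube_closing(mask: np.ndarray, k: int) -> np.ndarray:
    """Binary closing with a k-cube (k^ndim) structuring element.

    The volume is padded with background (False) by ``k`` on every axis before
    closing and cropped afterwards, so image borders cannot generate phantom
    fill.  Even kernels are centered at floor(k/2); the paired erosion uses
    the reflected element so closing is extensive (superset of the input).
    """
    if k < 1:
        raise ValueError("kernel size must be >= 1")
    m = np.asarray(mask, dtype=bool)
    m = np.pad(m, k, mode="constant", constant_values=False)
    size = (k,) * m.ndim
    dil = ndi.maximum_filter(m, size=size, mode="constant", cval=False)
    clo = _reflected(ndi.minimum_filter(dil, size=size, mode="constant", cval=True), k)
    sl = tuple(slice(k, -k) for _ in range(m.ndim))
    return clo[sl]


def cube_opening(mask: np.ndarray, k: int) -> np.ndarray:
    """Binary opening with a k-cube structuring element (erosion then dilation)."""
    if k < 1:
        raise ValueError("kernel size must be >= 1")
    m = np.asarray(mask, dtype=bool)
    m = np.pad(m, k, mode="constant", constant_values=False)
    size = (k,) * m.ndim
    ero = ndi.minimum_filter(m, size=size, mode="constant", cval=False)
    ope = _reflected(ndi.maximum_filter(ero, size=size, mode="constant", cval=False), k)
    sl = tuple(slice(k, -k) for _ in range(m.ndim))
    return ope[sl]


def black_tophat(mask: np.ndarray, k: int) -> np.ndarray:
    """closing(mask, k) minus mask: the concave indentations smaller than k."""
    return cube_closing(mask, k) & ~np.asarray(mask, dtype=bool)


def distance_to(mask: np.ndarray, spacing) -> np.ndarray:
    """Exact Euclidean distance (physical units) from every voxel to the mask.

    Zero inside the mask.  ``spacing`` is the per-axis physical voxel size.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("reference mask is empty")
    if m.all():
        return np.zeros(m.shape, dtype=float)
    return ndi.distance_transform_edt(~m, sampling=spacing)


def disk_structuring_element(radius_px: float) -> np.ndarray:
    r = int(np.floor(radius_px))
    if r < 1:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def binary_opening_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    se = disk_structuring_element(radius_px)
    return ndi.binary_opening(mask, structure=se)


def binary_closing_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    se = disk_structuring_element(radius_px)
    pad = se.shape[0]
    m = np.pad(np.asarray(mask, bool), pad, mode="constant")
    out = ndi.binary_closing(m, structure=se)
    return out[pad:-pad, pad:-pad]
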