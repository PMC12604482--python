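import numpy as np
import pytest

from craterscope import segmentation3d as s3
from craterscope import synthetic as syn
from craterscope.core_io import RegionMaskSet


@pytest.fixture(scope="session")
def tumor_phantom():
    """One 3D tumor phantom with four ~30 um pockets, shared across tests."""
    spec = syn.PhantomSpec(seed=1, pocket_count=4, shape=(48, 160, 160),
                           pocket_diameter_mean=30, pocket_diameter_sd=4)
    img, masks, manifest = syn.make_tumor_phantom(spec)
    return spec, img, masks, manifest


@pytest.fixture(scope="session")
def segmented_phantom(tumor_phantom):
    """The shared phantom run through tumor + crater segmentation."""
    _, img, _, manifest = tumor_phantom
    tumor = s3.segment_tumor(img, "tumor")
    seg = s3.segment_craters(tumor)
    masks = RegionMaskSet(tumor=tumor, craters=seg.labels, spacing=img.spacing)
    return img, masks, manifest


@pytest.fixture(scope="session")
def mif_phantom():
    img, cell_mask, manifest = syn.make_mif_phantom(seed=0)
    return img, cell_mask, manifest


def brute_force_closing(mask: np.ndarray, k: int) -> np.ndarray:
    """Independent shift-and-OR / shift-and-AND cube closing oracle.

    Uses the documented convention: even k-cubes are centred at floor(k/2),
    so the dilation element covers offsets [-(k//2 - 1), k//2] (symmetric for
    odd k) and the erosion uses the same element in adjoint form.
    """
    from itertools import product

    lo = -(k // 2 - 1) if k % 2 == 0 else -(k // 2)
    hi = k // 2
    offsets = list(product(range(lo, hi + 1), repeat=mask.ndim))
    pad = k + 2
    m = np.pad(np.asarray(mask, bool), pad)
    axes = tuple(range(mask.ndim))
    dil = np.zeros_like(m)
    for sh in offsets:
        dil |= np.roll(m, sh, axis=axes)
    ero = np.ones_like(m)
    for sh in offsets:
        ero &= np.roll(dil, tuple(-s for s in sh), axis=axes)
    sl = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    return ero[sl]


def brute_force_opening(mask: np.ndarray, k: int) -> np.ndarray:
    from itertools import product

    lo = -(k // 2 - 1) if k % 2 == 0 else -(k // 2)
    hi = k // 2
    offsets = list(product(range(lo, hi + 1), repeat=mask.ndim))
    pad = k + 2
    m = np.pad(np.asarray(mask, bool), pad)
    axes = tuple(range(mask.ndim))
    ero = np.ones_like(m)
    for sh in offsets:
        ero &= np.roll(m, tuple(-s for s in sh), axis=axes)
    dil = np.zeros_like(m)
    for sh in offsets:
        dil |= np.roll(ero, sh, axis=axes)
    sl = tuple(slice(pad, -pad) for _ in range(mask.ndim))
    return dil[sl]
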