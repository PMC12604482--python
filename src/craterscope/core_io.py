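"""Calibrated images, region masks, cell tables and region annotations.

All coordinates are 0-based array indices internally; exported tables are in
physical micrometres with the origin at array index (0, ..., 0).  Readers never
guess units: an image without pixel-size metadata and without an explicit
override is an error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, shape as shapely_shape


class CalibrationError(ValueError):
    """Raised when physical pixel/voxel sizes cannot be established."""


@dataclass
class CalibratedImage:
    """n-D intensity image with physical per-axis spacing in micrometres.

    If ``channels`` is not None, axis 0 of ``data`` is the channel axis and the
    remaining axes are spatial; otherwise all axes are spatial.  ``spacing``
    has one entry per spatial axis, ordered like the array axes (e.g. (z, y, x)
    for a 3D stack).
    """

    data: np.ndarray
    spacing: tuple
    channels: Optional[list] = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise CalibrationError(f"spacing must be strictly positive, got {self.spacing}")
        n_spatial = self.data.ndim - (1 if self.channels is not None else 0)
        if len(self.spacing) != n_spatial:
            raise CalibrationError(
                f"spacing has {len(self.spacing)} entries for {n_spatial} spatial axes"
            )
        if self.channels is not None and len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {self.data.shape[0]} channels"
            )

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:] if self.channels is not None else self.data.shape

    @property
    def is_3d(self) -> bool:
        return len(self.spatial_shape) == 3

    @property
    def axes(self) -> str:
        spatial = "ZYX"[-len(self.spatial_shape):]
        return ("C" + spatial) if self.channels is not None else spatial

    def channel(self, name) -> np.ndarray:
        if self.channels is None:
            raise KeyError("image has no channel axis")
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {self.channels}")
        return self.data[self.channels.index(name)]


@dataclass
class RegionMaskSet:
    """Co-registered masks: tumor, labeled crater instances, margin, vessels."""

    tumor: np.ndarray
    craters: np.ndarray
    spacing: tuple
    margin: Optional[np.ndarray] = None
    vessels: Optional[np.ndarray] = None
    excluded_cells: Optional[np.ndarray] = None

    def __post_init__(self):
        self.tumor = np.asarray(self.tumor, dtype=bool)
        self.craters = np.asarray(self.craters)
        if not np.issubdtype(self.craters.dtype, np.integer):
            raise ValueError("crater mask must be an integer label mask")
        if self.craters.min() < 0:
            raise ValueError("crater labels must be non-negative (0 = background)")
        self.spacing = tuple(float(s) for s in self.spacing)
        for name in ("craters", "margin", "vessels", "excluded_cells"):
            m = getattr(self, name)
            if m is not None and m.shape != self.tumor.shape:
                raise ValueError(f"mask {name!r} shape {m.shape} != tumor shape {self.tumor.shape}")
        if len(self.spacing) != self.tumor.ndim:
            raise ValueError("spacing length must equal mask dimensionality")
        if self.margin is not None and np.any(np.asarray(self.margin, bool) & self.tumor):
            raise ValueError("margin must be disjoint from tumor")

    @property
    def crater_labels(self) -> np.ndarray:
        labels = np.unique(self.craters)
        return labels[labels > 0]


@dataclass
class RegionAnnotation:
    """One polygonal region annotation in physical micrometre coordinates."""

    polygon: Polygon
    class_name: str
    annotator: str
    properties: dict = field(default_factory=dict)

    @property
    def area_um2(self) -> float:
        return float(self.polygon.area)


# ---------------------------------------------------------------------------
# images

_DESCRIPTION_KEY = "craterscope"


def write_image(img: CalibratedImage, path) -> Path:
    """Write a TIFF with spacing/channel metadata embedded as JSON description."""
    path = Path(path)
    meta = {
        _DESCRIPTION_KEY: {
            "spacing_um": list(img.spacing),
            "channels": img.channels,
            "axes": img.axes,
        }
    }
    tifffile.imwrite(path, img.data, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_image(path, spacing_override: Optional[Sequence[float]] = None,
               channels: Optional[list] = None) -> CalibratedImage:
    """Read a TIFF/OME-TIFF into a :class:`CalibratedImage`.

    Spacing is taken from metadata (our JSON description, OME physical sizes,
    or ImageJ resolution tags); ``spacing_override`` wins when supplied.  An
    image without any recoverable spacing and no override raises
    :class:`CalibrationError` rather than silently assuming a unit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_spacing = None
        meta_channels = None
        desc = tf.pages[0].description or ""
        try:
            parsed = json.loads(desc)
            block = parsed.get(_DESCRIPTION_KEY, {})
            if "spacing_um" in block:
                meta_spacing = tuple(block["spacing_um"])
            meta_channels = block.get("channels")
        except (json.JSONDecodeError, AttributeError):
            pass
        if meta_spacing is None and tf.is_ome and tf.ome_metadata:
            om = tf.ome_metadata
            sizes = {}
            for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
                tok = f'{key}="'
                if tok in om:
                    sizes[key] = float(om.split(tok)[1].split('"')[0])
            if "PhysicalSizeY" in sizes and "PhysicalSizeX" in sizes:
                ndim_spatial = data.ndim if channels is None and meta_channels is None else data.ndim - 1
                if ndim_spatial == 3 and "PhysicalSizeZ" in sizes:
                    meta_spacing = (sizes["PhysicalSizeZ"], sizes["PhysicalSizeY"], sizes["PhysicalSizeX"])
                elif ndim_spatial == 2:
                    meta_spacing = (sizes["PhysicalSizeY"], sizes["PhysicalSizeX"])
        if meta_spacing is None and tf.is_imagej:
            ij = tf.imagej_metadata or {}
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            if res is not None and res.value[0] > 0:
                px = res.value[1] / res.value[0]
                if data.ndim >= 3 and "spacing" in ij:
                    meta_spacing = (float(ij["spacing"]), px, px)
                else:
                    meta_spacing = (px, px)
    spacing = tuple(spacing_override) if spacing_override is not None else meta_spacing
    if spacing is None:
        raise CalibrationError(
            f"{path}: no pixel-size metadata found and no spacing_override supplied"
        )
    chans = channels if channels is not None else meta_channels
    if chans is None and data.ndim > len(spacing):
        chans = [f"c{i}" for i in range(data.shape[0])]
    return CalibratedImage(data=data, spacing=tuple(spacing), channels=chans)


# ---------------------------------------------------------------------------
# mask sets: integer TIFFs + JSON sidecar

_MASK_FILES = ("tumor", "craters", "margin", "vessels", "excluded_cells")


def write_masks(masks: RegionMaskSet, path) -> Path:
    """Serialize a mask set to a directory of integer TIFFs + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    present = []
    for name in _MASK_FILES:
        m = getattr(masks, name)
        if m is None:
            continue
        arr = m.astype(np.int32) if name == "craters" else m.astype(np.uint8)
        tifffile.imwrite(path / f"{name}.tif", arr)
        present.append(name)
    sidecar = {
        "spacing_um": list(masks.spacing),
        "shape": list(masks.tumor.shape),
        "masks": present,
        "crater_labels": [int(v) for v in masks.crater_labels],
    }
    (path / "masks.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_masks(path) -> RegionMaskSet:
    path = Path(path)
    sidecar = json.loads((path / "masks.json").read_text())
    arrays = {}
    for name in sidecar["masks"]:
        arr = tifffile.imread(path / f"{name}.tif")
        arrays[name] = arr.astype(np.int64) if name == "craters" else arr.astype(bool)
    return RegionMaskSet(spacing=tuple(sidecar["spacing_um"]), **arrays)


# ---------------------------------------------------------------------------
# cell / foci tables

def write_table(df: pd.DataFrame, path, units: Optional[dict] = None) -> Path:
    """CSV with a leading '# units:' comment line carrying column units."""
    path = Path(path)
    units = units or df.attrs.get("units", {})
    with open(path, "w") as fh:
        fh.write("# units: " + json.dumps(units) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        units = {}
        if first.startswith("# units:"):
            units = json.loads(first[len("# units:"):])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    df.attrs["units"] = units
    return df


# ---------------------------------------------------------------------------
# QuPath-dialect GeoJSON annotations

def read_annotations(path, annotator: Optional[str] = None) -> list:
    """Read polygon annotations from QuPath-dialect GeoJSON.

    The class name is taken from ``properties.classification.name``; the
    annotator id from ``properties.annotator`` unless overridden.  A
    self-intersecting polygon is rejected with the index of the offending
    feature.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    feats = payload.get("features", payload if isinstance(payload, list) else [])
    out = []
    for i, feat in enumerate(feats):
        props = feat.get("properties", {})
        cls = props.get("classification", {})
        name = cls.get("name") if isinstance(cls, dict) else cls
        if not name:
            raise ValueError(f"feature {i} in {path} has no classification name")
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"feature {i}: expected Polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise ValueError(f"feature {i} in {path}: invalid (self-intersecting?) polygon")
        who = annotator or props.get("annotator") or payload.get("annotator", "unknown")
        out.append(RegionAnnotation(polygon=geom, class_name=name, annotator=str(who),
                                    properties=props))
    return out


def write_annotations(annotations: Sequence[RegionAnnotation], path,
                      annotator: Optional[str] = None) -> Path:
    path = Path(path)
    feats = []
    for ann in annotations:
        feats.append({
            "type": "Feature",
            "geometry": ann.polygon.__geo_interface__,
            "properties": {
                "classification": {"name": ann.class_name},
                "annotator": annotator or ann.annotator,
                **{k: v for k, v in ann.properties.items() if k != "classification"},
            },
        })
    payload = {"type": "FeatureCollection", "features": feats}
    path.write_text(json.dumps(payload))
    return path


def merge_annotations(paths_by_annotator: dict) -> list:
    """Merge several annotators' GeoJSON files, tagging each by annotator id."""
    merged = []
    for who, p in paths_by_annotator.items():
        merged.extend(read_annotations(p, annotator=who))
    return merged
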