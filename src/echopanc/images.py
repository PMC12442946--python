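"""B-mode image and region-of-interest handling.

Coordinate convention: 0-based pixel indices, row 0 is the transducer/dermis
face, depth increases with the row index.  Pixel spacing is isotropic in
mm/pixel; depths are reported in cm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from PIL import Image as PILImage

REGION_LABELS = ("head", "body", "tail", "whole")


class ConfigurationError(RuntimeError):
    """Missing metadata (e.g. pixel spacing) that cannot be inferred."""


@dataclass
class UltrasoundImage:
    pixels: np.ndarray  # (rows, cols) uint8 grayscale
    pixel_spacing_mm: float  # isotropic mm/pixel
    patient_id: str = "unknown"
    class_label: str = "unknown"  # 'DM', 'non-DM' or 'unknown'

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        if not np.all(np.isfinite(self.pixels.astype(float))):
            raise ValueError("pixels must be finite")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RegionAnnotation:
    """Ordered polygon outline in pixel coordinates ([x, y] = [col, row])."""

    vertices: np.ndarray  # (n, 2) float
    region_label: str = "whole"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of [x, y]")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.region_label not in REGION_LABELS:
            raise ValueError(f"region_label must be one of {REGION_LABELS}")
        if not _is_simple_polygon(self.vertices):
            raise ValueError("polygon must be simple (non-self-intersecting)")


def _is_simple_polygon(verts: np.ndarray) -> bool:
    from shapely.geometry import Polygon
    try:
        return Polygon(verts).is_valid
    except Exception:
        return False


@dataclass
class PancreasMask:
    mask: np.ndarray  # boolean, same shape as the image
    region_label: str = "whole"
    #: fewer than 16 foreground pixels makes texture statistics unreliable
    MIN_PIXELS = 16

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.mask.sum() < self.MIN_PIXELS:
            warnings.warn("mask has fewer than 16 pixels; texture features "
                          "will be flagged unreliable", stacklevel=2)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def load_image(path, spacing_override: float | None = None,
               patient_id: str = "unknown",
               class_label: str = "unknown") -> UltrasoundImage:
    """Read a DICOM or PNG/TIFF image as 8-bit grayscale with known spacing.

    Spacing comes from the DICOM PixelSpacing tag when present, otherwise
    from ``spacing_override`` (mm/pixel); neither available is a
    :class:`ConfigurationError`.  Higher bit depths are min-max rescaled to
    0-255 with a warning; multi-frame DICOMs keep the first frame.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spacing = spacing_override
    if path.suffix.lower() in (".dcm", ".dicom", ""):
        import pydicom
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim == 3 and arr.shape[0] > 1 and arr.shape[-1] not in (3, 4):
            warnings.warn("multi-frame DICOM; using the first frame", stacklevel=2)
            arr = arr[0]
        tag_spacing = getattr(ds, "PixelSpacing", None)
        if tag_spacing is not None:
            spacing = float(tag_spacing[0])
    else:
        arr = np.asarray(PILImage.open(path))
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].astype(float).mean(axis=-1)
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        lo, hi = float(arr.min()), float(arr.max())
        warnings.warn("input is not 8-bit; min-max rescaling to 0-255",
                      stacklevel=2)
        arr = np.zeros_like(arr, dtype=np.uint8) if hi == lo else \
            np.round((arr.astype(float) - lo) / (hi - lo) * 255).astype(np.uint8)
    if spacing is None:
        raise ConfigurationError(
            f"{path.name}: no pixel spacing available; pass spacing_override")
    return UltrasoundImage(pixels=arr, pixel_spacing_mm=float(spacing),
                           patient_id=patient_id, class_label=class_label)


def save_image_png(image: UltrasoundImage, path) -> None:
    PILImage.fromarray(image.pixels, mode="L").save(path)


def save_mask_png(mask: PancreasMask, path) -> None:
    PILImage.fromarray((mask.mask * 255).astype(np.uint8), mode="L").save(path)


def load_mask_png(path, region_label: str = "whole") -> PancreasMask:
    arr = np.asarray(PILImage.open(path))
    return PancreasMask(mask=arr > 127, region_label=region_label)


def load_annotation_json(path) -> RegionAnnotation:
    with open(path) as fh:
        data = json.load(fh)
    return RegionAnnotation(vertices=np.asarray(data["vertices"], dtype=float),
                            region_label=data.get("region", "whole"))


def rasterize_annotation(ann: RegionAnnotation,
                         image: UltrasoundImage) -> PancreasMask:
    """Polygon -> binary mask: a pixel is foreground iff its center lies
    inside the polygon (even-odd rule for simple polygons)."""
    rows, cols = image.shape
    xs, ys = ann.vertices[:, 0], ann.vertices[:, 1]
    if xs.min() < -0.5 or ys.min() < -0.5 or xs.max() > cols - 0.5 or \
            ys.max() > rows - 0.5:
        raise ValueError("polygon vertices outside image bounds")
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    inside = MplPath(ann.vertices).contains_points(pts).reshape(rows, cols)
    return PancreasMask(mask=inside, region_label=ann.region_label)


class RegionView:
    """The pancreas isolated from the image: outside-mask pixels are
    excluded from all statistics (not set to zero)."""

    def __init__(self, image: UltrasoundImage, mask: PancreasMask):
        if image.shape != mask.mask.shape:
            raise ValueError("image and mask shapes differ")
        self.image = image
        self.mask = mask

    @property
    def values(self) -> np.ndarray:
        """In-mask pixel intensities (1-D)."""
        return self.image.pixels[self.mask.mask]

    def zero_filled(self) -> np.ndarray:
        """Visualization copy with outside-mask pixels set to zero."""
        out = np.zeros_like(self.image.pixels)
        out[self.mask.mask] = self.image.pixels[self.mask.mask]
        return out


def isolate_pancreas(image: UltrasoundImage, mask: PancreasMask) -> RegionView:
    return RegionView(image, mask)


def region_depth(mask: PancreasMask, image: UltrasoundImage) -> float:
    """Depth of the region centroid below the dermis (row 0), in cm."""
    rows = np.nonzero(mask.mask)[0]
    return float(rows.mean() * image.pixel_spacing_mm / 10.0)


def depth_profile(entries) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient, per-region depth summaries for a cohort.

    ``entries`` is an iterable of (image, mask) pairs; every depth is
    retained and the per-(patient, region) mean is reported for depth
    progression plots.  The second frame reports, per region label, the
    fraction of images in which that region appears.
    """
    rows = []
    for image, mask in entries:
        rows.append(dict(patient_id=image.patient_id,
                         region=mask.region_label,
                         class_label=image.class_label,
                         depth_cm=region_depth(mask, image)))
    df = pd.DataFrame(rows)
    summary = (df.groupby(["patient_id", "region"], as_index=False)
               .agg(depths=("depth_cm", list), mean_depth_cm=("depth_cm", "mean"),
                    n_images=("depth_cm", "size")))
    n_total = len(df)
    frac = (df.groupby("region")["depth_cm"].size() / n_total).rename(
        "fraction_of_images").reset_index()
    return summary, frac
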