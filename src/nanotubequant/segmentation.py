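"""Background-calibrated thresholding and connected-component segmentation.

The acquisition workflow this package automates adjusts an intensity
threshold per experiment and then size-selects objects.  That manual step
is replaced here by an explicit :class:`BackgroundModel` with four
reproducible rules:

``percentile``
    Threshold at the given percentile of donor-free control images
    (default rule for donor channels, percentile 99.9).
``mean_plus_k_sd``
    µ + k·σ of the pooled control pixels.
``otsu``
    Otsu's threshold on the pooled pixels (default rule for cell
    channels, computed on the image itself).
``manual``
    A user-supplied intensity.

Segmentation takes pixels *strictly above* the threshold, labels
connected components (8-connectivity by default so 1-px diagonal necks
stay attached), optionally fills internal holes, and keeps components by
inclusive area bounds stated in µm².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu

from .imgio import BinaryMask, CalibratedImage, um2_to_px


class BackgroundMethod(str, Enum):
    PERCENTILE = "percentile"
    MEAN_PLUS_K_SD = "mean_plus_k_sd"
    OTSU = "otsu"
    MANUAL = "manual"


@dataclass(frozen=True)
class BackgroundModel:
    """Intensity threshold separating fluorescent signal from background."""

    threshold_intensity: float
    method: BackgroundMethod
    parameters: dict = field(default_factory=dict)


def estimate_background(
    controls: Sequence[CalibratedImage],
    method: BackgroundMethod | str = BackgroundMethod.PERCENTILE,
    param: float | None = None,
) -> BackgroundModel:
    """Fit a :class:`BackgroundModel` from control images.

    For the ``percentile`` method the threshold is the *maximum* over the
    per-image percentiles, so on every control the supra-threshold pixel
    fraction is at most (100−param)/100 (up to ties).  ``manual`` returns
    ``param`` verbatim and needs no controls' intensity support.
    """
    method = BackgroundMethod(method)
    if method is BackgroundMethod.MANUAL:
        if param is None:
            raise ValueError("manual method requires param = threshold intensity")
        return BackgroundModel(float(param), method, {"value": float(param)})

    if len(controls) == 0:
        raise ValueError("at least one control image is required")
    sizes = {c.pixel_size for c in controls}
    if len(sizes) > 1:
        raise ValueError("control images must share calibration")

    if method is BackgroundMethod.PERCENTILE:
        p = 99.9 if param is None else float(param)
        if not 50.0 < p < 100.0:
            raise ValueError(f"percentile must be in (50, 100), got {p}")
        thr = max(float(np.percentile(c.pixels, p)) for c in controls)
        params = {"percentile": p}
    elif method is BackgroundMethod.MEAN_PLUS_K_SD:
        k = 5.0 if param is None else float(param)
        pooled = np.concatenate([c.pixels.ravel() for c in controls]).astype(float)
        thr = float(pooled.mean() + k * pooled.std())
        params = {"k": k}
    elif method is BackgroundMethod.OTSU:
        pooled = np.concatenate([c.pixels.ravel() for c in controls])
        thr = float(threshold_otsu(pooled))
        params = {}
    else:  # pragma: no cover
        raise ValueError(method)

    lo = min(float(c.pixels.min()) for c in controls)
    hi = max(float(c.pixels.max()) for c in controls)
    thr = float(np.clip(thr, lo, hi))
    return BackgroundModel(thr, method, params)


@dataclass(frozen=True)
class Region:
    """One labeled connected component with its bbox-cropped mask.

    ``bbox`` is (min_row, min_col, max_row, max_col) with exclusive upper
    bounds (half-open), tightly enclosing the mask.
    """

    label: int
    mask: BinaryMask  # cropped to bbox
    bbox: tuple[int, int, int, int]
    pixel_size: float
    source_shape: tuple[int, int]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.n_pixels * self.pixel_size**2

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask.pixels)
        return (float(rr.mean()) + self.bbox[0], float(cc.mean()) + self.bbox[1])

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) pixel coordinates in the source frame."""
        rr, cc = np.nonzero(self.mask.pixels)
        return np.column_stack([rr + self.bbox[0], cc + self.bbox[1]])

    def full_mask(self) -> np.ndarray:
        """Boolean raster of the region at the source-image shape."""
        out = np.zeros(self.source_shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask.pixels
        return out


@dataclass(frozen=True)
class RegionSet:
    """Labeled, pairwise-disjoint regions from one raster."""

    regions: tuple[Region, ...]
    source_shape: tuple[int, int]
    pixel_size: float
    connectivity: int = 8

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        object.__setattr__(self, "regions", tuple(self.regions))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def areas_um2(self) -> np.ndarray:
        return np.array([r.area_um2 for r in self.regions])

    def to_label_image(self) -> np.ndarray:
        """16-bit label raster (0 = background)."""
        out = np.zeros(self.source_shape, dtype=np.uint16)
        for r in self.regions:
            r0, c0, r1, c1 = r.bbox
            view = out[r0:r1, c0:c1]
            view[r.mask.pixels] = r.label
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            cy, cx = r.centroid
            rows.append(
                {
                    "label": r.label,
                    "area_um2": r.area_um2,
                    "centroid_row": cy,
                    "centroid_col": cx,
                    "bbox_min_row": r.bbox[0],
                    "bbox_min_col": r.bbox[1],
                    "bbox_max_row": r.bbox[2],
                    "bbox_max_col": r.bbox[3],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "label",
                "area_um2",
                "centroid_row",
                "centroid_col",
                "bbox_min_row",
                "bbox_min_col",
                "bbox_max_row",
                "bbox_max_col",
            ],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_label_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(Path(path), self.to_label_image())


def regions_from_labels(
    label_image: np.ndarray, pixel_size: float, connectivity: int = 8
) -> RegionSet:
    """Wrap an integer label raster as a :class:`RegionSet`."""
    regions = []
    for rp in measure.regionprops(label_image):
        r0, c0, r1, c1 = rp.bbox
        regions.append(
            Region(
                label=int(rp.label),
                mask=BinaryMask(rp.image, pixel_size),
                bbox=(r0, c0, r1, c1),
                pixel_size=pixel_size,
                source_shape=tuple(label_image.shape),
            )
        )
    return RegionSet(tuple(regions), tuple(label_image.shape), pixel_size, connectivity)


def label_mask(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component labeling of a boolean raster (4- or 8-connectivity)."""
    skimage_conn = 1 if connectivity == 4 else 2
    return measure.label(mask, connectivity=skimage_conn)


def segment(
    image: CalibratedImage,
    background: BackgroundModel,
    min_area_um2: float = 0.0,
    max_area_um2: float | None = None,
    connectivity: int = 8,
    fill_holes: bool = False,
) -> RegionSet:
    """Threshold, label, and area-filter an intensity channel.

    Components are the connected components of ``pixels > threshold``;
    both area bounds are inclusive.  An image with no supra-threshold
    pixel yields an empty set.
    """
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = image.pixels > background.threshold_intensity
    if fill_holes:
        mask = ndi.binary_fill_holes(mask)
    labels = label_mask(mask, connectivity)

    min_px = um2_to_px(min_area_um2, image.pixel_size) - 1e-9
    max_px = None if max_area_um2 is None else um2_to_px(max_area_um2, image.pixel_size) + 1e-9

    counts = np.bincount(labels.ravel())
    keep = np.zeros(counts.shape[0], dtype=bool)
    keep[1:] = counts[1:] >= min_px
    if max_px is not None:
        keep[1:] &= counts[1:] <= max_px
    relabeled = np.zeros_like(labels)
    new = 0
    mapping = np.zeros(counts.shape[0], dtype=labels.dtype)
    for old in range(1, counts.shape[0]):
        if keep[old]:
            new += 1
            mapping[old] = new
    relabeled = mapping[labels]
    return regions_from_labels(relabeled, image.pixel_size, connectivity)
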