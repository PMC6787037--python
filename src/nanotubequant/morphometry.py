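"""Region shape descriptors and manual cut-line separation.

Descriptors follow the conventions of the protrusion-screening workflow:

area
    pixel count × pixel_size².
length
    maximum Feret (caliper) diameter — the largest distance between any
    two points of the region.
circularity
    area / (π/4 · length²): the ratio of the object's area to that of a
    circle whose diameter equals the object's maximum Feret diameter.
    1.0 for a perfect circle, → 0 for elongated objects.
aspect ratio
    major/minor axis of the ellipse with the same second central moments
    as the region (≥ 1; higher = more elongated).
box-area ratio
    axis-aligned bounding-box area / region area (≥ 1; large for
    elongated or bent shapes).

Geometry convention — pixels as unit squares: a pixel covers a 1×1 square
centred on its integer coordinates.  The Feret diameter is therefore the
maximum pixel-centre distance plus 1 px, and the equivalent-ellipse
moments include the +1/12 per-pixel variance of a unit square.  This
keeps closed forms exact-ish for rectangles (length = √(w²+h²) ± 0.42 px)
and the aspect ratio finite even for 1-px-wide lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize

from .segmentation import Region, RegionSet, label_mask, regions_from_labels


@dataclass(frozen=True)
class ShapeDescriptors:
    """Per-region morphometry; NaN descriptors are flagged ``valid=False``."""

    area_um2: float
    length_um: float
    circularity: float
    aspect_ratio: float
    box_area_ratio: float
    n_pixels: int
    valid: bool = True

    @property
    def circularity_reported(self) -> float:
        """Circularity clipped to [0, 1.05] for reporting; filters use the raw value."""
        if math.isnan(self.circularity):
            return float("nan")
        return float(np.clip(self.circularity, 0.0, 1.05))


def max_feret_px(coords: np.ndarray) -> float:
    """Maximum pixel-centre distance of a coordinate set, via the convex hull.

    Exact (not orientation-sampled): the caliper maximum is attained at a
    pair of convex-hull vertices, over which all pairs are checked.
    Degenerate (collinear) sets fall back to all-pairs directly.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.shape[0] < 2:
        return 0.0
    if pts.shape[0] > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            pass  # collinear: all-pairs on the original points
    return float(pdist(pts).max())


def _equivalent_ellipse_axes_px(coords: np.ndarray) -> tuple[float, float]:
    """(major, minor) axis lengths of the second-moment equivalent ellipse.

    Central second moments carry the +1/12 unit-square term, so a w×h
    solid rectangle gives exactly major/minor = max(w,h)/min(w,h).
    """
    pts = np.asarray(coords, dtype=float)
    mu = pts.mean(axis=0)
    d = pts - mu
    cov = d.T @ d / pts.shape[0] + np.eye(2) / 12.0
    lam = np.linalg.eigvalsh(cov)  # ascending
    minor = 4.0 * math.sqrt(max(lam[0], 0.0))
    major = 4.0 * math.sqrt(max(lam[1], 0.0))
    return major, minor


def measure(region: Region) -> ShapeDescriptors:
    """Compute all shape descriptors for one region.

    A single-pixel region has a defined area but undefined length,
    circularity and aspect ratio; it is flagged invalid and excluded
    from summaries.
    """
    s = region.pixel_size
    n = region.n_pixels
    area = n * s**2
    if n < 2:
        return ShapeDescriptors(area, float("nan"), float("nan"), float("nan"),
                                float("nan"), n, valid=False)
    coords = region.coords
    feret_px = max_feret_px(coords) + 1.0  # unit-square edge-to-edge caliper
    length = feret_px * s
    circ = area / (math.pi / 4.0 * length**2)
    major, minor = _equivalent_ellipse_axes_px(coords)
    aspect = major / minor if minor > 0 else float("inf")
    r0, c0, r1, c1 = region.bbox
    box_ratio = (r1 - r0) * (c1 - c0) / n
    return ShapeDescriptors(area, length, circ, aspect, box_ratio, n, valid=True)


def traced_length_um(region: Region) -> float:
    """Skeleton (geodesic) length in µm — optional alternative to the Feret
    length for strongly curved protrusions.

    The region is skeletonized and the longest shortest path along the
    8-connected skeleton graph (edge weights 1 or √2 px) is returned.
    """
    s = region.pixel_size
    skel = skeletonize(region.mask.pixels)
    rr, cc = np.nonzero(skel)
    npx = rr.size
    if npx == 0:
        return 0.0
    if npx == 1:
        return s
    idx = {(r, c): i for i, (r, c) in enumerate(zip(rr.tolist(), cc.tolist()))}
    import scipy.sparse as sp

    rows, cols, w = [], [], []
    for i, (r, c) in enumerate(zip(rr.tolist(), cc.tolist())):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = idx.get((r + dr, c + dc))
                if j is not None and j > i:
                    rows.append(i)
                    cols.append(j)
                    w.append(math.hypot(dr, dc))
    g = sp.csr_matrix((w + w, (rows + cols, cols + rows)), shape=(npx, npx))
    # double sweep: farthest node from an arbitrary start, then farthest from it
    d0 = dijkstra(g, indices=0)
    a = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    d1 = dijkstra(g, indices=a)
    finite = np.where(np.isinf(d1), np.nan, d1)
    return (float(np.nanmax(finite)) + 1.0) * s


@dataclass(frozen=True)
class CutLine:
    """Polyline (in pixel coordinates) used to sever a protrusion from a body."""

    polyline: np.ndarray  # (n, 2) of (row, col)
    width: int = 1

    def __post_init__(self) -> None:
        poly = np.asarray(self.polyline, dtype=int)
        if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
            raise ValueError("polyline must be an (n>=2, 2) array of (row, col)")
        if self.width < 1:
            raise ValueError("width must be >= 1")
        object.__setattr__(self, "polyline", poly)

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        poly = self.polyline
        if (poly < 0).any() or (poly[:, 0] >= shape[0]).any() or (poly[:, 1] >= shape[1]).any():
            raise ValueError("cut line lies outside the raster bounds")
        out = np.zeros(shape, dtype=bool)
        for (r0, c0), (r1, c1) in zip(poly[:-1], poly[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            out[rr, cc] = True
        if self.width > 1:
            out = ndi.binary_dilation(out, iterations=(self.width - 1) // 2 + (self.width - 1) % 2)
            # width 1 -> none, width 2/3 -> 1 pass, width 4/5 -> 2 passes
        return out


@dataclass(frozen=True)
class CutResult:
    """Components after cutting: the largest is the cell body."""

    regions: RegionSet
    body_label: int | None

    @property
    def protrusion_candidates(self) -> tuple[Region, ...]:
        return tuple(r for r in self.regions if r.label != self.body_label)


def apply_cut_lines(cell: Region, cuts: list[CutLine], connectivity: int = 8) -> CutResult:
    """Remove cut-line pixels from a cell mask and re-label the pieces.

    The largest remaining component is tagged the body; all others are
    protrusion candidates.  A cut that disconnects nothing simply leaves
    a single component.
    """
    full = cell.full_mask()
    for cut in cuts:
        full &= ~cut.rasterize(cell.source_shape)
    labels = label_mask(full, connectivity)
    regions = regions_from_labels(labels, cell.pixel_size, connectivity)
    body = max(regions, key=lambda r: r.n_pixels).label if len(regions) else None
    return CutResult(regions, body)


_DESCRIPTOR_COLUMNS = ("area_um2", "length_um", "circularity", "aspect_ratio", "box_area_ratio")


def descriptors_to_dataframe(
    descriptors: list[ShapeDescriptors], groups: list | None = None
) -> pd.DataFrame:
    rows = []
    for i, d in enumerate(descriptors):
        row = {k: getattr(d, k) for k in _DESCRIPTOR_COLUMNS}
        row["n_pixels"] = d.n_pixels
        row["valid"] = d.valid
        row["group"] = groups[i] if groups is not None else "all"
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(descriptors: list[ShapeDescriptors], groups: list | None = None) -> pd.DataFrame:
    """Mean, sample SD (n−1) and n per descriptor per group.

    Invalid (single-pixel) regions are excluded.  A group of one reports
    SD 0 with ``single_item=True``; empty groups are omitted.  No outlier
    removal is performed.
    """
    df = descriptors_to_dataframe(descriptors, groups)
    df = df[df["valid"]]
    out = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        for col in _DESCRIPTOR_COLUMNS:
            vals = sub[col].to_numpy(dtype=float)
            out.append(
                {
                    "group": g,
                    "descriptor": col,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0,
                    "n": n,
                    "single_item": n == 1,
                }
            )
    return pd.DataFrame(out, columns=["group", "descriptor", "mean", "sd", "n", "single_item"])
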