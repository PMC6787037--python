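"""Membrane-protrusion detection by morphological opening residue.

A labeled cell mask is opened — ``n`` erosion passes followed by ``n``
dilation passes with a small square structuring element — which erases
peripheral structures thinner than the accumulated element extent while
the dilation restores the central cell body.  Subtracting the opened
body from the original mask leaves the *residue*: candidate protrusions.
Residue components are then filtered on shape (minimum area, minimum
longest axis, maximum circularity, minimum box-area ratio) to retain
thin TNT-like structures, and a cell is protrusion-positive when at
least one filtered protrusion touches its opened body.

The default element is a 3×3 square (7 passes), which captures
structures up to ≈ 2·passes·pixel_size µm wide.  A 2×2 square is also
offered; an even element has no centre pixel, so a fixed anchor rule is
applied (erode anchor top-left, dilate anchor bottom-right) which keeps
the opening anti-extensive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgio import BinaryMask, CalibratedImage
from .morphometry import measure
from .segmentation import (
    BackgroundMethod,
    BackgroundModel,
    Region,
    RegionSet,
    estimate_background,
    label_mask,
    regions_from_labels,
    segment,
)


class StructuringElement(str, Enum):
    SQUARE_2X2 = "square2x2"
    SQUARE_3X3 = "square3x3"


# scipy origin realizing the fixed anchor rule for the centreless 2x2
# element: erosion over {p, p+(0,1), p+(1,0), p+(1,1)} and its adjoint
# dilation, so erosion∘dilation is a true (anti-extensive) opening.
_SE: dict[StructuringElement, tuple[np.ndarray, tuple[int, int]]] = {
    StructuringElement.SQUARE_2X2: (np.ones((2, 2), bool), (-1, -1)),
    StructuringElement.SQUARE_3X3: (np.ones((3, 3), bool), (0, 0)),
}


@dataclass(frozen=True)
class MorphologyConfig:
    """Opening parameters for protrusion isolation.

    ``dilation_passes`` defaults to ``erosion_passes`` (a true opening);
    override only deliberately.  Passes are a pixel-space parameter — the
    captured protrusion width in µm is ≈ 2·passes·pixel_size, so users at
    other calibrations should rescale passes accordingly.
    """

    se_shape: StructuringElement = StructuringElement.SQUARE_3X3
    erosion_passes: int = 7
    dilation_passes: int | None = None

    def __post_init__(self) -> None:
        if self.erosion_passes < 1:
            raise ValueError("erosion_passes must be >= 1")
        if self.dilation_passes is not None and self.dilation_passes < 1:
            raise ValueError("dilation_passes must be >= 1")
        object.__setattr__(self, "se_shape", StructuringElement(self.se_shape))

    @property
    def effective_dilation_passes(self) -> int:
        return self.erosion_passes if self.dilation_passes is None else self.dilation_passes

    def captured_width_um(self, pixel_size: float) -> float:
        """Approximate maximum width (µm) of structures removed by the opening."""
        extent = 1 if self.se_shape is StructuringElement.SQUARE_2X2 else 2
        return self.erosion_passes * extent * pixel_size


@dataclass(frozen=True)
class ProtrusionFilterConfig:
    """Shape filters selecting TNT-like residue components.

    Defaults are the TNT screen: ≥ 20 µm² area, ≥ 10 µm longest axis,
    ≤ 0.6 circularity, ≥ 1.9 bounding-box-area/object-area.  All bounds
    inclusive.  ``min_box_area_ratio=None`` disables that filter.
    """

    min_area_um2: float = 20.0
    min_longest_axis_um: float = 10.0
    max_circularity: float = 0.6
    min_box_area_ratio: float | None = 1.9

    def __post_init__(self) -> None:
        if self.min_area_um2 <= 0 or self.min_longest_axis_um <= 0:
            raise ValueError("area and longest-axis minima must be positive")
        if not 0 < self.max_circularity <= 1:
            raise ValueError("max_circularity must be in (0, 1]")
        if self.min_box_area_ratio is not None and self.min_box_area_ratio <= 0:
            raise ValueError("min_box_area_ratio must be positive")

    def stronger_than(self, other: "ProtrusionFilterConfig") -> bool:
        """True when every bound of ``self`` is at least as strict as ``other``'s."""
        box_self = self.min_box_area_ratio or 0.0
        box_other = other.min_box_area_ratio or 0.0
        return (
            self.min_area_um2 >= other.min_area_um2
            and self.min_longest_axis_um >= other.min_longest_axis_um
            and self.max_circularity <= other.max_circularity
            and box_self >= box_other
        )


def _morph(mask: np.ndarray, se: StructuringElement, passes: int, op: str) -> np.ndarray:
    structure, origin = _SE[StructuringElement(se)]
    fn = ndi.binary_erosion if op == "erode" else ndi.binary_dilation
    return fn(mask, structure=structure, iterations=passes, origin=origin, border_value=0)


def open_mask(cell_mask: BinaryMask, cfg: MorphologyConfig = MorphologyConfig()) -> BinaryMask:
    """Morphological opening: erosion^n then dilation^n; result ⊆ input."""
    px = cell_mask.pixels
    if not px.any():
        return BinaryMask(np.zeros_like(px), cell_mask.pixel_size)
    eroded = _morph(px, cfg.se_shape, cfg.erosion_passes, "erode")
    opened = _morph(eroded, cfg.se_shape, cfg.effective_dilation_passes, "dilate")
    return BinaryMask(opened & px, cell_mask.pixel_size)


@dataclass(frozen=True)
class ProtrusionResult:
    """Per-cell outcome: opened body, residue, filtered protrusions, class.

    ``opened_body``, ``residue`` and ``protrusions`` live in the cell's
    bounding-box frame (offset by ``cell.bbox``).  ``degenerate`` marks
    cells whose body vanished entirely under erosion; they are reported
    separately and never counted positive.
    """

    cell: Region
    opened_body: BinaryMask
    residue: BinaryMask
    protrusions: RegionSet
    positive: bool
    degenerate: bool


def extract_residue(
    cell: Region, cfg: MorphologyConfig = MorphologyConfig()
) -> tuple[BinaryMask, BinaryMask, bool]:
    """(opened_body, residue, degenerate) for one cell, in its bbox frame.

    residue = cell mask minus opened body, exactly.
    """
    mask = BinaryMask(cell.mask.pixels, cell.pixel_size)
    opened = open_mask(mask, cfg)
    residue = BinaryMask(mask.pixels & ~opened.pixels, cell.pixel_size)
    degenerate = not opened.pixels.any()
    return opened, residue, degenerate


def filter_protrusions(
    residue: BinaryMask,
    filters: ProtrusionFilterConfig = ProtrusionFilterConfig(),
    connectivity: int = 8,
) -> RegionSet:
    """Residue components passing every shape filter (all bounds inclusive)."""
    labels = label_mask(residue.pixels, connectivity)
    candidates = regions_from_labels(labels, residue.pixel_size, connectivity)
    kept = []
    eps = 1e-9
    for region in candidates:
        d = measure(region)
        if not d.valid:
            continue
        if d.area_um2 < filters.min_area_um2 - eps:
            continue
        if d.length_um < filters.min_longest_axis_um - eps:
            continue
        if d.circularity > filters.max_circularity + eps:
            continue
        if filters.min_box_area_ratio is not None and d.box_area_ratio < filters.min_box_area_ratio - eps:
            continue
        kept.append(region)
    relabeled = tuple(
        Region(i + 1, r.mask, r.bbox, r.pixel_size, r.source_shape) for i, r in enumerate(kept)
    )
    return RegionSet(relabeled, residue.pixels.shape, residue.pixel_size, connectivity)


def classify_cell(opened_body: BinaryMask, protrusions: RegionSet) -> bool:
    """Positive iff ≥ 1 filtered protrusion overlaps or borders (8-neighbourhood)
    the opened cell body."""
    if not opened_body.pixels.any():
        return False
    for p in protrusions:
        touch = ndi.binary_dilation(p.full_mask(), structure=np.ones((3, 3), bool))
        if (touch & opened_body.pixels).any():
            return True
    return False


def analyze_cell(
    cell: Region,
    morph: MorphologyConfig = MorphologyConfig(),
    filters: ProtrusionFilterConfig = ProtrusionFilterConfig(),
) -> ProtrusionResult:
    """Run the full residue → filter → classify chain for one cell."""
    opened, residue, degenerate = extract_residue(cell, morph)
    protrusions = filter_protrusions(residue, filters)
    positive = False if degenerate else classify_cell(opened, protrusions)
    return ProtrusionResult(cell, opened, residue, protrusions, positive, degenerate)


def analyze_cell_channel(
    image: CalibratedImage,
    background: BackgroundModel | None = None,
    cell_min_area_um2: float = 100.0,
    morph: MorphologyConfig = MorphologyConfig(),
    filters: ProtrusionFilterConfig = ProtrusionFilterConfig(),
) -> list[ProtrusionResult]:
    """Segment a cell channel (≥ 100 µm² objects, holes filled) and classify
    every cell as protrusion-positive or -negative.

    When no background model is given, Otsu's threshold on the image
    itself is used — the default rule for cell channels.
    """
    if background is None:
        background = estimate_background([image], BackgroundMethod.OTSU)
    cells = segment(image, background, min_area_um2=cell_min_area_um2, fill_holes=True)
    return [analyze_cell(c, morph, filters) for c in cells]


def percent_positive(
    results: list[ProtrusionResult], groups: list | None = None
) -> pd.DataFrame:
    """Per-group protrusion-positive percentages.

    Degenerate cells are excluded from numerator and denominator and
    reported in ``n_degenerate``.  A group with zero valid cells is
    reported with ``percent`` NaN (missing), never as 0 %.
    """
    if groups is None:
        groups = ["all"] * len(results)
    if len(groups) != len(results):
        raise ValueError("groups must match results in length")
    df = pd.DataFrame(
        {
            "group": groups,
            "positive": [r.positive for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
    rows = []
    for g, sub in df.groupby("group", sort=True):
        valid = sub[~sub["degenerate"]]
        n = len(valid)
        n_pos = int(valid["positive"].sum())
        rows.append(
            {
                "group": g,
                "n_cells": n,
                "n_positive": n_pos,
                "n_degenerate": int(sub["degenerate"].sum()),
                "percent": 100.0 * n_pos / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_cells", "n_positive", "n_degenerate", "percent"])


def results_to_dataframe(results: list[ProtrusionResult]) -> pd.DataFrame:
    """Per-cell table (areas in µm², centroid in source-frame pixels)."""
    rows = []
    for r in results:
        cy, cx = r.cell.centroid
        rows.append(
            {
                "cell_label": r.cell.label,
                "cell_area_um2": r.cell.area_um2,
                "centroid_row": cy,
                "centroid_col": cx,
                "n_protrusions": len(r.protrusions),
                "positive": r.positive,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_label",
            "cell_area_um2",
            "centroid_row",
            "centroid_col",
            "n_protrusions",
            "positive",
            "degenerate",
        ],
    )
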