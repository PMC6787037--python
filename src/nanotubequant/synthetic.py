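"""Synthetic two-channel fluorescence scenes with exact ground truth.

The generator emulates the co-culture micrographs the pipelines were
designed for: eGFP⁺ macrophage bodies (rasterized ellipses, 150–600 µm²)
with or without thin TNT-like ribbons attached radially at the boundary;
DsRed⁺ fibroblast bodies (300–1500 µm²); and small donor puncta placed
inside, at the edge of, or outside recipient cells — all on an integer-
quantized Gaussian background with optional photon (Poisson) noise.

Default geometry sits deliberately near the analysis thresholds —
ribbon width 2 µm, length ~45 ± 15 µm, puncta 2–20 µm² — matching the
scale of real protrusion data (mean area ≈ 380 µm², mean length
≈ 45 µm), so default scenes exercise every filter where it matters.
Ribbons default to a gently curved quadratic-Bézier band (sagitta 8 % of
the chord, keeping the Feret length ≥ 0.9 × arc length); straight bands
(``protrusion_bend = 0``) have exact analytic area/length and are used
by the self-consistency checks.

Every placement is recorded in :class:`GroundTruth` in pixel
coordinates, so detection and classification can be scored exactly.
Generation is deterministic given the seed (integer-grid rasterization;
NumPy PCG64 noise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .imgio import BinaryMask, CalibratedImage, ChannelPair, ChannelTag
from .segmentation import Region


class SceneGeometryError(RuntimeError):
    """Requested objects cannot be placed in the field."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.  ``seed`` is mandatory.

    Counts default to the seeding density of the emulated co-cultures
    (≈ 40 macrophages and 12 fibroblasts per ~1 mm² field).
    """

    seed: int
    field_size: tuple[int, int] = (2048, 2048)
    pixel_size: float = 0.5  # µm per pixel
    n_macrophages: int = 40
    n_fibroblasts: int = 12
    # protrusion geometry
    protrusion_prevalence: float = 0.4
    protrusion_length_um: tuple[float, float] = (45.0, 15.0)  # mean, SD
    protrusion_min_length_um: float = 15.0
    protrusion_width_um: float = 2.0
    protrusion_bend: float = 0.08  # Bézier sagitta / chord; 0 = straight band
    macrophage_area_um2: tuple[float, float] = (150.0, 600.0)
    macrophage_aspect: tuple[float, float] = (1.0, 1.8)
    # transfer geometry
    fibroblast_area_um2: tuple[float, float] = (300.0, 1500.0)
    transfer_positive_fraction: float = 0.6
    puncta_per_positive_recipient: float = 3.0  # mean of 1 + Poisson(mean − 1)
    punctum_area_um2: tuple[float, float] = (2.0, 20.0)
    interior_puncta_counts: Sequence[int] | None = None  # explicit per-recipient override
    edge_puncta_counts: Sequence[int] | None = None
    oversize_blob_counts: Sequence[int] | None = None
    oversize_area_um2: float = 40.0
    n_outside_puncta: int = 0
    # rendering
    background: tuple[float, float] = (200.0, 20.0)  # mean, SD intensity
    foreground_intensity: float = 3000.0
    photon_noise: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.protrusion_prevalence <= 1.0:
            raise ValueError("protrusion_prevalence must be in [0, 1]")
        if self.pixel_size <= 0 or self.protrusion_width_um <= 0:
            raise ValueError("geometry must be positive")
        for counts, n in (
            (self.interior_puncta_counts, self.n_fibroblasts),
            (self.edge_puncta_counts, self.n_fibroblasts),
            (self.oversize_blob_counts, self.n_fibroblasts),
        ):
            if counts is not None and len(counts) != n:
                raise ValueError("explicit puncta count lists must have one entry per fibroblast")


@dataclass(frozen=True)
class CellTruth:
    body: Region
    protrusions: tuple[Region, ...]
    protrusion_positive: bool
    protrusion_length_um: tuple[float, ...] = ()  # sampled chord lengths


@dataclass(frozen=True)
class RecipientTruth:
    body: Region
    interior_puncta: tuple[Region, ...]
    edge_puncta: tuple[Region, ...]
    oversize_blobs: tuple[Region, ...]

    @property
    def donor_positive(self) -> bool:
        return len(self.interior_puncta) > 0


@dataclass(frozen=True)
class GroundTruth:
    cells: tuple[CellTruth, ...]
    recipients: tuple[RecipientTruth, ...]
    outside_puncta: tuple[Region, ...]
    spec: SceneSpec

    @property
    def n_protrusion_positive(self) -> int:
        return sum(c.protrusion_positive for c in self.cells)

    @property
    def n_donor_positive(self) -> int:
        return sum(r.donor_positive for r in self.recipients)

    def to_json(self, path: str | Path) -> None:
        """Summary annotation (centroids, areas, flags) as JSON."""

        def cell_entry(c: CellTruth) -> dict:
            return {
                "centroid": list(c.body.centroid),
                "body_area_um2": c.body.area_um2,
                "protrusion_positive": c.protrusion_positive,
                "n_protrusions": len(c.protrusions),
                "protrusion_lengths_um": list(c.protrusion_length_um),
            }

        def recipient_entry(r: RecipientTruth) -> dict:
            return {
                "centroid": list(r.body.centroid),
                "body_area_um2": r.body.area_um2,
                "donor_positive": r.donor_positive,
                "n_interior_puncta": len(r.interior_puncta),
                "n_edge_puncta": len(r.edge_puncta),
                "n_oversize_blobs": len(r.oversize_blobs),
            }

        payload = {
            "pixel_size": self.spec.pixel_size,
            "field_size": list(self.spec.field_size),
            "seed": self.spec.seed,
            "cells": [cell_entry(c) for c in self.cells],
            "recipients": [recipient_entry(r) for r in self.recipients],
            "n_outside_puncta": len(self.outside_puncta),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class Scene:
    cell: CalibratedImage
    donor: CalibratedImage
    recipient: CalibratedImage
    ground_truth: GroundTruth

    @property
    def pair(self) -> ChannelPair:
        return ChannelPair(self.donor, self.recipient)


def _region_from_mask(full: np.ndarray, label: int, pixel_size: float) -> Region:
    rr, cc = np.nonzero(full)
    r0, r1 = int(rr.min()), int(rr.max()) + 1
    c0, c1 = int(cc.min()), int(cc.max()) + 1
    return Region(
        label=label,
        mask=BinaryMask(full[r0:r1, c0:c1], pixel_size),
        bbox=(r0, c0, r1, c1),
        pixel_size=pixel_size,
        source_shape=tuple(full.shape),
    )


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], a: float, b: float, phi: float
) -> np.ndarray:
    """Pixels whose centres lie inside the ellipse (semi-axes a, b px, tilt phi)."""
    r0 = max(int(center[0] - a - 2), 0)
    r1 = min(int(center[0] + a + 3), shape[0])
    c0 = max(int(center[1] - a - 2), 0)
    c1 = min(int(center[1] + a + 3), shape[1])
    out = np.zeros(shape, bool)
    if r1 <= r0 or c1 <= c0:
        return out
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dy * math.cos(phi) + dx * math.sin(phi)
    v = -dy * math.sin(phi) + dx * math.cos(phi)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], r: float) -> np.ndarray:
    return _ellipse_mask(shape, center, r, r, 0.0)


def _band_mask(
    shape: tuple[int, int],
    p0: np.ndarray,
    direction: np.ndarray,
    chord_px: float,
    width_px: float,
    bend: float,
    bend_sign: float,
) -> np.ndarray:
    """Rasterize a straight or quadratic-Bézier band of the given width.

    A pixel belongs iff its centre is within width/2 of the centreline
    (flat ends for the straight case), so the straight band's area is
    chord × width px² up to rasterization ties.
    """
    u = direction / np.linalg.norm(direction)
    n = np.array([-u[1], u[0]])
    p2 = p0 + chord_px * u
    half = width_px / 2.0

    lo = np.minimum(p0, p2) - (abs(bend) * chord_px + half + 2)
    hi = np.maximum(p0, p2) + (abs(bend) * chord_px + half + 2)
    r0, c0 = int(max(lo[0], 0)), int(max(lo[1], 0))
    r1, c1 = int(min(hi[0] + 1, shape[0])), int(min(hi[1] + 1, shape[1]))
    out = np.zeros(shape, bool)
    if r1 <= r0 or c1 <= c0:
        return out
    yy, xx = np.mgrid[r0:r1, c0:c1]
    pts = np.stack([yy.ravel() - 0.0, xx.ravel() - 0.0], axis=1).astype(float)

    if bend == 0.0:
        d = pts - p0
        t = d @ u
        perp = d @ n
        inside = (t >= 0.0) & (t <= chord_px) & (np.abs(perp) <= half)
    else:
        sagitta = bend * chord_px
        mid = (p0 + p2) / 2.0
        p1 = mid + 2.0 * sagitta * bend_sign * n
        ts = np.linspace(0.0, 1.0, max(int(3 * chord_px), 16))
        curve = (
            np.outer((1 - ts) ** 2, p0) + np.outer(2 * (1 - ts) * ts, p1) + np.outer(ts**2, p2)
        )
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(curve).query(pts, k=1)
        inside = dist <= half
    out[r0:r1, c0:c1] = inside.reshape(yy.shape)
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, minimum: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= minimum:
            return float(x)
    return minimum


def _place(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    build,  # (center) -> mask or None
    margin: float,
    what: str,
    max_tries: int = 300,
) -> np.ndarray:
    """Rejection-place one object; objects keep a 2-px separation so
    8-connected components never merge."""
    shape = occupancy.shape
    if 2 * margin >= shape[0] or 2 * margin >= shape[1]:
        raise SceneGeometryError(f"{what} (extent {margin:.0f} px) cannot fit the field")
    for _ in range(max_tries):
        center = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        mask = build(center)
        if mask is None or not mask.any():
            continue
        grown = ndi.binary_dilation(mask, iterations=2)
        if not (grown & occupancy).any():
            occupancy |= mask
            return mask
    raise SceneGeometryError(f"could not place {what} after {max_tries} attempts")


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate the three channels (cell, donor, recipient) plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    s = spec.pixel_size
    shape = tuple(spec.field_size)

    occupancy_cell = np.zeros(shape, bool)
    occupancy_recipient = np.zeros(shape, bool)
    occupancy_donor = np.zeros(shape, bool)

    cell_raster = np.zeros(shape, bool)
    donor_raster = np.zeros(shape, bool)
    recipient_raster = np.zeros(shape, bool)

    # ---- macrophages (cell channel), optionally protrusion-bearing ----
    cells: list[CellTruth] = []
    for i in range(spec.n_macrophages):
        area_px = rng.uniform(*spec.macrophage_area_um2) / s**2
        q = rng.uniform(*spec.macrophage_aspect)
        a = math.sqrt(area_px * q / math.pi)
        b = math.sqrt(area_px / (q * math.pi))
        phi = rng.uniform(0.0, math.pi)
        positive = bool(rng.random() < spec.protrusion_prevalence)

        lengths: list[float] = []
        ribbon_geoms: list[tuple] = []
        if positive:
            length_um = _truncated_normal(
                rng, spec.protrusion_length_um[0], spec.protrusion_length_um[1],
                spec.protrusion_min_length_um,
            )
            lengths.append(length_um)
            t = rng.uniform(0.0, 2.0 * math.pi)
            bend_sign = 1.0 if rng.random() < 0.5 else -1.0
            ribbon_geoms.append((length_um / s, t, bend_sign))

        extent = a + (max(lengths, default=0.0) / s) + spec.protrusion_width_um / s + 4

        def build(center, a=a, b=b, phi=phi, geoms=ribbon_geoms):
            body = _ellipse_mask(shape, center, a, b, phi)
            if not body.any():
                return None
            parts = [body]
            for chord_px, t, bend_sign in geoms:
                # boundary point and outward normal of the tilted ellipse at parameter t
                local = np.array([a * math.cos(t), b * math.sin(t)])
                rot = np.array(
                    [[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]]
                )
                bp = np.asarray(center) + rot @ local
                normal_local = np.array([math.cos(t) / a, math.sin(t) / b])
                u = rot @ normal_local
                u = u / np.linalg.norm(u)
                p0 = bp - 1.5 * u  # embed the root so the ribbon stays attached
                end = p0 + (chord_px + 1.5) * u
                if not (
                    0 <= end[0] < shape[0] and 0 <= end[1] < shape[1]
                    and 0 <= p0[0] < shape[0] and 0 <= p0[1] < shape[1]
                ):
                    return None
                band = _band_mask(
                    shape, p0, u, chord_px + 1.5, spec.protrusion_width_um / s,
                    spec.protrusion_bend, bend_sign,
                )
                if not band.any():
                    return None
                parts.append(band)
            full = parts[0].copy()
            for p in parts[1:]:
                full |= p
            build.body = parts[0]
            build.ribbons = parts[1:]
            return full

        mask = _place(rng, occupancy_cell, build, extent, f"macrophage {i}")
        cell_raster |= mask
        body_region = _region_from_mask(build.body, i + 1, s)
        prot_regions = tuple(
            _region_from_mask(r & ~build.body, j + 1, s)
            for j, r in enumerate(build.ribbons)
            if (r & ~build.body).any()
        )
        cells.append(CellTruth(body_region, prot_regions, positive, tuple(lengths)))

    # ---- fibroblasts (recipient channel) ----
    recipient_bodies: list[np.ndarray] = []
    for i in range(spec.n_fibroblasts):
        area_px = rng.uniform(*spec.fibroblast_area_um2) / s**2
        q = rng.uniform(1.0, 1.8)
        a = math.sqrt(area_px * q / math.pi)
        b = math.sqrt(area_px / (q * math.pi))
        phi = rng.uniform(0.0, math.pi)

        def build(center, a=a, b=b, phi=phi):
            return _ellipse_mask(shape, center, a, b, phi)

        # generous separation so edge puncta of one cell cannot touch another
        def place_fib(center, build=build):
            m = build(center)
            if not m.any():
                return None
            grown = ndi.binary_dilation(m, iterations=12)
            if (grown & occupancy_recipient).any():
                return None
            return m

        mask = _place(rng, occupancy_recipient, place_fib, a + 14, f"fibroblast {i}")
        recipient_raster |= mask
        recipient_bodies.append(mask)

    # ---- puncta placement inside / at the edge of recipients ----
    n_fib = spec.n_fibroblasts
    if spec.interior_puncta_counts is not None:
        interior_counts = list(spec.interior_puncta_counts)
    else:
        n_pos = int(round(spec.transfer_positive_fraction * n_fib))
        order = rng.permutation(n_fib)
        interior_counts = [0] * n_fib
        mean_extra = max(spec.puncta_per_positive_recipient - 1.0, 0.0)
        for idx in order[:n_pos]:
            interior_counts[idx] = 1 + int(rng.poisson(mean_extra))
    edge_counts = list(spec.edge_puncta_counts) if spec.edge_puncta_counts is not None else [0] * n_fib
    oversize_counts = (
        list(spec.oversize_blob_counts) if spec.oversize_blob_counts is not None else [0] * n_fib
    )

    recipients: list[RecipientTruth] = []
    for i, body in enumerate(recipient_bodies):
        interior: list[Region] = []
        edge: list[Region] = []
        oversize: list[Region] = []

        def place_punctum(radius_px: float, where: str) -> Region:
            if where == "interior":
                # centre far enough in that the disk clears the boundary band
                depth = int(math.ceil(radius_px)) + 3
                allowed = ndi.binary_erosion(
                    body, structure=np.ones((3, 3), bool), iterations=depth, border_value=0
                )
            else:  # edge: centre on the ROI's outermost pixel ring
                allowed = body & ~ndi.binary_erosion(
                    body, structure=np.ones((3, 3), bool), iterations=1, border_value=0
                )
            coords = np.argwhere(allowed & ~ndi.binary_dilation(occupancy_donor, iterations=3))
            if coords.shape[0] == 0:
                raise SceneGeometryError(
                    f"no room for a {where} punctum in fibroblast {i}"
                )
            for _ in range(100):
                cy, cx = coords[rng.integers(coords.shape[0])]
                disk = _disk_mask(shape, (float(cy), float(cx)), radius_px)
                grown = ndi.binary_dilation(disk, iterations=2)
                if not (grown & occupancy_donor).any():
                    occupancy_donor[disk] = True
                    donor_raster[disk] = True
                    return _region_from_mask(disk, 1, s)
            raise SceneGeometryError(f"could not place {where} punctum in fibroblast {i}")

        for _ in range(interior_counts[i]):
            area_px = rng.uniform(*spec.punctum_area_um2) / s**2
            interior.append(place_punctum(math.sqrt(area_px / math.pi), "interior"))
        for _ in range(edge_counts[i]):
            area_px = rng.uniform(*spec.punctum_area_um2) / s**2
            edge.append(place_punctum(math.sqrt(area_px / math.pi), "edge"))
        for _ in range(oversize_counts[i]):
            area_px = spec.oversize_area_um2 / s**2
            oversize.append(place_punctum(math.sqrt(area_px / math.pi), "interior"))

        recipients.append(
            RecipientTruth(
                _region_from_mask(body, i + 1, s), tuple(interior), tuple(edge), tuple(oversize)
            )
        )

    # ---- puncta outside every recipient ----
    outside: list[Region] = []
    forbidden = ndi.binary_dilation(recipient_raster, iterations=4)
    for j in range(spec.n_outside_puncta):
        area_px = rng.uniform(*spec.punctum_area_um2) / s**2
        radius = math.sqrt(area_px / math.pi)

        def build_out(center, radius=radius):
            disk = _disk_mask(shape, center, radius)
            if (disk & forbidden).any():
                return None
            return disk

        disk = _place(rng, occupancy_donor, build_out, radius + 2, f"outside punctum {j}")
        donor_raster |= disk
        outside.append(_region_from_mask(disk, j + 1, s))

    truth = GroundTruth(tuple(cells), tuple(recipients), tuple(outside), spec)

    def render(raster: np.ndarray, sub_rng: np.random.Generator) -> np.ndarray:
        img = sub_rng.normal(spec.background[0], spec.background[1], shape)
        img = img + spec.foreground_intensity * raster
        img = np.clip(img, 0.0, None)
        if spec.photon_noise:
            img = sub_rng.poisson(img).astype(float)
        return np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    cell_img = CalibratedImage(render(cell_raster, rng), s, ChannelTag.CELL)
    donor_img = CalibratedImage(render(donor_raster, rng), s, ChannelTag.DONOR)
    recipient_img = CalibratedImage(render(recipient_raster, rng), s, ChannelTag.RECIPIENT)
    return Scene(cell_img, donor_img, recipient_img, truth)


def generate_control(spec: SceneSpec) -> CalibratedImage:
    """Donor-free control: background noise only, for threshold calibration."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.field_size)
    img = rng.normal(spec.background[0], spec.background[1], shape)
    img = np.clip(img, 0.0, None)
    if spec.photon_noise:
        img = rng.poisson(img).astype(float)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return CalibratedImage(img, spec.pixel_size, ChannelTag.DONOR)
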