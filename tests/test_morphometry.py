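import math

import numpy as np
import pytest

from nanotubequant.morphometry import (
    CutLine,
    apply_cut_lines,
    max_feret_px,
    measure,
    summarize,
    traced_length_um,
)
from conftest import disk_mask, rect_mask, region_from_mask


def all_pairs_feret(coords: np.ndarray) -> float:
    """Oracle: literal maximum over all pixel-centre pairs."""
    best = 0.0
    pts = np.asarray(coords, float)
    for i in range(len(pts)):
        d = np.hypot(pts[i + 1 :, 0] - pts[i, 0], pts[i + 1 :, 1] - pts[i, 1])
        if d.size:
            best = max(best, float(d.max()))
    return best


def moment_axes_oracle(coords: np.ndarray) -> tuple[float, float]:
    """Oracle: direct central second-moment sums with the unit-square term."""
    pts = np.asarray(coords, float)
    n = len(pts)
    mr, mc = pts[:, 0].mean(), pts[:, 1].mean()
    mrr = ((pts[:, 0] - mr) ** 2).sum() / n + 1 / 12
    mcc = ((pts[:, 1] - mc) ** 2).sum() / n + 1 / 12
    mrc = ((pts[:, 0] - mr) * (pts[:, 1] - mc)).sum() / n
    common = math.sqrt(((mrr - mcc) / 2) ** 2 + mrc**2)
    lam1 = (mrr + mcc) / 2 + common
    lam2 = (mrr + mcc) / 2 - common
    return 4 * math.sqrt(lam1), 4 * math.sqrt(max(lam2, 0.0))


def random_polyomino(rng, n_pixels):
    """Connected random blob grown pixel-by-pixel."""
    pts = {(0, 0)}
    frontier = [(0, 0)]
    while len(pts) < n_pixels:
        r, c = frontier[rng.integers(len(frontier))]
        dr, dc = [(-1, 0), (1, 0), (0, -1), (0, 1)][rng.integers(4)]
        q = (r + dr, c + dc)
        if q not in pts:
            pts.add(q)
            frontier.append(q)
    arr = np.array(sorted(pts))
    arr -= arr.min(axis=0)
    mask = np.zeros(arr.max(axis=0) + 1, bool)
    mask[arr[:, 0], arr[:, 1]] = True
    return mask


class TestMeasure:
    def test_disk_symmetric_descriptors(self):
        region = region_from_mask(disk_mask((120, 120), (60, 60), 50), 0.5)
        d = measure(region)
        assert 0.95 <= d.circularity <= 1.02
        assert 1.0 <= d.aspect_ratio <= 1.05

    @pytest.mark.parametrize("w,h", [(30, 10), (20, 20), (50, 4), (11, 7)])
    @pytest.mark.parametrize("s", [0.5, 1.0])
    def test_rectangle_closed_form(self, w, h, s):
        region = region_from_mask(rect_mask((h + 10, w + 10), 5, 5, h, w), s)
        d = measure(region)
        assert d.area_um2 == pytest.approx(w * h * s**2)
        assert abs(d.length_um - s * math.hypot(w, h)) <= 1.0 * s
        assert d.box_area_ratio == pytest.approx(1.0, rel=0.02)
        assert d.aspect_ratio == pytest.approx(max(w, h) / min(w, h), rel=0.01)

    def test_polyomino_brute_force_oracle(self, rng):
        for _ in range(40):
            mask = random_polyomino(rng, int(rng.integers(5, 120)))
            region = region_from_mask(mask, 0.5)
            d = measure(region)
            feret_oracle = all_pairs_feret(region.coords)
            assert max_feret_px(region.coords) == pytest.approx(feret_oracle, abs=1e-9)
            assert d.length_um == pytest.approx((feret_oracle + 1.0) * 0.5, abs=1e-9)
            maj, mino = moment_axes_oracle(region.coords)
            assert d.aspect_ratio == pytest.approx(maj / mino, rel=1e-9)
            area = region.n_pixels * 0.25
            assert d.circularity == pytest.approx(
                area / (math.pi / 4 * d.length_um**2), rel=1e-12
            )

    def test_feret_hull_equals_all_pairs_on_larger_regions(self, rng):
        for _ in range(5):
            mask = random_polyomino(rng, 500)
            region = region_from_mask(mask, 0.5)
            assert max_feret_px(region.coords) == pytest.approx(
                all_pairs_feret(region.coords), abs=1e-9
            )

    def test_scale_equivariance(self, rng):
        mask = random_polyomino(rng, 80)
        d1 = measure(region_from_mask(mask, 0.5))
        d2 = measure(region_from_mask(mask, 1.0))
        assert d2.length_um == pytest.approx(2 * d1.length_um)
        assert d2.area_um2 == pytest.approx(4 * d1.area_um2)
        for attr in ("circularity", "aspect_ratio", "box_area_ratio"):
            assert getattr(d2, attr) == pytest.approx(getattr(d1, attr))

    def test_rotation_tolerance_ellipse(self):
        vals = []
        for deg in (0, 15, 30, 45, 60, 75, 90):
            phi = math.radians(deg)
            yy, xx = np.mgrid[0:160, 0:160]
            dy, dx = yy - 80.0, xx - 80.0
            u = dy * math.cos(phi) + dx * math.sin(phi)
            v = -dy * math.sin(phi) + dx * math.cos(phi)
            mask = (u / 50) ** 2 + (v / 25) ** 2 <= 1
            d = measure(region_from_mask(mask, 0.5))
            vals.append((d.circularity, d.aspect_ratio))
        circ = [v[0] for v in vals]
        asp = [v[1] for v in vals]
        assert (max(circ) - min(circ)) / np.mean(circ) < 0.03
        assert (max(asp) - min(asp)) / np.mean(asp) < 0.03

    def test_rectangle_ladder_monotone(self):
        aspects, circs = [], []
        for length in (20, 40, 60, 80, 120):
            d = measure(region_from_mask(rect_mask((20, 140), 5, 5, 5, length), 0.5))
            aspects.append(d.aspect_ratio)
            circs.append(d.circularity)
        assert all(a < b for a, b in zip(aspects, aspects[1:]))
        assert all(a > b for a, b in zip(circs, circs[1:]))

    def test_single_pixel_flagged(self):
        region = region_from_mask(rect_mask((5, 5), 2, 2, 1, 1), 0.5)
        d = measure(region)
        assert not d.valid
        assert d.area_um2 == pytest.approx(0.25)
        assert math.isnan(d.length_um)

    def test_circularity_reported_is_capped(self):
        region = region_from_mask(rect_mask((6, 6), 2, 2, 2, 2), 0.5)
        d = measure(region)
        assert d.circularity_reported <= 1.05

    def test_traced_length_straight_line(self):
        region = region_from_mask(rect_mask((10, 70), 4, 5, 1, 60), 0.5)
        assert traced_length_um(region) == pytest.approx(30.0, abs=1.0)


class TestCutLines:
    def test_diametral_cut_halves_disk(self):
        mask = disk_mask((80, 80), (40, 40), 30)
        cell = region_from_mask(mask, 0.5)
        cut = CutLine(np.array([[40, 0], [40, 79]]))
        out = apply_cut_lines(cell, [cut])
        assert len(out.regions) == 2
        areas = sorted(r.n_pixels for r in out.regions)
        assert areas[0] / areas[1] > 0.9

    def test_empty_cut_list_identity(self):
        cell = region_from_mask(disk_mask((60, 60), (30, 30), 20), 0.5)
        out = apply_cut_lines(cell, [])
        assert len(out.regions) == 1
        assert out.body_label == out.regions.regions[0].label

    def test_non_disconnecting_cut(self):
        cell = region_from_mask(disk_mask((60, 60), (30, 30), 20), 0.5)
        cut = CutLine(np.array([[0, 0], [0, 59]]))  # misses the disk
        out = apply_cut_lines(cell, [cut])
        assert len(out.regions) == 1

    def test_ribbon_neck_cut_recovers_ground_truth_area(self):
        from nanotubequant import SceneSpec, generate_scene

        spec = SceneSpec(seed=21, field_size=(768, 768), n_macrophages=4,
                         n_fibroblasts=0, protrusion_prevalence=1.0,
                         protrusion_bend=0.0)
        scene = generate_scene(spec)
        checked = 0
        for ct in scene.ground_truth.cells:
            if not ct.protrusions:
                continue
            prot = ct.protrusions[0]
            # cut across the ribbon where it meets the body
            body_full = ct.body.full_mask()
            prot_full = prot.full_mask()
            union = region_from_mask(body_full | prot_full, spec.pixel_size)
            # neck: protrusion pixels adjacent to the body
            from scipy import ndimage as ndi

            near = ndi.binary_dilation(body_full, iterations=2) & prot_full
            if not near.any():
                continue
            rr, cc = np.nonzero(near)
            r0, r1 = rr.min() - 3, rr.max() + 3
            c0, c1 = cc.min() - 3, cc.max() + 3
            h, w = union.source_shape
            cut = CutLine(np.array([
                [np.clip(r0, 0, h - 1), np.clip(c0, 0, w - 1)],
                [np.clip(r1, 0, h - 1), np.clip(c1, 0, w - 1)],
            ]), width=3)
            out = apply_cut_lines(union, [cut])
            if len(out.regions) < 2:
                continue
            cand = max(out.protrusion_candidates, key=lambda r: r.n_pixels)
            assert cand.area_um2 == pytest.approx(prot.area_um2, rel=0.15)
            checked += 1
        assert checked >= 1


class TestSummarize:
    def _descriptor(self, mask):
        return measure(region_from_mask(mask, 0.5))

    def test_single_item_group(self):
        d = self._descriptor(disk_mask((40, 40), (20, 20), 10))
        table = summarize([d])
        row = table[table["descriptor"] == "area_um2"].iloc[0]
        assert row["mean"] == pytest.approx(d.area_um2)
        assert row["sd"] == 0.0
        assert row["single_item"]

    def test_identical_groups_identical_summaries(self):
        ds = [self._descriptor(disk_mask((40, 40), (20, 20), r)) for r in (8, 10, 12)]
        table = summarize(ds + ds, ["a"] * 3 + ["b"] * 3)
        a = table[table["group"] == "a"].reset_index(drop=True)
        b = table[table["group"] == "b"].reset_index(drop=True)
        assert (a["mean"] == b["mean"]).all() and (a["sd"] == b["sd"]).all()

    def test_population_mean_recovery(self, rng):
        """Areas drawn from the protrusion-scale distribution (mean 380 µm²,
        SD 145 µm²) are recovered within 3 standard errors at n = 200."""
        mean_um2, sd_um2, n = 380.0, 145.0, 200
        ds = []
        for _ in range(n):
            area = max(float(rng.normal(mean_um2, sd_um2)), 30.0)
            r_px = math.sqrt(area / 0.25 / math.pi)
            ds.append(self._descriptor(disk_mask((90, 90), (45, 45), r_px)))
        table = summarize(ds)
        row = table[table["descriptor"] == "area_um2"].iloc[0]
        se = sd_um2 / math.sqrt(n)
        assert abs(row["mean"] - mean_um2) < 3 * se + 5.0  # +5 µm² rasterization slack
        assert row["n"] == n

    def test_invalid_excluded(self):
        good = self._descriptor(disk_mask((40, 40), (20, 20), 10))
        single = self._descriptor(rect_mask((5, 5), 2, 2, 1, 1))
        table = summarize([good, single])
        assert (table["n"] == 1).all()
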