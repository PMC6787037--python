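import numpy as np
import pytest

from nanotubequant.imgio import BinaryMask
from nanotubequant.segmentation import Region
from nanotubequant.synthetic import _region_from_mask


def region_from_mask(mask: np.ndarray, pixel_size: float = 0.5, label: int = 1) -> Region:
    """Wrap a full-frame boolean mask as a Region (test helper)."""
    return _region_from_mask(np.asarray(mask, bool), label, pixel_size)


def disk_mask(shape, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def rect_mask(shape, r0, c0, h, w) -> np.ndarray:
    out = np.zeros(shape, bool)
    out[r0 : r0 + h, c0 : c0 + w] = True
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---- brute-force set-definition morphology oracle (independent of scipy) ----

OFFSETS = {
    "square3x3": [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)],
    "square2x2": [(0, 0), (0, 1), (1, 0), (1, 1)],  # erode anchor top-left
}


def oracle_erode(S: set, offsets) -> set:
    return {p for p in S if all((p[0] + dr, p[1] + dc) in S for dr, dc in offsets)}


def oracle_dilate(S: set, offsets, shape) -> set:
    out = set()
    for r, c in S:
        for dr, dc in offsets:
            q = (r + dr, c + dc)
            if 0 <= q[0] < shape[0] and 0 <= q[1] < shape[1]:
                out.add(q)
    return out


def oracle_open(mask: np.ndarray, se: str, passes: int) -> np.ndarray:
    """Literal set-definition opening: erosion^n then the adjoint dilation^n.

    For the centreless 2x2 element the erosion neighbourhood is
    {p, p+(0,1), p+(1,0), p+(1,1)} and the adjoint dilation spreads by the
    same offsets, which makes the composition a true opening.
    """
    offs = OFFSETS[se]
    S = {tuple(p) for p in np.argwhere(mask)}
    for _ in range(passes):
        S = oracle_erode(S, offs)
    for _ in range(passes):
        S = oracle_dilate(S, offs, mask.shape)
    out = np.zeros_like(mask, dtype=bool)
    for r, c in S:
        out[r, c] = True
    return out


def random_mask(rng: np.random.Generator, n: int, kind: int) -> np.ndarray:
    """Seeded test rasters: iid noise, fat blobs, or fragmented blobs."""
    from scipy.ndimage import gaussian_filter

    if kind % 3 == 0:
        return rng.random((n, n)) < 0.5
    if kind % 3 == 1:
        return gaussian_filter(rng.standard_normal((n, n)), 3.0) > 0.0
    return gaussian_filter(rng.standard_normal((n, n)), 1.5) > 0.1
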