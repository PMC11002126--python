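import numpy as np
import pytest
from scipy import ndimage as ndi

from fractalcad import KochSpec, RasterSpec, koch_snowflake, rasterize


@pytest.fixture(scope="session")
def koch_outline_1024():
    """Iteration-3 Koch snowflake outline rasterized on a 1024 px canvas."""
    shape = koch_snowflake(KochSpec(iterations=3, side_mm=20.0))
    return rasterize(shape, RasterSpec.fit(shape, 1024))


def random_blob(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """Smooth random blob: union of disks around the image center, closed
    morphologically so the boundary has no single-pixel necks."""
    mask = np.zeros((size, size), bool)
    yy, xx = np.mgrid[:size, :size]
    for _ in range(int(rng.integers(3, 7))):
        r = rng.uniform(size / 12, size / 5)
        cy = size / 2 + rng.uniform(-size / 6, size / 6)
        cx = size / 2 + rng.uniform(-size / 6, size / 6)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3), bool))
    labels, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        mask = labels == (1 + np.argmax(sizes))
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    return mask.astype(np.uint8)


def boundary_oracle(mask: np.ndarray) -> np.ndarray:
    """Brute-force boundary: foreground pixels with >= 1 background
    4-neighbor (neighbors outside the image do not count as background)."""
    m = np.asarray(mask) > 0
    out = np.zeros_like(m)
    h, w = m.shape
    for r in range(h):
        for c in range(w):
            if not m[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not m[rr, cc]:
                    out[r, c] = True
                    break
    return out.astype(np.uint8)


def box_count_oracle(mask: np.ndarray, scales) -> list[int]:
    """Brute-force nested-loop occupied-box counter on an origin grid."""
    m = np.asarray(mask) > 0
    h, w = m.shape
    counts = []
    for r in scales:
        k = 0
        for br in range(0, h, r):
            for bc in range(0, w, r):
                if m[br:br + r, bc:bc + r].any():
                    k += 1
        counts.append(k)
    return counts
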