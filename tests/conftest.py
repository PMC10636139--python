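import numpy as np
import pytest
from scipy import ndimage

from nucsize import GeneratorConfig, generate_scene


def disk_mask(radius: float, pad: int = 5) -> np.ndarray:
    """Binary raster of a filled disk (pixel-center rule)."""
    n = int(np.ceil(radius)) + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (yy**2 + xx**2 <= radius**2).astype(np.uint8)


def square_mask(side: int, pad: int = 5) -> np.ndarray:
    out = np.zeros((side + 2 * pad, side + 2 * pad), dtype=np.uint8)
    out[pad : pad + side, pad : pad + side] = 1
    return out


def dumbbell_mask(radius: float, center_distance: float) -> np.ndarray:
    """Two overlapping disks merged into one 8-connected object."""
    n = int(np.ceil(radius + center_distance)) + 5
    yy, xx = np.mgrid[0 : 2 * n, 0 : 3 * n]
    c1 = (n, n)
    c2 = (n, n + center_distance)
    d1 = (yy - c1[0]) ** 2 + (xx - c1[1]) ** 2 <= radius**2
    d2 = (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2 <= radius**2
    return (d1 | d2).astype(np.uint8)


def random_blob(rng: np.random.Generator, target_px: int = 50) -> np.ndarray:
    """A random connected blob grown by a seeded random walk."""
    size = 40
    img = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    img[r, c] = True
    while img.sum() < target_px:
        dr, dc = rng.integers(-1, 2, size=2)
        r = int(np.clip(r + dr, 1, size - 2))
        c = int(np.clip(c + dc, 1, size - 2))
        img[r, c] = True
    lab, _ = ndimage.label(img, structure=np.ones((3, 3)))
    return (lab == lab[size // 2, size // 2]).astype(np.uint8)


def brute_force_border_distance(mask: np.ndarray) -> float:
    """O(n^2) oracle: max pairwise distance between 4-connected border pixels."""
    img = mask.astype(bool)
    padded = np.pad(img, 1)
    border = padded & ~(
        np.roll(padded, 1, 0) & np.roll(padded, -1, 0)
        & np.roll(padded, 1, 1) & np.roll(padded, -1, 1)
    )
    pts = np.argwhere(border[1:-1, 1:-1]).astype(float)
    if len(pts) < 2:
        return 0.0
    best = 0.0
    for i in range(len(pts)):
        d = np.hypot(*(pts[i] - pts[i + 1 :]).T)
        if d.size:
            best = max(best, float(d.max()))
    return best


@pytest.fixture
def clean_scene():
    """A mid-sized scene with no merged objects, fixed seed."""
    return generate_scene(GeneratorConfig(n_objects=40, seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
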