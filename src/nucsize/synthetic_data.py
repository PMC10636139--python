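"""Synthetic instance masks with known ground truth.

Generates fields of elliptical "nuclei" at slide-scanner resolution with
controllable per-class diameter distributions, optional merged (touching)
pairs rendered as a single label, and a full truth table, so the
morphometry, filtering, classification and optimization modules can be
exercised end to end without any slide data.  Also generates per-image
diameter measurement tables with consensus labels, the input shape the
threshold grid search expects.

A pixel belongs to an ellipse iff its center satisfies the ellipse
inequality; all geometry uses pixel centers at integer coordinates, the
same convention the morphometry module uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from nucsize.classification import (
    DEFAULT_THRESHOLDS,
    REFERENCE_SIZES,
    NucleusClass,
)
from nucsize.threshold_optimization import ImageMeasurements, LabeledMeasurementSet

_CLASSES = (NucleusClass.SMALL.value, NucleusClass.INTERMEDIATE.value, NucleusClass.LARGE.value)


def default_diameter_bands(reference_um: float = REFERENCE_SIZES["dog"].reference_diameter_um):
    """Per-class equivalent-diameter bands implied by the default thresholds."""
    t = DEFAULT_THRESHOLDS
    return {
        "small": (t.small_lower * reference_um, t.small_upper * reference_um),
        "intermediate": (t.small_upper * reference_um, t.intermediate_upper * reference_um),
        "large": (t.intermediate_upper * reference_um, t.large_upper * reference_um),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions under which a synthetic scene is drawn.

    Defaults mirror the acquisition setting the workflow targets:
    1024x1024 px tiles at 0.25 µm/px, a balanced class mix, diameter bands
    equal to the default classification bands times the canine reference,
    mild elongation (axis ratio up to 1.6), and no merged objects.
    ``merged_pair_fraction`` is the fraction of labels rendered as two
    overlapping ellipses (touching nuclei segmented as one object).
    """

    image_size_px: tuple[int, int] = (1024, 1024)
    um_per_pixel: float = 0.25
    n_objects: int = 60
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    diameter_bands_um: dict = field(default_factory=default_diameter_bands)
    eccentricity_range: tuple[float, float] = (1.0, 1.6)
    merged_pair_fraction: float = 0.0
    seed: int = 0
    max_placement_attempts: int = 200

    def __post_init__(self) -> None:
        if self.n_objects < 1:
            raise ValueError("n_objects must be >= 1")
        if not math.isclose(sum(self.class_mix), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.merged_pair_fraction <= 1.0:
            raise ValueError("merged_pair_fraction must lie in [0, 1]")
        lo, hi = self.eccentricity_range
        if lo < 1.0 or hi < lo:
            raise ValueError("eccentricity_range must satisfy 1 <= lo <= hi")
        bands = [self.diameter_bands_um[c] for c in _CLASSES]
        for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
            if not (lo1 < hi1 <= lo2 < hi2):
                raise ValueError("diameter bands must be ordered and non-overlapping")


@dataclass(frozen=True)
class SyntheticScene:
    """A generated instance mask plus its per-object ground truth."""

    mask: np.ndarray
    truth: pd.DataFrame  # label, intended_class, true_equivalent_diameter_um,
    #                      is_merged_pair, area_px, centroid_row, centroid_col
    intended_image_class: str
    config: GeneratorConfig


def _ellipse_stamp(a: float, b: float, theta: float, jitter: tuple[float, float]) -> np.ndarray:
    """Boolean raster of an ellipse with semi-axes a, b rotated by theta."""
    half_r = abs(a * math.sin(theta)) + abs(b * math.cos(theta))
    half_c = abs(a * math.cos(theta)) + abs(b * math.sin(theta))
    hr, hc = int(math.ceil(half_r + 1)), int(math.ceil(half_c + 1))
    rows = np.arange(-hr, hr + 1)[:, None] - jitter[0]
    cols = np.arange(-hc, hc + 1)[None, :] - jitter[1]
    u = cols * math.cos(theta) + rows * math.sin(theta)
    v = -cols * math.sin(theta) + rows * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _crop(stamp: np.ndarray) -> np.ndarray:
    keep_r = np.flatnonzero(stamp.any(axis=1))
    keep_c = np.flatnonzero(stamp.any(axis=0))
    return stamp[keep_r[0] : keep_r[-1] + 1, keep_c[0] : keep_c[-1] + 1]


def _single_stamp(rng: np.random.Generator, radius_px: float, axis_ratio: float) -> np.ndarray:
    """Rasterize one ellipse, retrying sub-pixel jitter so the pixel count
    stays within 5% of the target area pi*r^2."""
    a = radius_px * math.sqrt(axis_ratio)
    b = radius_px / math.sqrt(axis_ratio)
    theta = rng.uniform(0.0, math.pi)
    target = math.pi * radius_px**2
    best, best_err = None, math.inf
    for _ in range(12):
        stamp = _ellipse_stamp(a, b, theta, tuple(rng.uniform(-0.5, 0.5, 2)))
        err = abs(int(stamp.sum()) - target) / target
        if err < best_err:
            best, best_err = stamp, err
        if err <= 0.02:
            break
    return _crop(best)


def _merged_pair_stamp(rng: np.random.Generator, radius_px: float, axis_ratio: float) -> np.ndarray:
    """Two overlapping ellipses joined end-to-end along their major axes."""
    a = radius_px * math.sqrt(axis_ratio)
    b = radius_px / math.sqrt(axis_ratio)
    theta = rng.uniform(0.0, math.pi)
    sep = rng.uniform(0.85, 0.95) * 2 * a
    dr, dc = sep * math.sin(theta), sep * math.cos(theta)
    pad = int(math.ceil(2 * a + abs(dr) + abs(dc) + 4))
    canvas = np.zeros((2 * pad + 1, 2 * pad + 1), dtype=bool)
    for frac in (-0.5, 0.5):
        stamp = _ellipse_stamp(a, b, theta, tuple(rng.uniform(-0.5, 0.5, 2)))
        cr = int(round(pad + frac * dr)) - stamp.shape[0] // 2
        cc = int(round(pad + frac * dc)) - stamp.shape[1] // 2
        canvas[cr : cr + stamp.shape[0], cc : cc + stamp.shape[1]] |= stamp
    return _crop(canvas)


_GAP_STRUCT = np.ones((5, 5), dtype=bool)  # enforces >= 2 px separation


def generate_scene(config: GeneratorConfig) -> SyntheticScene:
    """Draw one reproducible synthetic scene.

    Objects are placed uniformly at random with at least 2 px background
    between distinct labels and a 2 px image-border margin; placement is
    retried up to ``max_placement_attempts`` times per object and a
    ``RuntimeError`` is raised when packing fails (the total requested
    object area is also pre-checked against a 40% fill bound).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    mask = np.zeros((h, w), dtype=np.int32)
    forbidden = np.zeros((h, w), dtype=bool)

    n = config.n_objects
    n_merged = int(round(config.merged_pair_fraction * n))
    classes = rng.choice(len(_CLASSES), size=n, p=np.asarray(config.class_mix))
    merged_flags = np.zeros(n, dtype=bool)
    merged_flags[:n_merged] = True
    rng.shuffle(merged_flags)

    diameters = np.empty(n)
    for i, ci in enumerate(classes):
        lo, hi = config.diameter_bands_um[_CLASSES[ci]]
        diameters[i] = rng.uniform(lo, hi)
    radii_px = diameters / config.um_per_pixel / 2.0
    est_area = float(np.sum(math.pi * radii_px**2 * np.where(merged_flags, 2, 1)))
    if est_area >= 0.4 * h * w:
        raise ValueError("infeasible packing: requested object area exceeds 40% of the image")

    records = []
    for i in range(n):
        q = rng.uniform(*config.eccentricity_range)
        stamp = (
            _merged_pair_stamp(rng, radii_px[i], q)
            if merged_flags[i]
            else _single_stamp(rng, radii_px[i], q)
        )
        sh, sw = stamp.shape
        placed = False
        for _ in range(config.max_placement_attempts):
            r0 = int(rng.integers(2, h - sh - 2))
            c0 = int(rng.integers(2, w - sw - 2))
            if not (forbidden[r0 : r0 + sh, c0 : c0 + sw] & stamp).any():
                mask[r0 : r0 + sh, c0 : c0 + sw][stamp] = i + 1
                grown = ndimage.binary_dilation(np.pad(stamp, 2), structure=_GAP_STRUCT)
                gr0, gc0 = r0 - 2, c0 - 2
                forbidden[gr0 : gr0 + grown.shape[0], gc0 : gc0 + grown.shape[1]] |= grown[
                    : h - gr0, : w - gc0
                ]
                rr, cc = np.nonzero(stamp)
                records.append(
                    {
                        "label": i + 1,
                        "intended_class": _CLASSES[classes[i]],
                        "true_equivalent_diameter_um": diameters[i],
                        "is_merged_pair": bool(merged_flags[i]),
                        "area_px": int(stamp.sum()),
                        "centroid_row": float(rr.mean() + r0),
                        "centroid_col": float(cc.mean() + c0),
                    }
                )
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place object {i + 1} after bounded retries")

    truth = pd.DataFrame.from_records(records)
    counts = truth["intended_class"].value_counts()
    top = counts.max()
    # ties broken toward the larger class, same rule as the image vote
    intended = [c for c in reversed(_CLASSES) if counts.get(c, 0) == top][0]
    return SyntheticScene(mask=mask, truth=truth, intended_image_class=intended, config=config)


def generate_measurement_set(
    n_images: int,
    band_structure: dict | None = None,
    noise_sd_um: float = 0.0,
    seed: int = 0,
    reference_um: float = REFERENCE_SIZES["dog"].reference_diameter_um,
    measurements_per_image: tuple[int, int] = (20, 60),
    edge_images_per_class: int = 2,
    edge_width_ratio: float = 0.01,
) -> LabeledMeasurementSet:
    """Per-image diameter tables with consensus labels.

    Each image is assigned a class (round-robin so all three classes are
    represented, order shuffled), then 20-60 diameters are drawn uniformly
    from that class's band and perturbed with Gaussian noise of standard
    deviation ``noise_sd_um``.

    The first ``edge_images_per_class`` images of each class are
    *boundary* images whose diameters concentrate in a sliver of width
    ``edge_width_ratio`` (in reference multiples) just inside one edge of
    the class band, alternating between the lower and upper edge.  Such
    borderline cases make every class boundary identifiable: a threshold
    moved across a band edge flips the majority vote of the corresponding
    boundary image.  Without them, majority votes are insensitive to small
    threshold shifts and a grid search sees a broad plateau of equally
    scoring candidates.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    bands = band_structure if band_structure is not None else default_diameter_bands(reference_um)
    rng = np.random.default_rng(seed)
    per_class: dict[str, list[int]] = {c: [] for c in _CLASSES}
    labels = [_CLASSES[i % 3] for i in range(n_images)]
    rng.shuffle(labels)
    lo_n, hi_n = measurements_per_image
    sliver = edge_width_ratio * reference_um
    images = []
    for i, label in enumerate(labels):
        lo, hi = bands[label]
        rank = len(per_class[label])
        per_class[label].append(i)
        k = int(rng.integers(lo_n, hi_n + 1))
        if rank < edge_images_per_class:
            if rank % 2 == 0:  # lower band edge
                d = rng.uniform(lo, min(lo + sliver, hi), size=k)
            else:  # upper band edge
                d = rng.uniform(max(hi - sliver, lo), hi, size=k)
        else:
            d = rng.uniform(lo, hi, size=k)
        if noise_sd_um > 0:
            d = np.clip(d + rng.normal(0.0, noise_sd_um, size=k), 0.05, None)
        images.append(ImageMeasurements(f"img_{i:03d}", d, label))
    return LabeledMeasurementSet(images=tuple(images), reference_um=reference_um)
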