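"""Per-nucleus geometric features.

For every labeled object the module computes the pixel area, convex-hull
area, the maximum distance between border-pixel centers, the two shape
ratios whose mean defines the circularity score used for filtering, and
the equivalent circular diameter in micrometres:

* ``solidity_ratio``  r1 = A / A_hull — segmented area over convex-hull area,
* ``circle_ratio``    r2 = A / (pi * (F/2)^2) — area over the area of the
  circle whose diameter F is the maximum border-pixel distance,
* ``circularity``     c = (r1 + r2) / 2 — a perfect circle scores ~1,
* ``equivalent_diameter_um``  d = 2 * sqrt(A / pi) * s for pixel size s.

Merged (touching) nuclei segmented as one object depress both ratios well
below 1, which is what the downstream filter exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.measure import regionprops

from nucsize.mask_io import validate_instance_mask

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True, slots=True)
class RegionFeatures:
    """Measurements of one segmented nucleus."""

    label: int
    area_px: int
    area_um2: float
    hull_area_px: float
    max_border_distance_px: float
    solidity_ratio: float
    circle_ratio: float
    circularity: float
    equivalent_diameter_um: float
    centroid: tuple[float, float]  # (row, col)


def max_border_distance(object_pixels: np.ndarray) -> float:
    """Maximum Euclidean distance between border-pixel centers of an object.

    Parameters
    ----------
    object_pixels:
        ``(n, 2)`` array of (row, col) pixel coordinates of one object.
        Border pixels are those with at least one 4-neighbor outside the
        object.  Returns 0.0 for single-pixel objects.
    """
    coords = np.atleast_2d(np.asarray(object_pixels))
    if coords.shape[0] == 0:
        raise ValueError("object must contain at least one pixel")
    if coords.shape[0] == 1:
        return 0.0
    rmin, cmin = coords.min(axis=0)
    img = np.zeros((coords[:, 0].max() - rmin + 1, coords[:, 1].max() - cmin + 1), dtype=bool)
    img[coords[:, 0] - rmin, coords[:, 1] - cmin] = True
    border = img & ~ndimage.binary_erosion(img, structure=_FOUR_CONNECTED, border_value=0)
    pts = np.argwhere(border).astype(float)
    return _max_pairwise_distance(pts)


def _max_pairwise_distance(pts: np.ndarray) -> float:
    if pts.shape[0] < 2:
        return 0.0
    # the diameter of a point set is attained on its convex hull; reduce
    # first so large objects stay O(h^2) instead of O(n^2)
    if pts.shape[0] > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) sets: fall through to pdist
    return float(pdist(pts).max())


def compute_features(mask: np.ndarray, um_per_pixel: float) -> list[RegionFeatures]:
    """Measure every labeled object of an instance mask.

    Returns one :class:`RegionFeatures` per label in ascending label order.
    The convex-hull area is counted in pixels (pixels whose centers fall
    inside or on the hull), keeping both shape ratios on the same footing.
    Single-pixel objects have no defined border diameter and receive
    ``circle_ratio = 1`` by convention; they never survive the minimum-area
    filter at realistic resolutions.
    """
    if um_per_pixel <= 0:
        raise ValueError("um_per_pixel must be strictly positive")
    arr = validate_instance_mask(mask)
    out: list[RegionFeatures] = []
    for prop in regionprops(arr):
        area = int(prop.area)
        hull_area = float(prop.area_convex)
        border = prop.image & ~ndimage.binary_erosion(
            prop.image, structure=_FOUR_CONNECTED, border_value=0
        )
        feret = _max_pairwise_distance(np.argwhere(border).astype(float))
        solidity = area / hull_area
        circle_ratio = 1.0 if feret == 0.0 else area / (math.pi * (feret / 2.0) ** 2)
        diameter_um = 2.0 * math.sqrt(area / math.pi) * um_per_pixel
        out.append(
            RegionFeatures(
                label=int(prop.label),
                area_px=area,
                area_um2=area * um_per_pixel**2,
                hull_area_px=hull_area,
                max_border_distance_px=feret,
                solidity_ratio=solidity,
                circle_ratio=circle_ratio,
                circularity=(solidity + circle_ratio) / 2.0,
                equivalent_diameter_um=diameter_um,
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    out.sort(key=lambda f: f.label)
    return out


def features_to_dataframe(features: list[RegionFeatures]) -> pd.DataFrame:
    """One row per object, ready for CSV export."""
    return pd.DataFrame(
        {
            "label": [f.label for f in features],
            "area_px": [f.area_px for f in features],
            "area_um2": [f.area_um2 for f in features],
            "solidity_ratio": [f.solidity_ratio for f in features],
            "circle_ratio": [f.circle_ratio for f in features],
            "circularity": [f.circularity for f in features],
            "equivalent_diameter_um": [f.equivalent_diameter_um for f in features],
            "centroid_row": [f.centroid[0] for f in features],
            "centroid_col": [f.centroid[1] for f in features],
        }
    )
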