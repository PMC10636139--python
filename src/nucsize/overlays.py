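"""Visual audit outputs: class overlays, filter panel, class distribution.

Colors follow the reporting convention small = red, intermediate = yellow,
large = white; objects removed by the size/shape filter are shown in red on
a separate kept-vs-filtered panel.  All outputs are deterministic for fixed
inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless, deterministic rendering

import matplotlib.pyplot as plt
import numpy as np

from nucsize.classification import ImageReport, NucleusClass
from nucsize.mask_io import validate_instance_mask

_DEFAULT_CLASS_COLORS = {
    NucleusClass.SMALL: (255, 0, 0),
    NucleusClass.INTERMEDIATE: (255, 255, 0),
    NucleusClass.LARGE: (255, 255, 255),
    NucleusClass.EXCLUDED_SIZE: (128, 128, 128),
}


@dataclass(frozen=True)
class OverlaySpec:
    class_colors: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_COLORS))
    kept_color: tuple[int, int, int] = (255, 255, 255)
    filtered_color: tuple[int, int, int] = (255, 0, 0)
    opacity: float = 0.6
    fill: bool = True  # False draws outlines only


def _paint(base: np.ndarray, mask: np.ndarray, colors: dict[int, tuple], spec: OverlaySpec):
    out = base.astype(float)
    for label, color in colors.items():
        region = mask == label
        if not spec.fill:
            from scipy import ndimage

            region &= ~ndimage.binary_erosion(region)
        out[region] = (1 - spec.opacity) * out[region] + spec.opacity * np.asarray(color, float)
    return out.clip(0, 255).astype(np.uint8)


def render_overlays(
    mask: np.ndarray,
    report: ImageReport,
    out_dir: str | os.PathLike,
    image: np.ndarray | None = None,
    spec: OverlaySpec = OverlaySpec(),
) -> dict[str, str]:
    """Write the three audit images and return their paths.

    ``image`` is an optional RGB tile matching the mask's shape; without it
    objects are drawn on a neutral dark background.
    """
    import imageio.v3 as iio

    arr = validate_instance_mask(mask)
    if image is not None:
        image = np.asarray(image)
        if image.shape[:2] != arr.shape:
            raise ValueError(f"image shape {image.shape[:2]} != mask shape {arr.shape}")
        base = image[..., :3] if image.ndim == 3 else np.stack([image] * 3, axis=-1)
    else:
        base = np.full((*arr.shape, 3), 40, dtype=np.uint8)

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    class_colors = {r.label: spec.class_colors[r.nucleus_class] for r in report.per_nucleus}
    paths["classification"] = os.path.join(out_dir, "classification_overlay.png")
    iio.imwrite(paths["classification"], _paint(base, arr, class_colors, spec))

    filter_colors = {label: spec.kept_color for label in report.filter_result.kept}
    filter_colors.update(
        {label: spec.filtered_color for label, _ in report.filter_result.excluded}
    )
    paths["filtered"] = os.path.join(out_dir, "filtered_overlay.png")
    iio.imwrite(paths["filtered"], _paint(base, arr, filter_colors, spec))

    paths["distribution"] = os.path.join(out_dir, "class_distribution.png")
    fig, ax = plt.subplots(figsize=(4, 3))
    names = [c.value for c in (NucleusClass.SMALL, NucleusClass.INTERMEDIATE, NucleusClass.LARGE)]
    values = [report.class_counts[c] for c in
              (NucleusClass.SMALL, NucleusClass.INTERMEDIATE, NucleusClass.LARGE)]
    ax.bar(names, values, color=["red", "gold", "lightgray"], edgecolor="black")
    ax.set_ylabel("nuclei")
    ax.set_title(
        f"majority: {report.majority_class.value}  "
        f"(dropout {report.dropout_rate:.1%}, n={report.n_objects})"
    )
    fig.tight_layout()
    fig.savefig(paths["distribution"], dpi=100)
    plt.close(fig)
    return paths
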