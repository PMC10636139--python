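"""Nucleus- and image-level size classification.

Each kept nucleus is classified by its size ratio rho = d / r_ref, the
equivalent diameter over the species reference diameter (the mean diameter
of small non-neoplastic lymphocytes: 4.14 µm in dogs, 4.17 µm in cats).
Four multipliers of the reference delimit the classes:

    small         rho in [small_lower, small_upper)
    intermediate  rho in [small_upper, intermediate_upper)
    large         rho in [intermediate_upper, large_upper]
    excluded      rho outside [small_lower, large_upper]

The image class is the majority vote over classified nuclei; ties are
broken toward the larger class (the diagnostically conservative direction)
and flagged in the report.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from nucsize.filtering import FilterConfig, FilterResult, filter_objects
from nucsize.mask_io import DEFAULT_UM_PER_PIXEL, label_connected_components, validate_instance_mask
from nucsize.morphometry import RegionFeatures, compute_features


class NucleusClass(str, enum.Enum):
    SMALL = "small"
    INTERMEDIATE = "intermediate"
    LARGE = "large"
    EXCLUDED_SIZE = "excluded_size"


#: Vote order for tie-breaking: later entries win ties.
_SIZE_ORDER = (NucleusClass.SMALL, NucleusClass.INTERMEDIATE, NucleusClass.LARGE)


class UnclassifiableImageError(ValueError):
    """Raised when no nucleus falls into any size class, so no vote exists."""


@dataclass(frozen=True, slots=True)
class ReferenceSize:
    """Mean diameter of small non-neoplastic lymphocytes for one species."""

    species: str
    reference_diameter_um: float

    def __post_init__(self) -> None:
        if self.reference_diameter_um <= 0:
            raise ValueError("reference diameter must be positive")


REFERENCE_SIZES: dict[str, ReferenceSize] = {
    "dog": ReferenceSize("dog", 4.14),
    "cat": ReferenceSize("cat", 4.17),
}


@dataclass(frozen=True, slots=True)
class SizeThresholds:
    """Class boundaries as multipliers of the reference diameter.

    ``small_upper`` doubles as the intermediate lower bound and
    ``intermediate_upper`` as the large lower bound.
    """

    small_lower: float
    small_upper: float
    intermediate_upper: float
    large_upper: float

    def __post_init__(self) -> None:
        if not (self.small_lower < self.small_upper < self.intermediate_upper < self.large_upper):
            raise ValueError("thresholds must be strictly increasing")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.small_lower, self.small_upper, self.intermediate_upper, self.large_upper)


#: Grid-search-optimized thresholds (the workflow defaults).
DEFAULT_THRESHOLDS = SizeThresholds(1.0, 1.21, 1.5, 2.24)
#: Non-optimized alternative derived from the optimization set's box plot.
BOXPLOT_THRESHOLDS = SizeThresholds(0.994969, 1.258042, 1.420893, 2.601033)


def classify_nucleus(
    diameter_um: float, reference: ReferenceSize, thresholds: SizeThresholds = DEFAULT_THRESHOLDS
) -> NucleusClass:
    """Classify one nucleus by its equivalent diameter.

    Small and intermediate use half-open intervals [lower, upper); large is
    closed at the top so rho == large_upper is still classifiable.  A ratio
    outside [small_lower, large_upper] is excluded by size.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    rho = diameter_um / reference.reference_diameter_um
    if thresholds.small_lower <= rho < thresholds.small_upper:
        return NucleusClass.SMALL
    if thresholds.small_upper <= rho < thresholds.intermediate_upper:
        return NucleusClass.INTERMEDIATE
    if thresholds.intermediate_upper <= rho <= thresholds.large_upper:
        return NucleusClass.LARGE
    return NucleusClass.EXCLUDED_SIZE


def classify_image(
    classes: Iterable[NucleusClass],
) -> tuple[dict[NucleusClass, int], NucleusClass, bool]:
    """Majority vote over nucleus classes.

    Returns ``(class_counts, majority_class, tie_flag)``.  Size-excluded
    nuclei abstain.  Ties are broken toward the larger class and flagged.
    Raises :class:`UnclassifiableImageError` when no nucleus voted.
    """
    counts = {c: 0 for c in _SIZE_ORDER}
    for c in classes:
        if c in counts:
            counts[c] += 1
    top = max(counts.values())
    if top == 0:
        raise UnclassifiableImageError("no nucleus fell into any size class")
    winners = [c for c in _SIZE_ORDER if counts[c] == top]
    return counts, winners[-1], len(winners) > 1


@dataclass(frozen=True, slots=True)
class NucleusRecord:
    label: int
    equivalent_diameter_um: float
    size_ratio: float
    nucleus_class: NucleusClass


@dataclass(frozen=True, slots=True)
class ImageReport:
    """Full audit of one image's classification."""

    per_nucleus: tuple[NucleusRecord, ...]
    class_counts: Mapping[NucleusClass, int]
    majority_class: NucleusClass
    tie_flag: bool
    dropout_rate: float
    excluded_by_size: int
    n_objects: int
    filter_result: FilterResult
    reference: ReferenceSize
    thresholds: SizeThresholds

    def to_dict(self) -> dict:
        return {
            "majority_class": self.majority_class.value,
            "tie_flag": self.tie_flag,
            "class_counts": {c.value: n for c, n in self.class_counts.items()},
            "n_objects": self.n_objects,
            "dropout_rate": self.dropout_rate,
            "excluded_by_size": self.excluded_by_size,
            "excluded_by_filter": [
                {"label": label, "reason": reason} for label, reason in self.filter_result.excluded
            ],
            "reference": {
                "species": self.reference.species,
                "reference_diameter_um": self.reference.reference_diameter_um,
            },
            "thresholds": {
                "small_lower": self.thresholds.small_lower,
                "small_upper": self.thresholds.small_upper,
                "intermediate_upper": self.thresholds.intermediate_upper,
                "large_upper": self.thresholds.large_upper,
            },
            "per_nucleus": [
                {
                    "label": r.label,
                    "equivalent_diameter_um": r.equivalent_diameter_um,
                    "size_ratio": r.size_ratio,
                    "class": r.nucleus_class.value,
                }
                for r in self.per_nucleus
            ],
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def per_nucleus_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.per_nucleus],
                "equivalent_diameter_um": [r.equivalent_diameter_um for r in self.per_nucleus],
                "size_ratio": [r.size_ratio for r in self.per_nucleus],
                "class": [r.nucleus_class.value for r in self.per_nucleus],
            }
        )


def run_workflow(
    mask: np.ndarray,
    um_per_pixel: float = DEFAULT_UM_PER_PIXEL,
    reference: ReferenceSize = REFERENCE_SIZES["dog"],
    thresholds: SizeThresholds = DEFAULT_THRESHOLDS,
    filter_config: FilterConfig = FilterConfig(),
    is_binary: bool | None = None,
    features: list[RegionFeatures] | None = None,
) -> ImageReport:
    """Run the complete per-image pipeline on a mask.

    Composes connected-component labeling (for binary input), feature
    extraction, size/shape filtering, per-nucleus classification and the
    majority vote.  ``is_binary=None`` auto-detects: a mask whose maximum
    value is 1 is treated as binary segmentation output.
    """
    arr = np.asarray(mask)
    if is_binary is None:
        is_binary = arr.size > 0 and int(arr.max()) <= 1
    instance = label_connected_components(arr) if is_binary else validate_instance_mask(arr)
    if features is None:
        features = compute_features(instance, um_per_pixel)
    filt = filter_objects(features, filter_config)
    kept_set = set(filt.kept)
    records = []
    for f in features:
        if f.label not in kept_set:
            continue
        cls = classify_nucleus(f.equivalent_diameter_um, reference, thresholds)
        records.append(
            NucleusRecord(
                label=f.label,
                equivalent_diameter_um=f.equivalent_diameter_um,
                size_ratio=f.equivalent_diameter_um / reference.reference_diameter_um,
                nucleus_class=cls,
            )
        )
    counts, majority, tie = classify_image(r.nucleus_class for r in records)
    excluded_by_size = sum(1 for r in records if r.nucleus_class is NucleusClass.EXCLUDED_SIZE)
    return ImageReport(
        per_nucleus=tuple(records),
        class_counts=counts,
        majority_class=majority,
        tie_flag=tie,
        dropout_rate=filt.dropout_rate,
        excluded_by_size=excluded_by_size,
        n_objects=len(features),
        filter_result=filt,
        reference=reference,
        thresholds=thresholds,
    )
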