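"""Exclusion of implausible objects before size classification.

Objects are dropped when they are smaller than the minimum plausible
nucleus area, larger than an optional upper area limit, or fail the
circularity test (merged/touching nuclei segmented as one blob score well
below an isolated elliptical nucleus).  Every exclusion carries a reason so
the final report can show exactly which detections were discarded and why.
"""

from __future__ import annotations

from dataclasses import dataclass

from nucsize.morphometry import RegionFeatures

#: Valid exclusion reasons, in the order the checks are applied.
REASONS = ("too_small", "too_large", "non_elliptical")


@dataclass(frozen=True, slots=True)
class FilterConfig:
    """Size and shape limits for keeping a segmented object.

    ``min_area_um2`` rejects sub-nuclear debris (default 1 µm²);
    ``max_area_um2`` is off by default — oversized nuclei are instead
    excluded downstream when their size ratio exceeds the largest class
    band.  ``circularity_threshold`` keeps an object only when its
    circularity is strictly above the threshold (default 0.5).
    """

    min_area_um2: float = 1.0
    max_area_um2: float | None = None
    circularity_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.max_area_um2 is not None and self.max_area_um2 <= self.min_area_um2:
            raise ValueError("max_area_um2 must exceed min_area_um2")
        if not 0.0 < self.circularity_threshold < 1.0:
            raise ValueError("circularity_threshold must lie in (0, 1)")


@dataclass(frozen=True, slots=True)
class FilterResult:
    kept: tuple[int, ...]
    excluded: tuple[tuple[int, str], ...]  # (label, reason)
    dropout_rate: float

    @property
    def excluded_labels(self) -> tuple[int, ...]:
        return tuple(label for label, _ in self.excluded)


def filter_objects(
    features: list[RegionFeatures], config: FilterConfig = FilterConfig()
) -> FilterResult:
    """Partition objects into kept and excluded with per-object reasons.

    Checks are applied in a fixed order — too_small, too_large, then the
    circularity test — so the reported reason is deterministic for objects
    failing several checks.  ``dropout_rate`` is the excluded fraction over
    all input objects (0 for empty input).
    """
    kept: list[int] = []
    excluded: list[tuple[int, str]] = []
    for f in features:
        if f.area_um2 < config.min_area_um2:
            excluded.append((f.label, "too_small"))
        elif config.max_area_um2 is not None and f.area_um2 > config.max_area_um2:
            excluded.append((f.label, "too_large"))
        elif not f.circularity > config.circularity_threshold:
            excluded.append((f.label, "non_elliptical"))
        else:
            kept.append(f.label)
    total = len(features)
    rate = len(excluded) / total if total else 0.0
    return FilterResult(kept=tuple(kept), excluded=tuple(excluded), dropout_rate=rate)
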