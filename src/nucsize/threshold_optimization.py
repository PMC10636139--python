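"""Brute-force grid search over the four size-class thresholds.

Candidate threshold sets are the Cartesian product of four discretized
ranges (multipliers of the reference diameter), restricted to strictly
increasing quadruples.  Every candidate is scored by classifying each
image's measured nucleus diameters, taking the per-image majority class,
and computing the macro-averaged F1 of those majority predictions against
the expert consensus labels.  The search is exhaustive and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nucsize.classification import NucleusClass, SizeThresholds

_CLASS_CODES = {
    NucleusClass.SMALL.value: 1,
    NucleusClass.INTERMEDIATE.value: 2,
    NucleusClass.LARGE.value: 3,
}


@dataclass(frozen=True, slots=True)
class ThresholdGrid:
    """Per-parameter (lower_bound, upper_bound, step) search ranges."""

    small_lower: tuple[float, float, float] = (1.00, 1.29, 0.01)
    small_upper: tuple[float, float, float] = (1.18, 1.24, 0.01)
    intermediate_upper: tuple[float, float, float] = (1.35, 1.51, 0.01)
    large_upper: tuple[float, float, float] = (2.00, 2.59, 0.01)

    def __post_init__(self) -> None:
        for lo, hi, step in (
            self.small_lower,
            self.small_upper,
            self.intermediate_upper,
            self.large_upper,
        ):
            if step <= 0:
                raise ValueError("step must be positive")
            if lo > hi:
                raise ValueError("lower bound must not exceed upper bound")


#: Published search ranges for the four thresholds.
DEFAULT_GRID = ThresholdGrid()


@dataclass(frozen=True)
class ImageMeasurements:
    """Nucleus diameters measured on one image plus its consensus label."""

    image_id: str
    diameters_um: np.ndarray
    label: str

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_um, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError(f"image {self.image_id}: needs >= 1 diameter measurement")
        if self.label not in _CLASS_CODES:
            raise ValueError(f"image {self.image_id}: label must be one of {sorted(_CLASS_CODES)}")
        object.__setattr__(self, "diameters_um", d)


@dataclass(frozen=True)
class LabeledMeasurementSet:
    """Per-image diameter measurements with expert consensus image labels."""

    images: tuple[ImageMeasurements, ...]
    reference_um: float

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("measurement set must contain at least one image")
        if self.reference_um <= 0:
            raise ValueError("reference diameter must be positive")

    @classmethod
    def from_csv(
        cls, measurements_csv, labels_csv, reference_um: float
    ) -> "LabeledMeasurementSet":
        """Load from a (image_id, diameter_um) table and a (image_id, consensus_label) table."""
        meas = pd.read_csv(measurements_csv)
        labels = pd.read_csv(labels_csv)
        label_col = "consensus_label" if "consensus_label" in labels.columns else "label"
        by_image = dict(zip(labels["image_id"].astype(str), labels[label_col]))
        images = []
        for image_id, group in meas.groupby("image_id", sort=True):
            key = str(image_id)
            if key not in by_image:
                raise ValueError(f"no consensus label for image {key}")
            images.append(
                ImageMeasurements(key, group["diameter_um"].to_numpy(float), str(by_image[key]))
            )
        return cls(images=tuple(images), reference_um=reference_um)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        """Concatenated size ratios, per-measurement image index, truth codes."""
        ratios = np.concatenate([im.diameters_um / self.reference_um for im in self.images])
        img_idx = np.repeat(
            np.arange(len(self.images)), [im.diameters_um.size for im in self.images]
        )
        truth = np.array([_CLASS_CODES[im.label] for im in self.images])
        return ratios, img_idx, truth, len(self.images)


def _axis_values(rng: tuple[float, float, float]) -> np.ndarray:
    """Discretize (lo, hi, step) into exact decimals to avoid float drift."""
    lo, hi, step = rng
    decimals = max(0, -int(np.floor(np.log10(step) + 1e-9)))
    n = int(round((hi - lo) / step)) + 1
    return np.round(lo + step * np.arange(n), decimals)


def enumerate_candidates(grid: ThresholdGrid) -> list[SizeThresholds]:
    """All strictly-ordered threshold quadruples on the grid, lexicographic.

    Only quadruples with small_lower < small_upper < intermediate_upper <
    large_upper are valid classifiers; overlapping ranges would otherwise
    yield duplicate or degenerate candidates.
    """
    sl_v = _axis_values(grid.small_lower)
    su_v = _axis_values(grid.small_upper)
    iu_v = _axis_values(grid.intermediate_upper)
    lu_v = _axis_values(grid.large_upper)
    out = [
        SizeThresholds(sl, su, iu, lu)
        for sl in sl_v.tolist()
        for su in su_v.tolist()
        if sl < su
        for iu in iu_v.tolist()
        if su < iu
        for lu in lu_v.tolist()
        if iu < lu
    ]
    if not out:
        raise ValueError("grid contains no strictly-ordered candidate")
    return out


def _predict_codes(
    edges: tuple[float, float, float, float],
    ratios: np.ndarray,
    img_idx: np.ndarray,
    n_images: int,
) -> np.ndarray:
    """Per-image majority class codes (0 = unclassifiable, 1/2/3 = s/i/l)."""
    codes = np.digitize(ratios, edges)
    codes[ratios == edges[3]] = 3  # large band is closed at the top
    counts = np.zeros((n_images, 5), dtype=np.int64)
    np.add.at(counts, (img_idx, codes), 1)
    votes = counts[:, 1:4]
    # argmax over reversed columns breaks ties toward the larger class
    pred = 3 - votes[:, ::-1].argmax(axis=1)
    pred[votes.sum(axis=1) == 0] = 0
    return pred


def _macro_f1(truth: np.ndarray, pred: np.ndarray) -> float:
    """Macro F1 over the three size classes; unclassifiable predictions (0)
    match no class and count against recall of the true class."""
    total = 0.0
    for k in (1, 2, 3):
        tp = int(np.sum((truth == k) & (pred == k)))
        fp = int(np.sum((truth != k) & (pred == k)))
        fn = int(np.sum((truth == k) & (pred != k)))
        denom = 2 * tp + fp + fn
        total += (2 * tp / denom) if denom else 0.0
    return total / 3.0


def score_candidate(thresholds: SizeThresholds, data: LabeledMeasurementSet) -> float:
    """Macro F1 of the per-image majority classification under ``thresholds``."""
    ratios, img_idx, truth, n_images = data._arrays()
    pred = _predict_codes(thresholds.as_tuple(), ratios, img_idx, n_images)
    return _macro_f1(truth, pred)


@dataclass(frozen=True)
class OptimizationResult:
    best_thresholds: SizeThresholds
    best_f1: float
    n_candidates_evaluated: int
    ties: tuple[SizeThresholds, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "best_thresholds": dict(
                zip(
                    ("small_lower", "small_upper", "intermediate_upper", "large_upper"),
                    self.best_thresholds.as_tuple(),
                )
            ),
            "best_f1": self.best_f1,
            "n_candidates_evaluated": self.n_candidates_evaluated,
            "n_ties": len(self.ties),
            "ties": [list(t.as_tuple()) for t in self.ties],
        }


def optimize(grid: ThresholdGrid, data: LabeledMeasurementSet) -> OptimizationResult:
    """Exhaustively score every grid candidate and return the best.

    The winner is the first candidate in enumeration order achieving the
    maximal macro F1; all equally-scoring candidates are listed as ties.
    """
    candidates = enumerate_candidates(grid)
    ratios, img_idx, truth, n_images = data._arrays()
    best_f1 = -1.0
    best: SizeThresholds | None = None
    ties: list[SizeThresholds] = []
    for cand in candidates:
        pred = _predict_codes(cand.as_tuple(), ratios, img_idx, n_images)
        f1 = _macro_f1(truth, pred)
        if f1 > best_f1:
            best_f1, best, ties = f1, cand, [cand]
        elif f1 == best_f1:
            ties.append(cand)
    assert best is not None
    return OptimizationResult(
        best_thresholds=best,
        best_f1=best_f1,
        n_candidates_evaluated=len(candidates),
        ties=tuple(ties),
    )
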