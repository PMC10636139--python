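import itertools

import numpy as np
import pytest
from sklearn.metrics import f1_score

from nucsize import (
    DEFAULT_GRID,
    DEFAULT_THRESHOLDS,
    LabeledMeasurementSet,
    SizeThresholds,
    ThresholdGrid,
    enumerate_candidates,
    generate_measurement_set,
    optimize,
    score_candidate,
)
from nucsize.threshold_optimization import ImageMeasurements, _predict_codes

REF = 4.14


def _point(v):
    return (v, v, 0.01)


def _oracle_count(grid):
    """Independent nested-loop enumeration honoring the ordering constraint."""

    def axis(rng):
        lo, hi, step = rng
        return [round(lo + i * step, 2) for i in range(int(round((hi - lo) / step)) + 1)]

    return sum(
        1
        for sl, su, iu, lu in itertools.product(
            axis(grid.small_lower), axis(grid.small_upper),
            axis(grid.intermediate_upper), axis(grid.large_upper),
        )
        if sl < su < iu < lu
    )


class TestEnumeration:
    def test_single_point_ranges_give_one_candidate(self):
        grid = ThresholdGrid(_point(1.0), _point(1.2), _point(1.4), _point(2.0))
        cands = enumerate_candidates(grid)
        assert cands == [SizeThresholds(1.0, 1.2, 1.4, 2.0)]

    def test_overlapping_ranges_keep_strictly_ordered_pairs(self):
        grid = ThresholdGrid(
            small_lower=(1.18, 1.24, 0.01), small_upper=(1.18, 1.24, 0.01),
            intermediate_upper=_point(1.4), large_upper=_point(2.0),
        )
        assert len(enumerate_candidates(grid)) == 21  # 7 choose 2 ordered pairs

    def test_full_grid_count_matches_independent_oracle(self):
        assert len(enumerate_candidates(DEFAULT_GRID)) == _oracle_count(DEFAULT_GRID)

    def test_degenerate_grid_raises(self):
        with pytest.raises(ValueError):
            enumerate_candidates(ThresholdGrid(_point(1.3), _point(1.2), _point(1.4), _point(2.0)))

    def test_values_are_exact_decimals(self):
        for cand in enumerate_candidates(
            ThresholdGrid(_point(1.0), (1.18, 1.24, 0.01), _point(1.4), _point(2.0))
        ):
            assert round(cand.small_upper, 2) == cand.small_upper


class TestScoring:
    def test_perfect_separation_scores_one(self):
        data = generate_measurement_set(12, noise_sd_um=0.0, seed=3)
        assert score_candidate(DEFAULT_THRESHOLDS, data) == 1.0

    def test_total_confusion_scores_zero(self):
        # a single image labeled small whose diameters all classify large
        data = LabeledMeasurementSet(
            images=(ImageMeasurements("i0", np.full(30, 1.6 * REF), "small"),),
            reference_um=REF,
        )
        assert score_candidate(DEFAULT_THRESHOLDS, data) == 0.0

    @pytest.mark.parametrize("noise", [0.2, 0.5])
    def test_macro_f1_matches_sklearn_oracle(self, noise):
        data = generate_measurement_set(30, noise_sd_um=noise, seed=17)
        ratios, img_idx, truth, n = data._arrays()
        for cand in (DEFAULT_THRESHOLDS, SizeThresholds(1.05, 1.3, 1.45, 2.1)):
            pred = _predict_codes(cand.as_tuple(), ratios, img_idx, n)
            expected = f1_score(truth, pred, labels=[1, 2, 3], average="macro", zero_division=0)
            assert score_candidate(cand, data) == pytest.approx(expected, abs=1e-12)

    def test_unclassifiable_image_counts_against_all_classes(self):
        data = LabeledMeasurementSet(
            images=(
                ImageMeasurements("i0", np.full(10, 0.5 * REF), "small"),  # all excluded
                ImageMeasurements("i1", np.full(10, 1.1 * REF), "small"),
            ),
            reference_um=REF,
        )
        # one of two small images predicted correctly: recall 1/2, precision 1
        assert score_candidate(DEFAULT_THRESHOLDS, data) == pytest.approx((2 / 3) / 3)


@pytest.fixture(scope="module")
def data():
    return generate_measurement_set(15, noise_sd_um=0.0, seed=11)


class TestOptimize:
    def test_single_candidate_grid_returns_it(self, data):
        grid = ThresholdGrid(_point(1.0), _point(1.21), _point(1.5), _point(2.24))
        res = optimize(grid, data)
        assert res.best_thresholds == SizeThresholds(1.0, 1.21, 1.5, 2.24)
        assert res.n_candidates_evaluated == 1
        assert res.best_f1 == score_candidate(res.best_thresholds, data)

    def test_recovers_band_thresholds_on_reduced_grid(self, data):
        grid = ThresholdGrid(
            small_lower=(1.00, 1.05, 0.01), small_upper=(1.18, 1.24, 0.01),
            intermediate_upper=(1.45, 1.51, 0.01), large_upper=(2.20, 2.30, 0.01),
        )
        res = optimize(grid, data)
        for got, true in zip(res.best_thresholds.as_tuple(), (1.0, 1.21, 1.5, 2.24)):
            assert abs(got - true) <= 0.01 + 1e-9

    def test_duplicating_every_image_leaves_result_unchanged(self, data):
        grid = ThresholdGrid(
            small_lower=_point(1.0), small_upper=(1.18, 1.24, 0.01),
            intermediate_upper=(1.45, 1.51, 0.01), large_upper=_point(2.24),
        )
        doubled = LabeledMeasurementSet(images=data.images * 2, reference_um=data.reference_um)
        assert optimize(grid, data).best_thresholds == optimize(grid, doubled).best_thresholds

    def test_optimum_dominates_random_grid_members(self, data, rng):
        grid = ThresholdGrid(
            small_lower=(1.00, 1.10, 0.01), small_upper=(1.18, 1.24, 0.01),
            intermediate_upper=(1.35, 1.51, 0.01), large_upper=(2.00, 2.30, 0.01),
        )
        res = optimize(grid, data)
        cands = enumerate_candidates(grid)
        for idx in rng.integers(0, len(cands), size=100):
            assert res.best_f1 >= score_candidate(cands[int(idx)], data)

    def test_deterministic_given_grid_and_data(self, data):
        grid = ThresholdGrid(
            small_lower=_point(1.0), small_upper=(1.18, 1.24, 0.01),
            intermediate_upper=(1.45, 1.51, 0.01), large_upper=_point(2.24),
        )
        assert optimize(grid, data) == optimize(grid, data)


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        data = generate_measurement_set(6, seed=2)
        import pandas as pd

        meas = pd.DataFrame(
            [
                {"image_id": im.image_id, "diameter_um": d}
                for im in data.images
                for d in im.diameters_um
            ]
        )
        labels = pd.DataFrame(
            [{"image_id": im.image_id, "consensus_label": im.label} for im in data.images]
        )
        mpath, lpath = tmp_path / "m.csv", tmp_path / "l.csv"
        meas.to_csv(mpath, index=False)
        labels.to_csv(lpath, index=False)
        loaded = LabeledMeasurementSet.from_csv(mpath, lpath, REF)
        assert len(loaded.images) == 6
        for a, b in zip(loaded.images, sorted(data.images, key=lambda im: im.image_id)):
            assert a.label == b.label
            assert np.allclose(np.sort(a.diameters_um), np.sort(b.diameters_um))
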