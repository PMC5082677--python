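"""Dimensionless quantities, Gaussian-weighted aggregation, rescaling,
colonization index, and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilmarch import (
    aggregate,
    classify_strain,
    colonization_index,
    coverage_fraction,
    gaussian_weights,
    linear_ratio,
    normalized_fractal,
    rescale_across_strains,
)
from biofilmarch.indices import aggregation_table, classify_index, colonization_report

# hand-computed N=3, λ=0.5 weights: μ=2, σ²=2/3, w′=exp(-3(j-2)²/4),
# w1 = e^(-3/4) / (1 + 2e^(-3/4))
W3 = np.array([0.24289531, 0.51420938, 0.24289531])


class TestDimensionlessQuantities:
    @pytest.mark.parametrize("a,total,expect", [(2500, 10000, 0.25), (7, 7, 1.0), (0, 5, 0.0)])
    def test_coverage_fraction(self, a, total, expect):
        assert coverage_fraction(a, total) == pytest.approx(expect)

    def test_coverage_rejects_area_above_total(self):
        with pytest.raises(ValueError):
            coverage_fraction(11, 10)

    def test_full_square_slice_scores_one(self):
        # pattern = slice: A = a, ideal boundary P = 4√a
        a = 10000.0
        assert linear_ratio(a, 4 * np.sqrt(a), a) == pytest.approx(1.0)

    def test_half_width_square_scores_half(self):
        # 50×50 solid square (ideal boundary 200) inside a 100×100 slice
        assert linear_ratio(2500.0, 200.0, 10000.0) == pytest.approx(0.5)

    def test_empty_pattern_is_zero_by_convention(self):
        assert linear_ratio(0.0, 0.0, 100.0) == 0.0

    def test_positive_area_with_zero_perimeter_rejected(self):
        with pytest.raises(ValueError):
            linear_ratio(10.0, 0.0, 100.0)

    def test_linear_ratio_clamped_with_raw_available(self):
        # a coarse contour makes the discrete ratio exceed 1 slightly
        assert linear_ratio(10000.0, 350.0, 10000.0) == 1.0
        assert linear_ratio(10000.0, 350.0, 10000.0, clamp=False) > 1.0

    @pytest.mark.parametrize("db,expect", [(2.0, 1.0), (1.0, 0.5), (0.0, 0.0)])
    def test_normalized_fractal(self, db, expect):
        assert normalized_fractal(db) == pytest.approx(expect)

    def test_normalized_fractal_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            normalized_fractal(2.5)


class TestGaussianWeights:
    def test_single_slice_weight_one(self):
        ws = gaussian_weights(1)
        np.testing.assert_allclose(ws.weights, [1.0])

    def test_two_slices_split_evenly(self):
        np.testing.assert_allclose(gaussian_weights(2).weights, [0.5, 0.5])

    def test_three_slices_match_hand_computation(self):
        ws = gaussian_weights(3)
        assert ws.mu == pytest.approx(2.0)
        assert ws.sigma == pytest.approx(np.sqrt(2 / 3))
        np.testing.assert_allclose(ws.weights, W3, atol=1e-8)

    @given(st.integers(1, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_weights_sum_to_one_and_are_symmetric(self, n):
        ws = gaussian_weights(n)
        assert ws.weights.sum() == pytest.approx(1.0)
        assert (ws.weights >= 0).all()
        np.testing.assert_allclose(ws.weights, ws.weights[::-1], atol=1e-12)

    def test_off_center_lambda_shifts_peak(self):
        ws = gaussian_weights(9, lam=0.25)  # μ = 2.5: weight peaks low in the stack
        assert ws.weights.argmax() <= 2

    def test_literal_sigma_variant_differs(self):
        std = gaussian_weights(5).weights
        lit = gaussian_weights(5, literal_sigma=True).weights
        assert not np.allclose(std, lit)
        assert lit.sum() == pytest.approx(1.0)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError):
            gaussian_weights(0)


class TestAggregation:
    def test_max_and_mean(self):
        s = [0.1, 0.3, 0.2]
        assert aggregate(s, "max") == pytest.approx(0.3)
        assert aggregate(s, "mean") == pytest.approx(0.2)

    def test_weighted_matches_hand_computation(self):
        expected = float(W3 @ [0.1, 0.3, 0.2])  # ≈ 0.2271
        assert aggregate([0.1, 0.3, 0.2], "weighted") == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(0.2271, abs=1e-4)

    @pytest.mark.parametrize("op", ["max", "mean", "weighted"])
    def test_constant_series_fixed_point(self, op):
        assert aggregate([0.4] * 7, op) == pytest.approx(0.4)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_mean_and_weighted_never_exceed_max(self, series):
        mx = aggregate(series, "max")
        assert aggregate(series, "mean") <= mx + 1e-12
        assert aggregate(series, "weighted") <= mx + 1e-12

    def test_weight_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate([0.1, 0.2], "weighted", weights=gaussian_weights(3))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], "mean")


def _toy_table():
    series = {
        "s1": {"coverage": np.array([0.2, 0.4]), "linear_ratio": np.array([0.1, 0.1]), "fractal": np.array([0.5, 0.7])},
        "s2": {"coverage": np.array([0.4, 0.8]), "linear_ratio": np.array([0.2, 0.4]), "fractal": np.array([0.9, 0.9])},
    }
    return aggregation_table(series)


class TestRescaling:
    def test_column_divided_by_its_maximum(self):
        table = pd.DataFrame(
            {
                "strain": ["a", "b", "c"],
                "quantity": ["coverage"] * 3,
                "operator": ["mean"] * 3,
                "value": [0.2, 0.4, 0.8],
            }
        )
        out = rescale_across_strains(table)
        np.testing.assert_allclose(out["rescaled"], [0.25, 0.5, 1.0])

    def test_each_column_max_is_exactly_one(self):
        out = rescale_across_strains(_toy_table())
        for _, grp in out.groupby(["quantity", "operator"]):
            assert grp["rescaled"].max() == 1.0

    def test_single_strain_rescales_to_all_ones(self):
        table = _toy_table()
        out = rescale_across_strains(table[table["strain"] == "s1"].copy())
        np.testing.assert_allclose(out["rescaled"], 1.0)

    def test_idempotent(self):
        once = rescale_across_strains(_toy_table())
        again = rescale_across_strains(once.drop(columns="rescaled").assign(value=once["rescaled"]))
        np.testing.assert_allclose(once["rescaled"], again["rescaled"])

    def test_zero_column_rejected(self):
        table = pd.DataFrame(
            {"strain": ["a", "b"], "quantity": ["coverage"] * 2, "operator": ["max"] * 2, "value": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            rescale_across_strains(table)


class TestColonizationIndex:
    @pytest.mark.parametrize("triple,expect", [((1, 1, 1), 1.0), ((0, 0, 0), 0.0), ((0.3, 0.6, 0.9), 0.6)])
    def test_mean_of_three(self, triple, expect):
        assert colonization_index(np.array(triple)) == pytest.approx(expect)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            colonization_index(np.array([0.5, 1.2, 0.3]))

    @pytest.mark.parametrize(
        "ic,expect",
        [
            ((0.410930, 0.423024, 0.425755), "porous"),  # reticulate cyanobacterium
            ((0.576164, 0.513284, 0.507068), "intermediate"),  # green alga, middling mat
            ((0.988081, 1.0, 0.996889), "compact"),  # dense gelatinous mat
        ],
    )
    def test_reference_strains_classified(self, ic, expect):
        label, per_op, unanimous = classify_strain(dict(zip(("max", "mean", "weighted"), ic)))
        assert label == expect
        assert unanimous

    def test_boundary_values(self):
        assert classify_index(0.5) == "intermediate"  # 0.5 opens the intermediate band
        assert classify_index(0.7) == "compact"  # 0.7 opens the compact band
        assert classify_index(0.49999) == "porous"

    def test_majority_vote_on_disagreement(self):
        label, _, unanimous = classify_strain({"max": 0.49, "mean": 0.51, "weighted": 0.52})
        assert label == "intermediate" and not unanimous

    def test_report_shape_and_labels(self):
        out = rescale_across_strains(_toy_table())
        rep = colonization_report(out)
        assert set(rep["strain"]) == {"s1", "s2"}
        assert rep.set_index("strain").loc["s2", "label"] == "compact"  # maximal strain: all ones
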