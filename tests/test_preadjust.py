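"""Test-day adjustment: Legendre bases, model recovery, weights, terciles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from farmbayes.preadjust import (
    AdjustmentConfig,
    AdjustmentFit,
    adjust_and_average,
    classify_environment,
    fit_testday_adjustment,
    garrick_weight,
    legendre_basis,
)
from .conftest import make_td_records


# ---------------------------------------------------------------------- #
class TestLegendreBasis:
    def test_closed_form_values_at_midpoint_and_endpoint(self):
        B = legendre_basis([155.0, 305.0], 3, (5.0, 305.0))
        np.testing.assert_allclose(B[0], [1.0, 0.0, -0.5, 0.0], atol=1e-12)
        np.testing.assert_allclose(B[1], [1.0, 1.0, 1.0, 1.0], atol=1e-12)

    def test_columns_nearly_orthogonal_on_even_grid(self):
        # Legendre polynomials are orthogonal in L2[-1,1]; on an even grid the
        # Gram matrix approximates the integral, so off-diagonals are small
        grid = np.linspace(5.0, 305.0, 305)
        B = legendre_basis(grid, 3, (5.0, 305.0))
        gram = B.T @ B / len(grid)
        exact_diag = 1.0 / (2 * np.arange(4) + 1)  # int P_k^2 / 2
        np.testing.assert_allclose(np.diag(gram), exact_diag, rtol=0.02)
        # exact off-diagonals are 0; the grid sum carries O(1/n) error
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 2.0 / len(grid)

    def test_out_of_range_dim_rejected_with_offenders(self):
        with pytest.raises(ValueError, match="400"):
            legendre_basis([100.0, 400.0], 3, (5.0, 305.0))


# ---------------------------------------------------------------------- #
class TestGarrickWeight:
    def test_single_record_weight_is_exactly_one(self):
        assert garrick_weight(1, 0.19, 0.60) == 1.0
        assert garrick_weight(1, 0.4, 0.5) == 1.0

    def test_reference_evaluation_r18(self):
        # 18*0.81 / (1 + 17*0.60 - 18*0.19) = 14.58 / 7.78
        assert garrick_weight(18, 0.19, 0.60) == pytest.approx(1.8740, abs=5e-5)

    def test_many_records_limit(self):
        w = garrick_weight(10**7, 0.19, 0.60)
        assert w == pytest.approx((1 - 0.19) / (0.60 - 0.19), rel=1e-4)

    @given(
        r=st.integers(1, 200),
        h2=st.floats(0.05, 0.45),
        gap=st.floats(0.01, 0.4),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_nondecreasing_in_record_count(self, r, h2, gap):
        t = min(h2 + gap, 0.95)
        assert garrick_weight(r + 1, h2, t) >= garrick_weight(r, h2, t) - 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            garrick_weight(0, 0.19, 0.60)
        with pytest.raises(ValueError):
            garrick_weight(5, 0.7, 0.60)


# ---------------------------------------------------------------------- #
class TestAdjustmentFit:
    def test_null_data_gives_null_coefficients(self):
        records = make_td_records(n_cows=200, records_per_cow=8, noise_sd=0.5, seed=1)
        fit = fit_testday_adjustment(records)
        n = len(records)
        se_bound = 3 * 0.5 / np.sqrt(n / 20)  # crude 3-SE bound per coefficient
        non_intercept = fit.coef.drop("intercept")
        assert np.abs(non_intercept).max() < max(se_bound, 0.6)
        assert fit.coef["intercept"] == pytest.approx(10.0, abs=0.3)

    def test_recovers_known_lactation_curves(self):
        curve = {1: (2.0, -1.0, 0.5), 2: (1.0, 0.5, -0.3), 3: (0.0, 0.0, 0.0)}
        records = make_td_records(
            n_cows=300, records_per_cow=12, curve=curve, noise_sd=0.3, seed=2,
            cdc_effects=np.array([0.0, 1.0, -1.0, 0.5]),
        )
        fit = fit_testday_adjustment(records)
        for parity, coefs in curve.items():
            for k, truth in enumerate(coefs, start=1):
                est = fit.coef[f"parity[{parity}]:P{k}"]
                assert est == pytest.approx(truth, abs=0.25), (parity, k)

    def test_invariant_to_dataset_replication(self):
        records = make_td_records(n_cows=80, seed=3)
        fit1 = fit_testday_adjustment(records)
        fit2 = fit_testday_adjustment(pd.concat([records, records], ignore_index=True))
        pd.testing.assert_series_equal(fit1.coef, fit2.coef, atol=1e-8, rtol=0)

    def test_rank_deficient_design_identified(self):
        records = make_td_records(n_cows=60, seed=4)
        records["season"] = records["cdc_id"].str.replace("cdc", "s")  # alias cdc
        with pytest.raises(ValueError, match="confounded"):
            fit_testday_adjustment(records)


# ---------------------------------------------------------------------- #
class TestAdjustAndAverage:
    def test_zero_fit_averages_raw_records(self):
        records = pd.DataFrame(
            dict(cow_id=["a", "a", "b"], farm_id=["f", "f", "f"],
                 cdc_id=["c", "c", "c"], season=["s", "s", "s"],
                 parity=[1, 1, 1], dim=[50.0, 100.0, 80.0]))
        records["yield"] = [5.0, 7.0, 4.0]
        out = adjust_and_average(records, AdjustmentFit.null())
        a = out.set_index("cow_id")
        assert a.loc["a", "adjusted_mean"] == pytest.approx(6.0)
        assert a.loc["a", "n_records"] == 2
        assert a.loc["b", "adjusted_mean"] == pytest.approx(4.0)
        assert a.loc["b", "n_records"] == 1

    def test_known_cdc_offset_removed(self):
        records = make_td_records(
            n_cows=240, records_per_cow=8, seed=5,
            cdc_effects=np.array([0.0, 2.0, 0.0, 0.0]), noise_sd=0.3,
        )
        fit = fit_testday_adjustment(records)
        adjusted = adjust_and_average(records, fit)
        raw = records.groupby("cow_id")["yield"].mean()
        merged = adjusted.set_index("cow_id").join(raw.rename("raw"))
        shift = (merged["raw"] - merged["adjusted_mean"]).groupby(
            merged["cdc_id"]
        ).mean()
        assert shift["cdc1"] - shift["cdc0"] == pytest.approx(2.0, abs=0.3)

    def test_unseen_level_rejected(self):
        records = make_td_records(n_cows=60, seed=6)
        fit = fit_testday_adjustment(records)
        other = records.copy()
        other.loc[0, "cdc_id"] = "cdc99"
        with pytest.raises(KeyError, match="cdc99"):
            adjust_and_average(other, fit)

    def test_null_fit_preserves_grand_mean(self):
        records = make_td_records(n_cows=50, seed=7)
        out = adjust_and_average(records, AdjustmentFit.null())
        per_cow_raw = records.groupby("cow_id")["yield"].mean().sort_index()
        np.testing.assert_allclose(out.sort_values("cow_id")["adjusted_mean"],
                                   per_cow_raw, rtol=1e-12)


# ---------------------------------------------------------------------- #
class TestEnvironmentClasses:
    @staticmethod
    def _fit_with(scores: dict, cdc_of, farm_of):
        fit = AdjustmentFit.null()
        fit.levels["cdc"] = sorted({c for c in cdc_of.values()})
        fit.farm_effects = pd.Series(scores)
        return fit

    def test_three_cows_split_low_medium_high(self):
        cows = pd.DataFrame(dict(cow_id=["a", "b", "c"],
                                 farm_id=["f1", "f2", "f3"],
                                 cdc_id=["c0", "c0", "c0"]))
        fit = AdjustmentFit.null()
        fit.levels["cdc"] = ["c0"]
        fit.farm_effects = pd.Series({"f1": -1.0, "f2": 0.0, "f3": 1.0})
        cls = classify_environment(fit, cows)
        assert list(cls) == ["low", "medium", "high"]

    def test_class_sizes_differ_by_at_most_one(self):
        n = 10
        cows = pd.DataFrame(dict(cow_id=[f"c{i}" for i in range(n)],
                                 farm_id=[f"f{i}" for i in range(n)],
                                 cdc_id=["c0"] * n))
        fit = AdjustmentFit.null()
        fit.levels["cdc"] = ["c0"]
        fit.farm_effects = pd.Series({f"f{i}": float(i % 4) for i in range(n)})
        sizes = classify_environment(fit, cows).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_ties_resolved_by_stable_cow_order(self):
        n = 6
        cows = pd.DataFrame(dict(cow_id=[f"c{i}" for i in range(n)],
                                 farm_id=["f0"] * n, cdc_id=["c0"] * n))
        fit = AdjustmentFit.null()
        fit.levels["cdc"] = ["c0"]
        fit.farm_effects = pd.Series({"f0": 0.0})
        cls = classify_environment(fit, cows)
        assert list(cls) == ["low", "low", "medium", "medium", "high", "high"]

    def test_missing_farm_prediction_rejected(self):
        cows = pd.DataFrame(dict(cow_id=["a"], farm_id=["nowhere"], cdc_id=["c0"]))
        fit = AdjustmentFit.null()
        fit.levels["cdc"] = ["c0"]
        with pytest.raises(KeyError, match="nowhere"):
            classify_environment(fit, cows)
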