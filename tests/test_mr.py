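"""Wald ratios, IVW fixed-effects combination, and the weighted median."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrkinetics import (MRConfig, ValidationError, WaldEstimate, forest_table,
                        ivw_fixed_effects, run_two_sample_mr, wald_ratio,
                        weighted_median, weighted_median_point)


def _we(ratio, se, snp="rs0"):
    return WaldEstimate(snp_id=snp, ratio=ratio, se=se)


class TestWaldRatio:
    def test_cyp1a1_row_first_order(self):
        # beta_y/beta_x and |se_y/beta_x| on the CYP1A1 coffee/cigarettes row
        w = wald_ratio(0.09, 0.01, -0.2125, 0.0964, snp_id="rs2470893")
        assert w.ratio == pytest.approx(-2.3611, abs=1e-4)
        assert w.se == pytest.approx(1.0711, abs=1e-4)
        assert w.weight == pytest.approx(w.se**-2)

    def test_zero_outcome_beta(self):
        w = wald_ratio(-0.05, 0.01, 0.0, 0.08)
        assert w.ratio == 0.0
        assert w.se == pytest.approx(0.08 / 0.05)

    def test_second_order_reduces_to_first_when_se_x_zero(self):
        a = wald_ratio(0.09, 0.0, -0.2125, 0.0964, order="first")
        b = wald_ratio(0.09, 0.0, -0.2125, 0.0964, order="second")
        assert a.se == pytest.approx(b.se)

    def test_second_order_adds_exposure_term(self):
        b = wald_ratio(0.09, 0.01, -0.2125, 0.0964, order="second")
        expected = np.sqrt(0.0964**2 / 0.09**2 + 0.2125**2 * 0.01**2 / 0.09**4)
        assert b.se == pytest.approx(expected)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ZeroDivisionError, match="rs9"):
            wald_ratio(0.0, 0.01, 0.1, 0.1, snp_id="rs9")

    def test_negative_se_raises(self):
        with pytest.raises(ValidationError):
            wald_ratio(0.1, -0.01, 0.1, 0.1)


class TestIVW:
    def test_single_estimate_passes_through(self):
        res = ivw_fixed_effects([_we(-2.0, 0.5)])
        assert res.estimate == pytest.approx(-2.0)
        assert res.se == pytest.approx(0.5)
        assert res.n_snps == 1

    def test_two_equal_estimates_shrink_se_by_sqrt2(self):
        res = ivw_fixed_effects([_we(1.2, 0.4, "a"), _we(1.2, 0.4, "b")])
        assert res.estimate == pytest.approx(1.2)
        assert res.se == pytest.approx(0.4 / np.sqrt(2))

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            ivw_fixed_effects([])

    def test_ci_and_p_consistency(self):
        res = ivw_fixed_effects([_we(-2.0, 0.5)])
        assert res.ci_low == pytest.approx(res.estimate - 1.96 * res.se)
        assert res.ci_high == pytest.approx(res.estimate + 1.96 * res.se)
        assert (res.p < 0.05) == (abs(res.estimate) > 1.96 * res.se)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.05, 3)),
                    min_size=1, max_size=8))
    def test_matches_naive_summation_and_is_convex(self, pairs):
        ests = [_we(r, s, f"rs{i}") for i, (r, s) in enumerate(pairs)]
        res = ivw_fixed_effects(ests)
        num = sum(s**-2 * r for r, s in pairs)
        den = sum(s**-2 for _, s in pairs)
        assert res.estimate == pytest.approx(num / den, abs=1e-12)
        assert min(r for r, _ in pairs) - 1e-12 <= res.estimate <= max(r for r, _ in pairs) + 1e-12

    def test_invariant_to_order_and_weight_rescaling(self):
        ests = [_we(-2.4, 0.9, "a"), _we(0.4, 0.3, "b"), _we(1.0, 1.5, "c")]
        forward = ivw_fixed_effects(ests).estimate
        backward = ivw_fixed_effects(ests[::-1]).estimate
        scaled = ivw_fixed_effects([_we(e.ratio, e.se * 3.0, e.snp_id) for e in ests]).estimate
        assert forward == pytest.approx(backward)
        assert forward == pytest.approx(scaled)


class TestWeightedMedian:
    def test_equal_weights_hand_example(self):
        # three equal-weight ratios {-3, 1, 2}: mid-weights {1/6, 1/2, 5/6},
        # interpolation at 1/2 lands exactly on the middle ratio
        ests = [_we(-3, 1.0, "a"), _we(1, 1.0, "b"), _we(2, 1.0, "c")]
        res = weighted_median(ests, n_boot=10, seed=1)
        assert res.estimate == pytest.approx(1.0)

    def test_single_estimate(self):
        res = weighted_median([_we(0.7, 0.2)], n_boot=10, seed=1)
        assert res.estimate == pytest.approx(0.7)

    def test_equal_weights_match_interpolated_median_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            r = rng.normal(size=5)
            est = weighted_median_point(r, np.ones(5))
            # oracle: equal-weight mid-quantile interpolation at p = 0.5
            expect = float(np.interp(0.5, (np.arange(5) + 0.5) / 5, np.sort(r)))
            assert est == pytest.approx(expect)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.1, 2)),
                    min_size=3, max_size=6),
           st.integers(0, 5), st.floats(0.01, 3))
    def test_monotone_in_any_single_ratio(self, pairs, idx, bump):
        ests = [_we(r, s, f"rs{i}") for i, (r, s) in enumerate(pairs)]
        idx = idx % len(ests)
        bumped = list(ests)
        bumped[idx] = _we(ests[idx].ratio + bump, ests[idx].se, ests[idx].snp_id)
        before = weighted_median_point(np.array([e.ratio for e in ests]),
                                       np.array([e.weight for e in ests]))
        after = weighted_median_point(np.array([e.ratio for e in bumped]),
                                      np.array([e.weight for e in bumped]))
        assert after >= before - 1e-12

    def test_bootstrap_reproducible_bit_for_bit(self):
        ests = [_we(-2.4, 0.9, "a"), _we(0.4, 0.3, "b"), _we(1.0, 1.5, "c")]
        a = weighted_median(ests, n_boot=500, seed=9)
        b = weighted_median(ests, n_boot=500, seed=9)
        assert a.se == b.se and a.estimate == b.estimate

    def test_bootstrap_se_converges_with_replicates(self):
        ests = [_we(-2.4, 0.9, "a"), _we(0.4, 0.3, "b"), _we(1.0, 1.5, "c")]
        spread = []
        for n_boot in (50, 5000):
            ses = [weighted_median(ests, n_boot=n_boot, seed=s).se for s in range(8)]
            spread.append(np.std(ses))
        assert spread[1] < spread[0] / 2  # ~ n_boot^(-1/2) shrinkage

    def test_requires_seed_and_positive_n_boot(self):
        ests = [_we(1, 1, "a"), _we(2, 1, "b"), _we(3, 1, "c")]
        with pytest.raises(ValidationError):
            weighted_median(ests, n_boot=0, seed=1)
        with pytest.raises(ValidationError):
            weighted_median(ests, n_boot=10, seed=None)
        with pytest.raises(ValidationError):
            weighted_median([], n_boot=10, seed=1)


class TestPipelineAndForest:
    def test_fixture_models_reproduce_published_scale(self, cigarettes_results):
        assert cigarettes_results[("8-SNP", "IVW-FE")].estimate == pytest.approx(-1.50, abs=0.01)
        assert cigarettes_results[("6-SNP", "IVW-FE")].estimate == pytest.approx(-1.69, abs=0.01)
        assert cigarettes_results[("2-SNP", "IVW-FE")].estimate == pytest.approx(-2.10, abs=0.01)

    def test_empty_model_request_gives_empty_results(self, cigarettes_set):
        assert run_two_sample_mr(cigarettes_set, MRConfig(models=())) == []

    def test_forest_rows_are_ratio_pm_1p96_se(self, cigarettes_results):
        res = cigarettes_results[("8-SNP", "IVW-FE")]
        table = forest_table(res)
        row = table[table.snp_id == "rs2470893"].iloc[0]
        assert row.ratio == pytest.approx(-2.3611, abs=1e-4)
        assert row.ci_low == pytest.approx(-4.4605, abs=1e-4)
        assert row.ci_high == pytest.approx(-0.2617, abs=1e-4)

    def test_forest_combined_row_passes_through(self, cigarettes_results):
        res = cigarettes_results[("8-SNP", "IVW-FE")]
        combined = forest_table(res).iloc[-1]
        assert combined.ratio == res.estimate
        assert combined.ci_low == res.ci_low

    def test_single_snp_forest_has_identical_rows(self):
        res = ivw_fixed_effects([_we(-2.0, 0.5, "rs1")])
        table = forest_table(res)
        assert len(table) == 2
        assert table.iloc[0].ratio == pytest.approx(table.iloc[1].ratio)
        assert table.iloc[0].ci_low == pytest.approx(table.iloc[1].ci_low)
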