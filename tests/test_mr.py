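"""MR engine: selection/clumping/harmonization rules, estimator oracles,
sensitivity statistics and battery bookkeeping."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gxekit import mr
from gxekit.exceptions import InsufficientDataError, ParameterError
from gxekit.simulate import SumstatSimConfig, gen_sumstats

from conftest import make_harmonized


def sumstat_row(variant_id="rs1", chrom="1", pos=1000, ea="A", oa="G",
                eaf=0.3, beta=0.1, se=0.01, pvalue=1e-6, n=10000):
    return dict(variant_id=variant_id, chrom=chrom, pos=pos, effect_allele=ea,
                other_allele=oa, eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n)


class TestSelectInstruments:
    def test_below_threshold_retained(self):
        df = pd.DataFrame([sumstat_row(pvalue=4e-5)])
        assert len(mr.select_instruments(df, 5e-5)) == 1

    def test_exactly_at_threshold_excluded(self):
        df = pd.DataFrame([sumstat_row(pvalue=5e-5)])
        assert len(mr.select_instruments(df, 5e-5)) == 0

    def test_none_passing_warns_and_returns_empty(self, caplog):
        df = pd.DataFrame([sumstat_row(pvalue=0.5), sumstat_row("rs2", pvalue=0.9)])
        with caplog.at_level("WARNING"):
            out = mr.select_instruments(df, 5e-5)
        assert len(out) == 0
        assert "no instruments" in caplog.text


class TestGreedyClump:
    def test_correlated_pair_keeps_lowest_p(self):
        df = pd.DataFrame([
            sumstat_row("rs1", pos=100_000, pvalue=1e-5),
            sumstat_row("rs2", pos=105_000, pvalue=1e-6),
        ])
        out = mr.greedy_clump(df, {("rs1", "rs2"): 0.5}, window_kb=10_000, r2_threshold=0.001)
        assert list(out["variant_id"]) == ["rs2"]

    def test_uncorrelated_all_kept(self):
        df = pd.DataFrame([
            sumstat_row("rs1", pos=100_000, pvalue=1e-5),
            sumstat_row("rs2", pos=105_000, pvalue=1e-6),
        ])
        out = mr.greedy_clump(df, {("rs1", "rs2"): 0.0})
        assert len(out) == 2

    def test_correlated_but_outside_window_both_kept(self):
        df = pd.DataFrame([
            sumstat_row("rs1", pos=1, pvalue=1e-6),
            sumstat_row("rs2", pos=20_000_000_001, pvalue=1e-5),
        ])
        out = mr.greedy_clump(df, {("rs1", "rs2"): 0.9}, window_kb=10_000)
        assert len(out) == 2


def _paired_tables(out_ea="A", out_oa="G", out_beta=0.05, exp_eaf=0.3, out_eaf=0.3):
    exposure = pd.DataFrame([sumstat_row(eaf=exp_eaf)])
    outcome = pd.DataFrame([sumstat_row(ea=out_ea, oa=out_oa, beta=out_beta,
                                        se=0.02, pvalue=0.01, eaf=out_eaf)])
    return exposure, outcome


class TestHarmonize:
    def test_swapped_outcome_alleles_flip_beta(self):
        exp, out_direct = _paired_tables()
        _, out_swapped = _paired_tables(out_ea="G", out_oa="A", out_beta=-0.05,
                                        out_eaf=0.7)
        h1 = mr.harmonize(exp, out_direct)
        h2 = mr.harmonize(exp, out_swapped)
        assert h1["b_y"].iloc[0] == h2["b_y"].iloc[0] == 0.05

    def test_palindrome_near_half_frequency_excluded(self):
        exposure = pd.DataFrame([
            sumstat_row("rs1", ea="A", oa="T", eaf=0.45),
            sumstat_row("rs2", ea="A", oa="T", eaf=0.10),
        ])
        outcome = exposure.assign(beta=0.05, se=0.02, pvalue=0.01)
        h = mr.harmonize(exposure, outcome, palindrome_maf_limit=0.42)
        assert list(h["variant_id"]) == ["rs2"]

    def test_incompatible_alleles_dropped(self):
        exp, _ = _paired_tables()
        _, bad = _paired_tables(out_ea="A", out_oa="C")
        with pytest.raises(InsufficientDataError):
            mr.harmonize(exp, bad)

    def test_wald_columns(self):
        exp, out = _paired_tables()
        h = mr.harmonize(exp, out)
        assert h["wald_ratio"].iloc[0] == pytest.approx(0.5)
        assert h["wald_se"].iloc[0] == pytest.approx(0.2)
        assert h["f_stat"].iloc[0] == pytest.approx(100.0)

    def test_second_order_wald_se_adds_exposure_term(self):
        exp, out = _paired_tables()
        h2 = mr.harmonize(exp, out, second_order_se=True)
        # sqrt(se_y^2/b_x^2 + b_y^2 se_x^2 / b_x^4) with the example numbers
        expected = np.sqrt(0.02**2 / 0.1**2 + 0.05**2 * 0.01**2 / 0.1**4)
        assert h2["wald_se"].iloc[0] == pytest.approx(expected)
        assert expected > 0.2  # strictly wider than the first-order se


class TestPleiotropyFilter:
    def test_outcome_stronger_than_exposure_removed(self):
        h = make_harmonized([0.1, 0.2])
        h["p_x"] = [1e-5, 1e-5]
        h["p_y"] = [1e-8, 0.5]
        out = mr.pleiotropy_filter(h)
        assert list(out["variant_id"]) == ["rs1"]

    def test_equal_pvalues_retained(self):
        h = make_harmonized([0.1])
        h["p_x"] = h["p_y"] = [1e-5]
        assert len(mr.pleiotropy_filter(h)) == 1

    def test_all_removed_is_hard_error(self):
        h = make_harmonized([0.1])
        h["p_x"], h["p_y"] = [1e-5], [1e-8]
        with pytest.raises(InsufficientDataError):
            mr.pleiotropy_filter(h)


def wls_origin_oracle(b_x, b_y, se_y):
    """Closed-form weighted least squares through the origin of b_y on b_x
    with weights 1/se_y^2 (independent IVW oracle)."""
    w = 1.0 / np.asarray(se_y) ** 2
    beta = np.sum(w * b_x * b_y) / np.sum(w * b_x**2)
    se_fixed = np.sqrt(1.0 / np.sum(w * np.asarray(b_x) ** 2))
    return beta, se_fixed


class TestIvw:
    def test_homogeneous_ratios(self):
        est = mr.ivw(make_harmonized([0.5, 0.5, 0.5]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(np.sqrt(1 / 3))  # Q=0 -> fixed-effect se

    def test_matches_wls_through_origin_oracle(self):
        b_x = np.array([0.10, 0.20, 0.10])
        b_y = np.array([0.05, 0.12, 0.04])
        se_y = np.array([0.01, 0.02, 0.01])
        h = make_harmonized(b_y / b_x, weights=(b_x / se_y) ** 2,
                            b_x=b_x, se_x=np.full(3, 1e-9))
        beta_o, se_fixed = wls_origin_oracle(b_x, b_y, se_y)
        est = mr.ivw(h)
        q = np.sum((b_x / se_y) ** 2 * (b_y / b_x - beta_o) ** 2)
        assert est.beta == pytest.approx(beta_o, rel=1e-12)
        assert est.se == pytest.approx(se_fixed * max(1, np.sqrt(q / 2)), rel=1e-12)

    def test_single_instrument_rejected(self):
        with pytest.raises(InsufficientDataError):
            mr.ivw(make_harmonized([0.5]))

    @given(
        st.lists(
            st.tuples(
                st.floats(0.02, 0.5), st.floats(-0.2, 0.2), st.floats(0.005, 0.05)
            ),
            min_size=2,
            max_size=30,
        )
    )
    def test_property_equals_oracle(self, rows):
        b_x = np.array([r[0] for r in rows])
        b_y = np.array([r[1] for r in rows])
        se_y = np.array([r[2] for r in rows])
        h = make_harmonized(b_y / b_x, weights=(b_x / se_y) ** 2, b_x=b_x)
        beta_o, _ = wls_origin_oracle(b_x, b_y, se_y)
        assert mr.ivw(h).beta == pytest.approx(beta_o, rel=1e-10, abs=1e-12)


class TestEgger:
    def test_homogeneous_ratios_give_zero_intercept_and_ivw_slope(self):
        b_x = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonized(np.full(4, 0.4), weights=(b_x / 0.01) ** 2, b_x=b_x)
        slope, intercept = mr.egger(h)
        assert intercept.beta == pytest.approx(0.0, abs=1e-10)
        assert slope.beta == pytest.approx(0.4, abs=1e-10)

    def test_directional_pleiotropy_intercept_recovery(self):
        # every instrument carries a direct effect with mean 0.1: the Egger
        # intercept estimates that mean under InSIDE
        intercepts = []
        for rep in range(20):
            cfg = SumstatSimConfig(n_snps=500, theta=0.1, pleiotropy_mode="directional",
                                   pleiotropy_mean=0.1, invalid_fraction=1.0, seed=rep)
            exposure, outcome = gen_sumstats(cfg)
            # keep strong instruments only: near-zero exposure effects get
            # sign-flipped by the orientation step, which would cancel their
            # directional pleiotropy and attenuate the intercept
            h = mr.harmonize(mr.select_instruments(exposure, 5e-5), outcome)
            intercepts.append(mr.egger(h)[1].beta)
        intercepts = np.array(intercepts)
        mc_se = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
        assert abs(intercepts.mean() - 0.1) < 4 * mc_se

    def test_too_few_instruments_rejected(self):
        with pytest.raises(InsufficientDataError):
            mr.egger(make_harmonized([0.1, 0.2]))


class TestWeightedMedian:
    def test_middle_element_equal_weights(self):
        est = mr.weighted_median(make_harmonized([0.1, 0.2, 0.9]), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_cumulative_weight_interpolation_oracle(self):
        # hand enumeration: ratios (1,2,3,4), weights (.1,.2,.3,.4);
        # midpoint cumulative weights (.05,.2,.45,.8) bracket 0.5 between the
        # third and fourth ratios: 3 + (0.5-0.45)/(0.8-0.45) = 3 + 1/7
        est = mr.weighted_median(
            make_harmonized([1.0, 2.0, 3.0, 4.0], weights=[0.1, 0.2, 0.3, 0.4]),
            n_boot=50, seed=1,
        )
        assert est.beta == pytest.approx(3 + 1 / 7)

    def test_majority_weight_pins_estimate(self):
        ratios = [0.0, 0.1, 0.37, 0.37, 0.37, 0.37, 0.37, 0.37, 0.9, 1.5]
        weights = [0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        est = mr.weighted_median(make_harmonized(ratios, weights), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.37)

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=20))
    def test_property_within_ratio_range(self, ratios):
        est = mr.weighted_median(make_harmonized(ratios), n_boot=20, seed=0)
        assert min(ratios) - 1e-12 <= est.beta <= max(ratios) + 1e-12


class TestWeightedMode:
    def test_identical_ratios(self):
        est = mr.weighted_mode(make_harmonized([0.3, 0.3, 0.3]), n_boot=20, seed=1)
        assert est.beta == pytest.approx(0.3)

    def test_dominant_cluster_wins(self):
        ratios = [0.2] * 7 + [1.0] * 3
        est = mr.weighted_mode(make_harmonized(ratios), n_boot=50, seed=1)
        assert abs(est.beta - 0.2) < 0.05

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ParameterError):
            mr.weighted_mode(make_harmonized([0.1, 0.2, 0.3]), bandwidth_factor=0.0)


class TestSensitivityStatistics:
    def test_q_zero_for_homogeneous(self):
        q, p = mr.cochran_q(make_harmonized([0.5, 0.5, 0.5]), 0.5)
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_q_mean_matches_chi_square(self, rng):
        # ratios drawn exactly as Normal(theta, wald_se): Q ~ chi2(k-1)
        k, reps = 20, 300
        qs = []
        for _ in range(reps):
            ratios = 0.1 + 0.1 * rng.standard_normal(k)
            h = make_harmonized(ratios, weights=np.full(k, 100.0))
            qs.append(mr.cochran_q(h, mr.ivw(h).beta)[0])
        qs = np.array(qs)
        assert abs(qs.mean() - (k - 1)) < 4 * qs.std(ddof=1) / np.sqrt(reps)

    def test_outlier_dominates_q(self):
        h = make_harmonized([0.1, 0.1, 0.1, 10.0])
        q, _ = mr.cochran_q(h, 0.1)
        q_out = h["weight"].iloc[3] * (10.0 - 0.1) ** 2
        assert q_out / q > 0.99

    @pytest.mark.parametrize(
        "q,k,expected", [(9.0, 10, 0.0), (18.0, 10, 0.5), (5.0, 10, 0.0), (0.0, 5, 0.0)]
    )
    def test_i_squared_algebra(self, q, k, expected):
        assert mr.i_squared(q, k) == pytest.approx(expected)

    def test_mean_f(self):
        h = make_harmonized([0.5], b_x=[0.1], se_x=[0.02])
        f, weak = mr.mean_f(h)
        assert f == pytest.approx(25.0)
        assert not weak
        h2 = make_harmonized([0.5, 0.5], b_x=[1.0, 1.0], se_x=[1 / np.sqrt(10), 1 / np.sqrt(30)])
        f2, weak2 = mr.mean_f(h2)
        assert f2 == pytest.approx(20.0)
        assert not weak2
        h3 = make_harmonized([0.5], b_x=[1.0], se_x=[1 / np.sqrt(9.9)])
        _, weak3 = mr.mean_f(h3)
        assert weak3


class TestRadialOutliers:
    def test_homogeneous_no_outliers(self):
        ids, cleaned = mr.radial_outliers(make_harmonized([0.2, 0.2, 0.2, 0.2]))
        assert ids == []
        assert len(cleaned) == 4

    def test_planted_outlier_flagged(self):
        ratios = [0.1] * 30 + [1.0]
        weights = [100.0] * 30 + [400.0]  # outlier has the smallest wald se
        h = make_harmonized(ratios, weights)
        ids, cleaned = mr.radial_outliers(h)
        assert ids == ["rs30"]
        assert len(cleaned) == 30

    def test_alpha_zero_flags_nothing(self):
        ids, _ = mr.radial_outliers(make_harmonized([0.1, 0.5, 2.0]), alpha=0.0)
        assert ids == []

    def test_battery_iterated_removal_flags_at_least_single_pass(self):
        cfg = SumstatSimConfig(n_snps=100, theta=0.1, outlier_fraction=0.05, seed=9)
        exposure, outcome = gen_sumstats(cfg)
        once = mr.run_mr_battery(exposure, outcome, mr.MrConfig(seed=1, n_boot=50))
        iterated = mr.run_mr_battery(
            exposure, outcome, mr.MrConfig(seed=1, n_boot=50, radial_iterate=True)
        )
        assert set(once.radial_outlier_ids) <= set(iterated.radial_outlier_ids)


class TestLeaveOneOut:
    def test_one_row_per_instrument(self):
        loo = mr.leave_one_out(make_harmonized([0.1, 0.2, 0.3, 0.4]))
        assert len(loo) == 4

    def test_removing_outlier_reproduces_clean_ivw_exactly(self):
        clean = make_harmonized([0.1, 0.12, 0.11, 0.09], ids=list("abcd"))
        contaminated = pd.concat(
            [clean, make_harmonized([5.0], ids=["outlier"])], ignore_index=True
        )
        loo = mr.leave_one_out(contaminated)
        row = loo[loo["left_out"] == "outlier"].iloc[0]
        assert row["beta"] == mr.ivw(clean).beta

    def test_homogeneous_loo_estimates_equal_full(self):
        h = make_harmonized([0.3] * 5)
        loo = mr.leave_one_out(h)
        assert np.allclose(loo["beta"], 0.3)


class TestBattery:
    def test_bookkeeping_counts(self):
        cfg = SumstatSimConfig(n_snps=120, theta=0.1, palindrome_fraction=0.1, seed=11)
        report = mr.run_mr_battery(*gen_sumstats(cfg), mr.MrConfig(seed=1, n_boot=50))
        assert (
            report.n_snps_final
            == report.n_snps_initial - report.n_removed_radial - report.n_removed_pleiotropy
        )
        assert 0.0 <= report.i_squared < 1.0
        assert report.cochran_q >= 0.0
        assert len(report.loo_table) == report.n_snps_final

    def test_null_ivw_pvalues_roughly_uniform(self):
        # selection-free null: harmonize + IVW; rejection at 0.05 near nominal
        rejections = 0
        reps = 200
        for rep in range(reps):
            h = mr.harmonize(*gen_sumstats(SumstatSimConfig(n_snps=50, theta=0.0, seed=rep)))
            rejections += mr.ivw(h).pvalue < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_allele_scramble_invariance_single_config(self):
        base = SumstatSimConfig(n_snps=80, theta=0.1, palindrome_fraction=0.2, seed=5)
        scrambled = SumstatSimConfig(**{**vars(base), "allele_scramble": True})
        cfg = mr.MrConfig(seed=2, n_boot=100)
        rep_a = mr.run_mr_battery(*gen_sumstats(base), cfg)
        rep_b = mr.run_mr_battery(*gen_sumstats(scrambled), cfg)
        assert rep_a.to_dict() == rep_b.to_dict()
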