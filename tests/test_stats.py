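"""Error metrics, multiple comparisons, RM-ANOVA and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from linguavol.errors import StatsError
from linguavol.stats import (
    TIMEPOINTS,
    classify_ratio_change,
    coefficient_of_variation,
    cohort_analysis,
    decrease_regression,
    gg_epsilon,
    holm_sidak_adjust,
    holm_sidak_paired,
    method_error,
    rm_anova_gg,
    rm_anova_gg_wide,
    two_way_rm_interaction,
)


def _long_table(rng, n=12, effects=None, measures=("OCC", "TV", "ratio")):
    """Random complete cohort table with optional per-timepoint mean shifts."""
    rows = []
    effects = effects or {}
    base = {"OCC": 38.0, "TV": 22.0, "ratio": 57.0}
    for sid in range(1, n + 1):
        subj = rng.normal(0, 3)
        for m in measures:
            for t_i, tp in enumerate(TIMEPOINTS):
                shift = effects.get(m, (0, 0, 0, 0))[t_i]
                rows.append({"subject_id": sid, "timepoint": tp, "measure": m,
                             "value": base[m] + subj + shift + rng.normal(0, 1.5)})
    return pd.DataFrame(rows)


class TestMethodError:
    def test_perfect_measurements_have_zero_error(self):
        res = method_error([54.9, 54.9, 54.9], 54.9)
        assert res.mean_diff_cm3 == 0.0 and res.mean_pct_diff == 0.0

    def test_hand_computed_example(self):
        res = method_error([55.0, 54.8], 54.9)
        assert res.mean_diff_cm3 == pytest.approx(0.1)
        assert res.mean_pct_diff == pytest.approx(100 * 0.1 / 54.9)
        assert res.n == 2

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(StatsError):
            method_error([1.0], 0.0)


class TestCoefficientOfVariation:
    def test_constant_list_is_zero(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_intra_subject_example(self):
        # repeated-measurement summary mean 23.40, SD 1.00 -> CV 4.27%
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        x = (x - x.mean()) / x.std(ddof=1)  # exact mean 0, SD 1
        values = 23.40 + x
        assert coefficient_of_variation(values) == pytest.approx(100 / 23.40, abs=1e-9)
        assert coefficient_of_variation(values) == pytest.approx(4.27, abs=0.01)

    def test_matches_two_pass_sd_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.uniform(10, 50, size=rng.integers(3, 30))
            mean = sum(v) / len(v)
            sd = (sum((x - mean) ** 2 for x in v) / (len(v) - 1)) ** 0.5
            assert coefficient_of_variation(v) == pytest.approx(100 * sd / mean)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            coefficient_of_variation([3.0])
        with pytest.raises(StatsError):
            coefficient_of_variation([1.0, -1.0])


class TestHolmSidak:
    def test_single_comparison_unchanged(self):
        np.testing.assert_allclose(holm_sidak_adjust(np.array([0.03])), [0.03])

    def test_hand_evaluated_step_down(self):
        adj = holm_sidak_adjust(np.array([0.01, 0.02, 0.30]))
        expected = [1 - 0.99 ** 3, 1 - 0.98 ** 2, 0.30]
        np.testing.assert_allclose(adj, expected, atol=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = rng.uniform(0, 1, size=rng.integers(2, 9))
            ours = holm_sidak_adjust(p)
            _, ref, _, _ = multipletests(p, method="holm-sidak")
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_monotone_and_never_below_raw(self, p_list):
        p = np.asarray(p_list)
        adj = holm_sidak_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_paired_tests_on_identical_timepoints_give_p_one(self):
        rng = np.random.default_rng(3)
        table = _long_table(rng, n=8)
        occ = table[table.measure == "OCC"]
        dup = occ[occ.timepoint == "T0"].copy()
        for tp in ("T1", "T2", "T3"):
            d2 = dup.copy()
            d2["timepoint"] = tp
            occ = pd.concat([occ[occ.timepoint != tp], d2])
        res = holm_sidak_paired(pd.concat([occ]), "OCC", comparisons=(("T0", "T1"),))
        assert res.iloc[0].t == 0.0 and res.iloc[0].p_raw == 1.0

    def test_detects_a_real_decrease(self):
        rng = np.random.default_rng(4)
        table = _long_table(rng, n=15, effects={"OCC": (0, -6, -6, -6)})
        res = holm_sidak_paired(table, "OCC")
        res = res.set_index(["timepoint_a", "timepoint_b"])
        assert res.loc[("T0", "T1")].reject
        assert not res.loc[("T1", "T2")].reject

    def test_incomplete_pairs_refused(self):
        rng = np.random.default_rng(5)
        table = _long_table(rng, n=6)
        table = table[~((table.subject_id == 3) & (table.timepoint == "T1"))]
        with pytest.raises(StatsError, match="missing|incomplete"):
            holm_sidak_paired(table, "OCC")


class TestGgEpsilon:
    def test_exchangeable_covariance_gives_one(self):
        sigma2, rho = 4.0, 0.6
        cov = sigma2 * (np.full((4, 4), rho) + (1 - rho) * np.eye(4))
        assert gg_epsilon(cov) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), k=st.integers(2, 6))
    def test_bounds(self, seed, k):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(k + 3, k))
        eps = gg_epsilon(np.cov(x, rowvar=False))
        assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0 + 1e-12


class TestRmAnovaGG:
    def test_two_timepoints_reduce_to_paired_t(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 2)) + [0, 1.0]
        res = rm_anova_gg_wide(x)
        t, p = sps.ttest_rel(x[:, 0], x[:, 1])
        assert res.epsilon == pytest.approx(1.0)
        assert res.F == pytest.approx(t ** 2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_matches_pingouin_with_gg_correction(self):
        import pingouin as pg
        rng = np.random.default_rng(7)
        table = _long_table(rng, n=14, effects={"ratio": (0, -1.5, 0.5, 1.0)})
        res = rm_anova_gg(table, "ratio")
        sub = table[table.measure == "ratio"]
        ref = pg.rm_anova(data=sub, dv="value", within="timepoint",
                          subject="subject_id", correction=True)
        assert res.F == pytest.approx(float(ref["F"][0]), rel=1e-8)
        assert res.epsilon == pytest.approx(float(ref["eps"][0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_GG_corr"][0]), rel=1e-6)

    def test_no_time_variation_gives_f_zero_p_one(self):
        x = np.tile(np.arange(5, dtype=float)[:, None], (1, 4))
        res = rm_anova_gg_wide(x)
        assert res.F == 0.0 and res.p == 1.0

    def test_type_one_error_rate_near_nominal(self):
        # null cohorts: no timepoint effect in the means, study-like
        # per-timepoint SDs and exchangeable subject tracking
        rng = np.random.default_rng(8)
        sd = np.array([4.55, 3.84, 3.48, 3.20])
        corr = np.full((4, 4), 0.85) + 0.15 * np.eye(4)
        chol = np.linalg.cholesky(np.outer(sd, sd) * corr)
        nsim, n = 10_000, 15
        rejections = 0
        for _ in range(nsim):
            x = rng.standard_normal((n, 4)) @ chol.T
            rejections += rm_anova_gg_wide(x).p < 0.05
        assert 0.04 <= rejections / nsim <= 0.06


class TestTwoWayInteraction:
    def test_parallel_profiles_have_no_interaction(self):
        # dyadic values and 8 subjects keep every cell mean exact in floats,
        # so exactly parallel profiles give an interaction SS of exactly 0
        rows = []
        profile = {"T0": 0.0, "T1": -6.0, "T2": -6.5, "T3": -6.25}
        for sid in range(1, 9):
            subj = 0.5 * sid
            for tp in TIMEPOINTS:
                occ = 38.0 + subj + profile[tp]
                rows.append({"subject_id": sid, "timepoint": tp, "measure": "OCC",
                             "value": occ})
                # TV exactly parallel: OCC minus a per-subject constant
                rows.append({"subject_id": sid, "timepoint": tp, "measure": "TV",
                             "value": occ - 16.0 - 0.25 * sid})
        res = two_way_rm_interaction(pd.DataFrame(rows))
        assert res.interaction_F == 0.0
        assert res.interaction_p == 1.0

    def test_matches_pingouin_two_within_factors(self):
        import pingouin as pg
        rng = np.random.default_rng(10)
        table = _long_table(rng, n=12, effects={"OCC": (0, -6, -5, -5),
                                                "TV": (0, -4, -4, -3)})
        res = two_way_rm_interaction(table)
        sub = table[table.measure.isin(["OCC", "TV"])]
        ref = pg.rm_anova(data=sub, dv="value", within=["measure", "timepoint"],
                          subject="subject_id", correction=False)
        ref_int = ref[ref.Source == "measure * timepoint"].iloc[0]
        assert res.interaction_F == pytest.approx(float(ref_int["F"]), rel=1e-6)
        assert res.interaction_p == pytest.approx(float(ref_int["p_unc"]), rel=1e-4)

    def test_interaction_grows_with_injected_effect(self):
        rng = np.random.default_rng(11)
        fs = []
        for delta in (0.0, 2.0, 4.0):
            table = _long_table(rng, n=12,
                                effects={"OCC": (0, -6, -6, -6),
                                         "TV": (0, -6 + delta, -6 + delta, -6 + delta)})
            fs.append(two_way_rm_interaction(table).interaction_F)
        assert fs[0] < fs[1] < fs[2]

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(12)
        table = _long_table(rng, n=1)
        with pytest.raises(StatsError):
            two_way_rm_interaction(pd.concat([table]))


class TestDecreaseRegression:
    def test_perfectly_linear_data(self):
        rows = []
        for sid, d in enumerate([2.0, 4.0, 6.0, 8.0], start=1):
            rows += [
                {"subject_id": sid, "timepoint": "T0", "measure": "OCC", "value": 38 + d},
                {"subject_id": sid, "timepoint": "T1", "measure": "OCC", "value": 38 - d},
                {"subject_id": sid, "timepoint": "T0", "measure": "TV", "value": 20 + d},
                {"subject_id": sid, "timepoint": "T1", "measure": "TV", "value": 20},
            ]
        res = decrease_regression(pd.DataFrame(rows))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.p < 1e-6
        assert res.slope == pytest.approx(0.5)

    def test_matches_normal_equations_on_hand_set(self):
        d_occ = np.array([2.0, 3.5, 5.0, 6.0, 9.0])
        d_tv = np.array([1.0, 2.0, 2.5, 4.5, 5.0])
        rows = []
        for sid, (do, dt) in enumerate(zip(d_occ, d_tv), start=1):
            rows += [
                {"subject_id": sid, "timepoint": "T0", "measure": "OCC", "value": 40.0},
                {"subject_id": sid, "timepoint": "T1", "measure": "OCC", "value": 40.0 - do},
                {"subject_id": sid, "timepoint": "T0", "measure": "TV", "value": 22.0},
                {"subject_id": sid, "timepoint": "T1", "measure": "TV", "value": 22.0 - dt},
            ]
        res = decrease_regression(pd.DataFrame(rows))
        sxx = np.sum((d_occ - d_occ.mean()) ** 2)
        sxy = np.sum((d_occ - d_occ.mean()) * (d_tv - d_tv.mean()))
        slope = sxy / sxx
        intercept = d_tv.mean() - slope * d_occ.mean()
        r = sxy / np.sqrt(sxx * np.sum((d_tv - d_tv.mean()) ** 2))
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert res.pearson_r == pytest.approx(r, rel=1e-10)
        # p from t = r sqrt((n-2)/(1-r^2))
        t = r * np.sqrt(3 / (1 - r ** 2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 3), rel=1e-9)

    def test_r_matches_brute_force_covariance(self):
        rng = np.random.default_rng(13)
        table = _long_table(rng, n=20)
        res = decrease_regression(table)
        occ = table[table.measure == "OCC"].pivot(index="subject_id",
                                                  columns="timepoint", values="value")
        tv = table[table.measure == "TV"].pivot(index="subject_id",
                                                columns="timepoint", values="value")
        do = (occ["T0"] - occ["T1"]).to_numpy()
        dt = (tv["T0"] - tv["T1"]).to_numpy()
        num = np.mean(do * dt) - do.mean() * dt.mean()
        den = np.sqrt((np.mean(do ** 2) - do.mean() ** 2) * (np.mean(dt ** 2) - dt.mean() ** 2))
        assert res.pearson_r == pytest.approx(num / den, abs=1e-10)

    def test_zero_variance_rejected(self):
        rows = []
        for sid in (1, 2, 3):
            rows += [
                {"subject_id": sid, "timepoint": "T0", "measure": "OCC", "value": 40.0},
                {"subject_id": sid, "timepoint": "T1", "measure": "OCC", "value": 35.0},
                {"subject_id": sid, "timepoint": "T0", "measure": "TV", "value": 22.0},
                {"subject_id": sid, "timepoint": "T1", "measure": "TV", "value": 20.0 - sid},
            ]
        with pytest.raises(StatsError, match="variance"):
            decrease_regression(pd.DataFrame(rows))


class TestClassification:
    @pytest.mark.parametrize("delta,label", [
        (0.0, "I"),
        (2.0, "I"),       # boundary inclusive ("within -2.0 to +2.0")
        (-2.0, "I"),
        (2.5, "II"),
        (2.0001, "II"),
        (-2.0001, "III"),
        (-7.0, "III"),
    ])
    def test_thresholds(self, delta, label):
        assert classify_ratio_change(delta).label == label

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(-50, 50))
    def test_partitions_the_line(self, d):
        assert classify_ratio_change(d).label in {"I", "II", "III"}

    def test_non_finite_rejected(self):
        with pytest.raises(StatsError):
            classify_ratio_change(float("nan"))


class TestCohortAnalysis:
    def test_contains_all_five_analyses_and_counts_sum(self):
        rng = np.random.default_rng(14)
        table = _long_table(rng, n=15, effects={"OCC": (0, -6, -6, -6),
                                                "TV": (0, -4, -4, -3)})
        out = cohort_analysis(table)
        assert set(out) >= {"holm_sidak", "two_way", "regression",
                            "ratio_rm_anova", "groups", "group_counts"}
        assert sum(out["group_counts"].values()) == 15

    def test_deterministic_given_the_same_table(self):
        rng1 = np.random.default_rng(15)
        rng2 = np.random.default_rng(15)
        t1, t2 = _long_table(rng1), _long_table(rng2)
        a, b = cohort_analysis(t1), cohort_analysis(t2)
        assert a["regression"].pearson_r == b["regression"].pearson_r
        assert a["group_counts"] == b["group_counts"]
        pd.testing.assert_frame_equal(a["holm_sidak"]["OCC"], b["holm_sidak"]["OCC"])
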