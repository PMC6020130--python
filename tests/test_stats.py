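"""Permutation GLM tests, clinical association scan, FDR correction."""

import numpy as np
import pandas as pd
import pytest

from tractnet.stats import (
    clinical_association_scan,
    fdr_correct,
    permutation_group_scan,
    permutation_group_test,
)


def _cohort(n_ts=15, n_cs=15, seed=0):
    rng = np.random.default_rng(seed)
    n = n_ts + n_cs
    return pd.DataFrame(
        {
            "subject": [f"s{i}" for i in range(n)],
            "group": ["TS"] * n_ts + ["CS"] * n_cs,
            "age": rng.uniform(9, 21, n),
            "iq": rng.normal(112, 12, n),
            "tiv": rng.normal(1.4e6, 1e5, n),
            "ygtss": np.concatenate([rng.uniform(5, 80, n_ts), np.full(n_cs, np.nan)]),
            "puts": np.concatenate([rng.uniform(9, 36, n_ts), np.full(n_cs, np.nan)]),
        }
    )


class TestPermutationGroupTest:
    def test_constant_metric_gives_p_one(self):
        cohort = _cohort()
        with pytest.warns(UserWarning, match="constant"):
            res = permutation_group_test(np.full(30, 3.3), cohort)
        assert res.p == 1.0 and res.t == 0.0

    def test_strong_group_shift_detected(self):
        cohort = _cohort(seed=1)
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 30)
        y[:15] += 3.0
        res = permutation_group_test(y, cohort, n_perm=500, seed=3)
        assert res.p < 0.01
        assert res.beta > 0

    def test_observed_t_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        cohort = _cohort(seed=4)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 30)
        res = permutation_group_test(y, cohort, n_perm=10, seed=0)
        x = sm.add_constant(
            np.column_stack(
                [
                    (cohort["group"] == "TS").astype(float),
                    cohort[["age", "iq", "tiv"]].to_numpy(),
                ]
            )
        )
        fit = sm.OLS(y, x).fit()
        assert res.t == pytest.approx(fit.tvalues[1])
        assert res.beta == pytest.approx(fit.params[1])

    def test_p_never_zero(self):
        cohort = _cohort(seed=6)
        y = np.concatenate([np.zeros(15), np.ones(15)]) + np.random.default_rng(7).normal(0, 1e-6, 30)
        res = permutation_group_test(y, cohort, n_perm=100, seed=8)
        assert res.p >= 1 / 101

    def test_p_invariant_to_affine_covariate_rescaling(self):
        cohort = _cohort(seed=9)
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, 30)
        res1 = permutation_group_test(y, cohort, n_perm=300, seed=11)
        scaled = cohort.copy()
        scaled["age"] = scaled["age"] * 12.0 + 7.0  # months, shifted
        scaled["tiv"] = scaled["tiv"] / 1000.0  # cm^3
        res2 = permutation_group_test(y, scaled, n_perm=300, seed=11)
        assert res2.p == res1.p
        assert res2.t == pytest.approx(res1.t)

    def test_p_stable_under_subject_reordering(self):
        cohort = _cohort(seed=12)
        rng = np.random.default_rng(13)
        y = rng.normal(0, 1, 30) + 0.8 * (cohort["group"] == "TS").to_numpy()
        res1 = permutation_group_test(y, cohort, n_perm=2000, seed=14)
        order = rng.permutation(30)
        res2 = permutation_group_test(
            y[order], cohort.iloc[order].reset_index(drop=True), n_perm=2000, seed=14
        )
        assert res2.t == pytest.approx(res1.t)
        # permutation p agrees within Monte-Carlo error
        assert abs(res2.p - res1.p) < 0.05

    def test_doubling_permutations_changes_p_within_mc_error(self):
        cohort = _cohort(seed=15)
        rng = np.random.default_rng(16)
        y = rng.normal(0, 1, 30) + 0.7 * (cohort["group"] == "TS").to_numpy()
        p1 = permutation_group_test(y, cohort, n_perm=1000, seed=17).p
        p2 = permutation_group_test(y, cohort, n_perm=2000, seed=18).p
        se = np.sqrt(p1 * (1 - p1) / 1000)
        assert abs(p1 - p2) < 4 * se + 1e-3

    def test_clinical_scores_do_not_enter_group_test(self):
        cohort = _cohort(seed=19)
        rng = np.random.default_rng(20)
        y = rng.normal(0, 1, 30)
        res1 = permutation_group_test(y, cohort, n_perm=200, seed=21)
        mutated = cohort.copy()
        mutated["ygtss"] = 99.0
        mutated["puts"] = 36.0
        res2 = permutation_group_test(y, mutated, n_perm=200, seed=21)
        assert res1.t == res2.t and res1.p == res2.p

    def test_missing_covariate_rejected(self):
        cohort = _cohort()
        cohort.loc[3, "iq"] = np.nan
        with pytest.raises(ValueError, match="complete"):
            permutation_group_test(np.arange(30.0), cohort)

    def test_scan_matches_single_tests(self):
        cohort = _cohort(seed=22)
        rng = np.random.default_rng(23)
        y = rng.normal(0, 1, (30, 3))
        t_scan, p_scan = permutation_group_scan(y, cohort, n_perm=200, seed=24)
        for j in range(3):
            res = permutation_group_test(y[:, j], cohort, n_perm=200, seed=24)
            assert t_scan[j] == pytest.approx(res.t)


def _metric_long_table(cohort, thresholds, rng, planted=None):
    """Long metric table over 24 nodes x 9 metrics; optional planted signal."""
    from tractnet.stats import SCAN_METRICS

    rows = []
    ts = cohort[cohort["group"] == "TS"]
    for subj in ts["subject"]:
        for thr in thresholds:
            for node in range(24):
                for metric in SCAN_METRICS:
                    rows.append((subj, thr, node, metric, rng.normal()))
    df = pd.DataFrame(
        rows, columns=["subject", "threshold", "node", "metric", "value"]
    )
    if planted:
        node, metric, score = planted
        sel = (df["node"] == node) & (df["metric"] == metric)
        score_z = (
            ts.set_index("subject")[score] - ts[score].mean()
        ) / ts[score].std(ddof=1)
        df.loc[sel, "value"] += 2.0 * df.loc[sel, "subject"].map(score_z).to_numpy()
    return df


class TestClinicalAssociationScan:
    def test_grid_has_expected_cell_count_and_columns(self):
        cohort = _cohort(n_ts=12, n_cs=3, seed=25)
        thresholds = [0.2, 0.3]
        rng = np.random.default_rng(26)
        metrics = _metric_long_table(cohort, thresholds, rng)
        out = clinical_association_scan(metrics, cohort, "puts", np.array(thresholds))
        assert len(out) == 2 * 24 * 9
        assert {"beta", "t", "p", "p_fdr", "significant_fdr"} <= set(out.columns)

    def test_planted_association_found_at_its_cell(self):
        cohort = _cohort(n_ts=20, n_cs=3, seed=27)
        thresholds = [0.25]
        rng = np.random.default_rng(28)
        metrics = _metric_long_table(
            cohort, thresholds, rng, planted=(5, "local_efficiency", "puts")
        )
        out = clinical_association_scan(metrics, cohort, "puts", np.array(thresholds))
        best = out.loc[out["t"].abs().idxmax()]
        assert best["node"] == 5 and best["metric"] == "local_efficiency"
        assert best["beta"] > 0

    def test_constant_metric_cell_degenerates_to_p_one(self):
        cohort = _cohort(n_ts=10, n_cs=2, seed=29)
        rng = np.random.default_rng(30)
        metrics = _metric_long_table(cohort, [0.2], rng)
        metrics.loc[
            (metrics["node"] == 0) & (metrics["metric"] == "density"), "value"
        ] = 0.5
        out = clinical_association_scan(metrics, cohort, "puts", np.array([0.2]))
        cell = out[(out["node"] == 0) & (out["metric"] == "density")].iloc[0]
        assert cell["p"] == 1.0 and np.isnan(cell["beta"])

    def test_permutation_p_agrees_with_parametric_on_strong_effect(self):
        cohort = _cohort(n_ts=20, n_cs=2, seed=31)
        rng = np.random.default_rng(32)
        metrics = _metric_long_table(
            cohort, [0.25], rng, planted=(3, "betweenness", "puts")
        )
        out = clinical_association_scan(
            metrics, cohort, "puts", np.array([0.25]), n_perm=400, seed=33
        )
        cell = out[(out["node"] == 3) & (out["metric"] == "betweenness")].iloc[0]
        assert cell["p"] < 0.01
        assert cell["p_perm"] < 0.05

    def test_controls_never_enter_the_scan(self):
        cohort = _cohort(n_ts=10, n_cs=5, seed=34)
        rng = np.random.default_rng(35)
        metrics = _metric_long_table(cohort, [0.2], rng)
        out1 = clinical_association_scan(metrics, cohort, "puts", np.array([0.2]))
        mutated = cohort.copy()
        mutated.loc[mutated["group"] == "CS", ["age", "iq", "tiv"]] = 0.0
        out2 = clinical_association_scan(metrics, mutated, "puts", np.array([0.2]))
        pd.testing.assert_frame_equal(out1, out2)

    def test_too_few_patients_rejected(self):
        cohort = _cohort(n_ts=4, n_cs=2, seed=36)
        rng = np.random.default_rng(37)
        metrics = _metric_long_table(cohort, [0.2], rng)
        with pytest.raises(ValueError, match="fewer patients"):
            clinical_association_scan(metrics, cohort, "puts", np.array([0.2]))


class TestFDR:
    def test_step_up_example_rejects_all_four(self):
        # largest k with p(k) <= k q / m is k = 4
        reject, p_adj = fdr_correct(np.array([0.01, 0.02, 0.04, 0.05]), q=0.05)
        assert reject.all()

    def test_all_ones_rejects_none(self):
        reject, p_adj = fdr_correct(np.ones(10), q=0.05)
        assert not reject.any()
        assert (p_adj == 1.0).all()

    def test_single_p_compared_directly_to_q(self):
        reject, p_adj = fdr_correct(np.array([0.04]), q=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_adjusted_p_monotone_in_raw_rank(self):
        rng = np.random.default_rng(38)
        p = rng.uniform(0, 1, 50)
        _rej, p_adj = fdr_correct(p)
        order = np.argsort(p)
        assert (np.diff(p_adj[order]) >= -1e-12).all()

    def test_rejections_are_exactly_adjusted_p_below_q(self):
        rng = np.random.default_rng(39)
        p = rng.uniform(0, 0.2, 40)
        rej, p_adj = fdr_correct(p, q=0.05)
        assert np.array_equal(rej, p_adj <= 0.05)

    def test_empty_family(self):
        rej, p_adj = fdr_correct(np.array([]))
        assert rej.size == 0 and p_adj.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.5, 1.2]))

    def test_by_variant_is_more_conservative(self):
        p = np.array([0.001, 0.01, 0.02, 0.04, 0.3])
        _r1, bh = fdr_correct(p, method="bh")
        _r2, by = fdr_correct(p, method="by")
        assert (by >= bh - 1e-12).all()
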