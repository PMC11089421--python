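"""Case-control statistics: residual t-tests, ANCOVA, BH-FDR oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dynconn.groupstats import ancova_group_effect, bh_fdr, residual_ttest


def hand_bh(p):
    """Independent Benjamini-Hochberg computation: step-up with cummin."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def make_cohort(n_case=21, n_control=21, seed=0):
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    return rng, pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["case"] * n_case + ["control"] * n_control,
            "age": rng.uniform(6, 8, size=n),
            "sex": np.arange(n) % 2,  # balanced, never degenerate
            "deprivation_decile": rng.integers(1, 11, size=n),
        }
    )


def make_edges(cohort, rng, n_edges, age_beta=0.3, sex_beta=0.5):
    n = len(cohort)
    base = rng.normal(size=(n, n_edges))
    covar = np.outer(cohort["age"], np.full(n_edges, age_beta)) + np.outer(
        cohort["sex"], np.full(n_edges, sex_beta)
    )
    return pd.DataFrame(
        base + covar, index=cohort["subject_id"],
        columns=[f"e{i}" for i in range(n_edges)],
    )


class TestBHFDR:
    def test_hand_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.37])), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr(np.ones(5)), 1.0)

    def test_matches_hand_computation(self, rng):
        p = rng.uniform(size=200)
        np.testing.assert_allclose(bh_fdr(p), hand_bh(p), atol=1e-12)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))


class TestResidualTTest:
    def test_identical_groups_duplicated_gives_zero_t(self):
        rng, cohort = make_cohort(5, 5, seed=1)
        half = rng.normal(size=(5, 10))
        # control block duplicates case block, covariates matched pairwise
        cohort.loc[5:, "age"] = cohort.loc[:4, "age"].to_numpy()
        cohort.loc[5:, "sex"] = cohort.loc[:4, "sex"].to_numpy()
        edges = pd.DataFrame(
            np.vstack([half, half]), index=cohort["subject_id"],
            columns=[f"e{i}" for i in range(10)],
        )
        res = residual_ttest(edges, cohort)
        np.testing.assert_allclose(res["t_statistic"], 0.0, atol=1e-10)

    def test_degrees_of_freedom_checkpoint(self):
        """Reported p equals the two-tailed t tail at n1+n2-2 df (=40 here,
        where |t| = 2.02 sits at p ~ 0.05)."""
        rng, cohort = make_cohort(22, 20, seed=2)
        edges = make_edges(cohort, rng, 50)
        res = residual_ttest(edges, cohort)
        expect = 2 * stats.t.sf(np.abs(res["t_statistic"]), df=40)
        np.testing.assert_allclose(res["p_uncorrected"], expect, atol=1e-12)
        assert 2 * stats.t.sf(2.02, df=40) == pytest.approx(0.05, abs=0.0005)

    def test_null_positive_rate_near_alpha(self):
        rng, cohort = make_cohort(21, 21, seed=3)
        edges = make_edges(cohort, rng, 4000)
        res = residual_ttest(edges, cohort)
        rate = (res["p_uncorrected"] < 0.05).mean()
        assert 0.035 < rate < 0.065

    def test_injected_effects_detected_with_fdr(self):
        rng, cohort = make_cohort(21, 21, seed=4)
        edges = make_edges(cohort, rng, 465)
        is_case = (cohort["group"] == "case").to_numpy()
        shifted = [f"e{i}" for i in range(10)]
        edges.loc[is_case, shifted] += 2.0  # 2 SD shift on 10 of 465 edges
        res = residual_ttest(edges, cohort).set_index("edge")
        assert res.loc[shifted, "significant_fdr"].sum() >= 8
        assert res.drop(index=shifted)["significant_fdr"].sum() <= 2

    def test_rank_deficient_covariates_rejected(self):
        rng, cohort = make_cohort(5, 5, seed=5)
        cohort["sex"] = 1  # collinear with intercept
        edges = make_edges(cohort, rng, 4)
        with pytest.raises(ValueError, match="rank"):
            residual_ttest(edges, cohort)

    def test_too_small_group_rejected(self):
        rng, cohort = make_cohort(2, 8, seed=6)
        edges = make_edges(cohort, rng, 4)
        with pytest.raises(ValueError, match="at least 3"):
            residual_ttest(edges, cohort)


class TestANCOVA:
    def test_metric_equal_to_age_absorbed(self):
        rng, cohort = make_cohort(10, 10, seed=7)
        metric = pd.Series(
            cohort["age"].to_numpy(), index=cohort["subject_id"], name="m"
        )
        t, p = ancova_group_effect(metric, cohort)
        # the age covariate fits the metric perfectly; the group term keeps
        # only numerical residue
        assert abs(t) < 0.5
        assert p > 0.5

    def test_permutation_null_p_uniform(self):
        rng, cohort = make_cohort(20, 20, seed=8)
        ps = []
        for rep in range(200):
            perm = cohort.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            metric = pd.Series(
                rng.normal(size=40), index=cohort["subject_id"]
            )
            ps.append(ancova_group_effect(metric, perm)[1])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_injected_shift_power(self):
        rng, cohort = make_cohort(20, 20, seed=9)
        detected = 0
        n_rep = 40
        for rep in range(n_rep):
            metric = pd.Series(
                rng.normal(size=40), index=cohort["subject_id"]
            )
            metric[cohort["group"].to_numpy() == "case"] += 1.0  # 1 SD shift
            if ancova_group_effect(metric, cohort)[1] < 0.05:
                detected += 1
        assert detected / n_rep > 0.8

    def test_undefined_metric_subjects_dropped(self):
        rng, cohort = make_cohort(10, 10, seed=10)
        metric = pd.Series(rng.normal(size=20), index=cohort["subject_id"])
        metric.iloc[:3] = np.nan
        t, p = ancova_group_effect(metric, cohort)
        assert np.isfinite(t) and 0 <= p <= 1
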