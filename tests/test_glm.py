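"""Design building, loading GLM inference, and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sbmtools import build_design, fdr_bh, fit_loading_glm
from sbmtools.glm import ADHD_TERMS, RankDeficiencyError


def _table(n, n_sites=2, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "diagnosis": rng.choice(["autism", "td"], size=n),
            "age": rng.uniform(6, 30, size=n),
            "sex": rng.choice(["male", "female"], size=n),
            "fsiq": rng.normal(100, 15, size=n),
            "site": rng.choice([f"site{j}" for j in range(n_sites)], size=n),
            "adhd": rng.integers(0, 2, size=n).astype(float),
        }
    )


class TestBuildDesign:
    def test_two_sites_one_dummy(self):
        d = build_design(_table(60, n_sites=2))
        assert sum(c.startswith("site[") for c in d.columns) == 1

    def test_listwise_deletion_with_adhd_term(self):
        t = _table(599)
        t.loc[t.index[:99], "adhd"] = np.nan  # ADHD known for 500 of 599
        d = build_design(t, ADHD_TERMS)
        assert d.n == 500
        assert build_design(t).n == 599  # main model unaffected

    def test_constant_age_with_age_squared_rank_deficient(self):
        t = _table(50)
        t["age"] = 12.0
        with pytest.raises(RankDeficiencyError):
            build_design(t, ("group", "age", "age2"))

    def test_group_coding_td_zero(self):
        t = _table(30)
        d = build_design(t, ("group",))
        gcol = d.matrix[:, d.group_col]
        aut = (t["diagnosis"] == "autism").to_numpy(float)
        np.testing.assert_array_equal(gcol, aut)


class TestFitLoadingGLM:
    def test_planted_component_has_smallest_p(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = _table(300, seed=seed)
            L = rng.laplace(0, 1 / np.sqrt(2), size=(300, 20))
            L[(t["diagnosis"] == "autism").to_numpy(), 3] += 0.8
            d = build_design(t)
            fit = fit_loading_glm(L[d.row_index], d)
            hits += int(np.argmin(fit.p)) == 3
        assert hits >= 9

    def test_null_p_values_uniform(self):
        """Group-independent noise loadings give uniform p over seeds."""
        pvals = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            t = _table(50, seed=seed)
            L = rng.normal(size=(50, 1))
            d = build_design(t)
            pvals.append(fit_loading_glm(L[d.row_index], d).p[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_perfect_separation_limit(self):
        t = _table(80)
        d = build_design(t, ("group",))
        L = d.matrix[:, [d.group_col]].copy()
        fit = fit_loading_glm(L, d)
        assert fit.p[0] == pytest.approx(0.0, abs=1e-30)
        assert abs(fit.d[0]) > 10

    def test_beta_equals_residualized_group_difference(self):
        """Frisch-Waugh: group beta = slope after residualizing on covariates."""
        rng = np.random.default_rng(2)
        t = _table(150, seed=2)
        L = rng.normal(size=(150, 4))
        d = build_design(t)
        fit = fit_loading_glm(L[d.row_index], d)
        X = d.matrix
        j = d.group_col
        Z = np.delete(X, j, axis=1)
        P = np.eye(len(X)) - Z @ np.linalg.pinv(Z)
        g_res = P @ X[:, j]
        for k in range(4):
            y_res = P @ L[d.row_index][:, k]
            beta_oracle = (g_res @ y_res) / (g_res @ g_res)
            assert fit.beta[k] == pytest.approx(beta_oracle, rel=1e-10)

    def test_sign_consistency(self):
        t = _table(120, seed=8)
        rng = np.random.default_rng(8)
        L = rng.normal(size=(120, 6))
        d = build_design(t)
        fit = fit_loading_glm(L[d.row_index], d)
        np.testing.assert_array_equal(np.sign(fit.t), np.sign(fit.beta))
        np.testing.assert_array_equal(np.sign(fit.d), np.sign(fit.t))


class TestFdrBH:
    def test_hand_executed_step_up(self):
        rejected, threshold = fdr_bh([0.001, 0.5, 0.9], q=0.05)
        assert list(rejected) == [0]
        assert threshold == 0.001

    def test_all_ones_reject_none(self):
        rejected, threshold = fdr_bh(np.ones(10), q=0.05)
        assert rejected.size == 0 and np.isnan(threshold)

    def test_all_at_critical_line_reject_all(self):
        m = 100
        p = 0.05 * np.arange(1, m + 1) / m
        rejected, _ = fdr_bh(p, q=0.05)
        assert rejected.size == m

    def test_empty_input(self):
        rejected, _ = fdr_bh([], q=0.05)
        assert rejected.size == 0

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            rejected, _ = fdr_bh(p, q=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            ours = np.zeros(len(p), bool)
            ours[rejected] = True
            np.testing.assert_array_equal(ours, ref)

    def test_monotone_in_p(self, rng):
        """Lowering any p-value never shrinks the rejection set."""
        for _ in range(20):
            p = rng.uniform(size=15)
            base, _ = fdr_bh(p, q=0.1)
            i = rng.integers(15)
            p2 = p.copy()
            p2[i] *= rng.uniform()
            new, _ = fdr_bh(p2, q=0.1)
            assert set(base) - {i} <= set(new)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_rejections_form_p_value_prefix(self, pvals, q):
        """BH rejects exactly the hypotheses at or below its threshold,
        and the threshold satisfies the step-up definition."""
        rejected, threshold = fdr_bh(pvals, q)
        p = np.asarray(pvals)
        if rejected.size == 0:
            assert np.isnan(threshold)
            # brute force: no rank satisfies p_(k) <= k q / m
            ranked = np.sort(p)
            m = len(p)
            assert not any(
                ranked[k - 1] <= k * q / m for k in range(1, m + 1)
            )
        else:
            assert set(rejected) == set(np.flatnonzero(p <= threshold))
            ranked = np.sort(p)
            m = len(p)
            k_star = max(
                k for k in range(1, m + 1) if ranked[k - 1] <= k * q / m
            )
            assert threshold == ranked[k_star - 1]
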