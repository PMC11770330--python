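"""Outcome statistics: classification, GLMs, FDR, CCA, mixed model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionfactors.association_stats import (
    SeparationError,
    bh_fdr,
    cca_first,
    domain_summary,
    fit_logistic,
    fit_logistic_mixed,
    lr_test,
    psci_classify,
    transition_table,
)


class TestDomainSummary:
    def test_single_test_identity(self):
        zs, ns = domain_summary({"memory": [0.7]})
        assert zs["memory"] == 0.7 and ns["memory"] == 1

    def test_symmetric_mean(self):
        zs, _ = domain_summary({"attention": [-1.0, 0.0, 1.0]})
        assert zs["attention"] == pytest.approx(0.0)

    def test_mean(self):
        zs, _ = domain_summary({"language": [-2.0, -1.0]})
        assert zs["language"] == pytest.approx(-1.5)

    def test_missing_tests_dropped(self):
        zs, ns = domain_summary({"memory": [np.nan, -1.0]})
        assert zs["memory"] == -1.0 and ns["memory"] == 1

    def test_empty_domain_flagged(self):
        zs, ns = domain_summary({"memory": [np.nan]})
        assert np.isnan(zs["memory"]) and ns["memory"] == 0


class TestPsciClassify:
    @pytest.mark.parametrize(
        "z, expected",
        [
            ((0, 0, 0, 0), 0),
            ((-1.6, 0, 0, 0), 1),
            ((-1.5, -1.5, -1.5, -1.5), 1),  # boundary inclusive
            ((-1.49, -1.49, -1.49, -1.49), 0),
        ],
    )
    def test_threshold_rule(self, z, expected):
        assert psci_classify(z) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            psci_classify((np.nan, 0, 0, 0))


class TestLogistic:
    def test_loglik_matches_direct_bernoulli_evaluation(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        eta = X @ [0.3, 1.0, -0.6]
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(y, X)
        p = 1 / (1 + np.exp(-(X @ fit.coef)))
        ll = np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        assert fit.loglik == pytest.approx(ll, rel=1e-8)

    def test_recovery_within_three_se(self):
        """Planted coefficient recovered within 3 SE in nearly all runs."""
        true = np.array([-0.5, 1.2])
        hits = 0
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            X = np.column_stack([np.ones(2000), rng.normal(size=2000)])
            y = (rng.uniform(size=2000) < 1 / (1 + np.exp(-(X @ true)))).astype(float)
            fit = fit_logistic(y, X)
            hits += abs(fit.coef[1] - true[1]) < 3 * fit.se[1]
        assert hits >= 28

    def test_or_and_ci_consistent(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(400), rng.normal(size=400)])
        y = (rng.uniform(size=400) < 0.4).astype(float)
        fit = fit_logistic(y, X)
        np.testing.assert_allclose(fit.or_, np.exp(fit.coef))
        assert np.all(fit.ci95[:, 0] <= fit.or_) and np.all(fit.or_ <= fit.ci95[:, 1])

    def test_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(50), np.ones(50)])
        with pytest.raises(ValueError, match="rank"):
            fit_logistic(np.random.default_rng(2).integers(0, 2, 50).astype(float), X)


class TestLRT:
    def test_identical_logliks(self):
        chi2, p = lr_test(-10.0, -10.0, 1)
        assert chi2 == 0.0 and p == 1.0

    def test_nesting_violation_rejected(self):
        with pytest.raises(ValueError, match="nesting"):
            lr_test(-12.0, -10.0, 1)

    def test_known_chi2_quantile(self):
        chi2, p = lr_test(-8.0, -9.92072941, 1)  # chi2 = 3.8415 -> p = 0.05
        assert p == pytest.approx(0.05, abs=1e-4)


class TestBH:
    def test_single_p_unchanged(self):
        p_adj, _ = bh_fdr([0.031])
        assert p_adj[0] == pytest.approx(0.031)

    def test_ties_all_equal(self):
        p_adj, _ = bh_fdr([0.02, 0.02, 0.02])
        np.testing.assert_allclose(p_adj, 0.02)

    def test_hand_computed_example(self):
        p_adj, reject = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(p_adj, [0.04, 0.04, 0.04, 0.04])
        assert reject.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_adjusted_p_monotone_capped_and_dominating(self, pvals):
        p = np.asarray(pvals)
        p_adj, _ = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(p_adj[order]) >= -1e-12)
        assert np.all(p_adj <= 1.0 + 1e-12)
        assert np.all(p_adj >= p - 1e-12)  # step-up never shrinks a p-value


class TestCCA:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 3))
        res = cca_first(X, X[:, 0].copy(), n_perm=99, seed=0)
        assert res.r1 == pytest.approx(1.0)

    def test_q1_equals_multiple_correlation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 4))
        yv = X @ [0.5, -0.2, 0.1, 0.3] + rng.normal(size=80)
        res = cca_first(X, yv, n_perm=99, seed=1)
        Xc = np.column_stack([np.ones(80), X])
        beta = np.linalg.lstsq(Xc, yv, rcond=None)[0]
        R = np.corrcoef(Xc @ beta, yv)[0, 1]
        assert res.r1 == pytest.approx(R, abs=1e-10)

    def test_constant_column_rejected(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            cca_first(X, rng.normal(size=40), n_perm=9)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            cca_first(rng.normal(size=(5, 4)), rng.normal(size=(5, 2)), n_perm=9)

    def test_perm_p_has_floor(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 2))
        res = cca_first(X, X[:, 0].copy(), n_perm=199, seed=2)
        assert res.perm_p == pytest.approx(1 / 200)


def _long_table(n, sigma, beta_f=2.0, beta_t=-0.4, beta_int=0.0, seed=1):
    r = np.random.default_rng(seed)
    load = r.dirichlet([1 / 3] * 3, n)[:, 1]
    age = r.normal(0, 1, n)
    edu = r.normal(0, 1, n)
    b = r.normal(0, sigma, n)
    frames = []
    for t in (0.0, 1.0):
        eta = -0.5 + beta_f * load + beta_t * t + beta_int * load * t + 0.5 * age - 0.4 * edu + b
        y = (r.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        frames.append(
            pd.DataFrame(
                {"subject_id": np.arange(n), "psci": y, "time": t,
                 "loading": load, "age": age, "education": edu}
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestMixedLogistic:
    def test_degenerates_to_plain_logistic(self):
        """With no between-subject heterogeneity the marginal MLE sits on
        the variance boundary and the fixed effects match a plain fit."""
        df = _long_table(400, sigma=1e-8, seed=5)
        mixed = fit_logistic_mixed(df)
        X = np.column_stack(
            [np.ones(len(df)), df.loading, df.time, df.loading * df.time, df.age, df.education]
        )
        plain = fit_logistic(df.psci.to_numpy(), X)
        rel = np.abs(mixed.coef - plain.coef) / np.maximum(np.abs(plain.coef), 1e-2)
        assert rel.max() < 0.02

    def test_quadrature_node_invariance(self):
        df = _long_table(150, sigma=1.0, seed=3)
        m15 = fit_logistic_mixed(df, n_nodes=15)
        m31 = fit_logistic_mixed(df, n_nodes=31)
        assert np.abs(m15.coef - m31.coef).max() < 1e-3

    def test_variance_recovered(self):
        df = _long_table(600, sigma=1.2, seed=7)
        m = fit_logistic_mixed(df)
        assert np.sqrt(m.re_var) == pytest.approx(1.2, abs=0.5)

    def test_zero_outcome_variance_rejected(self):
        df = _long_table(30, sigma=0.5, seed=9)
        df["psci"] = 1
        with pytest.raises(ValueError, match="variance"):
            fit_logistic_mixed(df)

    def test_missing_timepoint_allowed(self):
        df = _long_table(120, sigma=0.8, seed=11)
        df = df.drop(df[(df.time == 1.0) & (df.subject_id < 10)].index)
        m = fit_logistic_mixed(df)
        assert m.n_subjects == 120
        assert np.all(np.isfinite(m.coef))


class TestTransitionTable:
    def test_printed_cells_reproduce_marginals(self):
        psci6 = [1] * 30 + [1] * 25 + [0] * 10 + [0] * 40
        psci36 = [1] * 30 + [0] * 25 + [1] * 10 + [0] * 40
        tt = transition_table(psci6, psci36)
        assert (tt.both, tt.six_only, tt.thirtysix_only, tt.neither) == (30, 25, 10, 40)
        assert tt.month6_total == 55
        assert tt.month36_total == 40
        assert tt.converters == 35
        assert tt.n == 105

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            transition_table([0, 1], [1])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            transition_table([0, 2], [1, 0])
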