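"""ICP core: pooled regression, invariance tests, parent estimation and the
hidden-confounder estimator, each checked against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import special

import invarmir as iv
from invarmir.icp import UntestableSubsetError

# ---------------------------------------------------------------------------
# independent oracles (textbook formulas; no calls into invarmir internals)
# ---------------------------------------------------------------------------

def oracle_welch_p(a, b):
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / na + vb / nb
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * special.stdtr(df, -abs(t))


def oracle_f_p(a, b):
    na, nb = len(a), len(b)
    f = np.var(a, ddof=1) / np.var(b, ddof=1)
    # F cdf via regularised incomplete beta
    d1, d2 = na - 1, nb - 1
    cdf = special.betainc(d1 / 2, d2 / 2, d1 * f / (d1 * f + d2))
    return min(1.0, 2 * min(cdf, 1 - cdf))


def oracle_invariance_p(resid, mask):
    a, b = resid[mask], resid[~mask]
    return min(1.0, 2 * min(oracle_welch_p(a, b), oracle_f_p(a, b)))


def oracle_ols(X, Y, subset):
    n = len(Y)
    D = np.column_stack([np.ones(n)] + [X[:, j] for j in subset])
    coef = np.linalg.solve(D.T @ D, D.T @ Y)
    return coef, Y - D @ coef


def oracle_icp(X, Y, masks, alpha):
    """Exhaustive 2^p enumeration with the textbook-formula tests."""
    p = X.shape[1]
    accepted = []
    for size in range(p + 1):
        for subset in itertools.combinations(range(p), size):
            _, resid = oracle_ols(X, Y, subset)
            pv = min(oracle_invariance_p(resid, m) for m in masks)
            if min(1.0, len(masks) * pv) >= alpha:
                accepted.append(frozenset(subset))
    if accepted:
        parents = frozenset.intersection(*accepted)
    else:
        parents = frozenset()
    return accepted, parents


def _env_of(study):
    return study.env, study.regulators.sample_ids


# ---------------------------------------------------------------------------
# pooled regression
# ---------------------------------------------------------------------------

class TestFitPooledRegression:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=40)
        X = x[:, None]
        fit = iv.fit_pooled_regression(X, 2 * x, [0])
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-10)

    def test_empty_subset_mean_centres(self):
        fit = iv.fit_pooled_regression(np.zeros((3, 1)), [1.0, 2.0, 3.0], [])
        assert fit.intercept == pytest.approx(2.0)
        np.testing.assert_allclose(fit.residuals, [-1, 0, 1])

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(50, 3))
        Y = X @ [1.0, -2.0, 0.5] + rng.normal(size=50)
        fit = iv.fit_pooled_regression(X, Y, [0, 1, 2])
        coef, resid = oracle_ols(X, Y, (0, 1, 2))
        np.testing.assert_allclose(fit.coefficients, coef[1:], atol=1e-8)
        np.testing.assert_allclose(fit.residuals, resid, atol=1e-8)

    def test_collinear_subset_untestable(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(UntestableSubsetError):
            iv.fit_pooled_regression(X, x, [0, 1])


# ---------------------------------------------------------------------------
# invariance test
# ---------------------------------------------------------------------------

class TestInvariancePvalue:
    @staticmethod
    def _two_env(n1, n2):
        labels = {f"s{i}": ("A" if i < n1 else "B") for i in range(n1 + n2)}
        return iv.EnvironmentAssignment(labels), list(labels)

    def test_identical_groups_give_p_one(self):
        env, ids = self._two_env(4, 4)
        resid = np.array([0.3, -0.1, 0.2, -0.4] * 2)
        assert iv.invariance_pvalue(resid, env, "A", ids) == 1.0

    def test_large_mean_shift_drives_p_to_zero(self, rng):
        env, ids = self._two_env(200, 200)
        resid = np.concatenate([rng.normal(0, 1, 200), rng.normal(50, 1, 200)])
        assert iv.invariance_pvalue(resid, env, "A", ids) < 1e-10

    def test_matches_textbook_formula_on_fixed_vectors(self):
        a = np.array([0.1, -0.2, 0.05, 0.0])
        b = np.array([1.1, 0.9, 1.2, 0.8])
        env, ids = self._two_env(4, 4)
        resid = np.concatenate([a, b])
        expected = oracle_invariance_p(resid, np.array([True] * 4 + [False] * 4))
        assert iv.invariance_pvalue(resid, env, "A", ids) == pytest.approx(
            expected, rel=1e-12
        )

    def test_random_residuals_match_oracle(self, rng):
        env, ids = self._two_env(15, 25)
        for _ in range(20):
            resid = rng.normal(size=40) * rng.uniform(0.5, 2)
            mask = np.array([True] * 15 + [False] * 25)
            assert iv.invariance_pvalue(resid, env, "A", ids) == pytest.approx(
                oracle_invariance_p(resid, mask), rel=1e-10
            )

    def test_degenerate_constant_residuals(self):
        env, ids = self._two_env(3, 3)
        assert iv.invariance_pvalue(np.zeros(6), env, "A", ids) == 1.0


class TestTestSubset:
    def test_single_environment_rejected_at_construction(self):
        with pytest.raises(ValueError):
            iv.EnvironmentAssignment({f"s{i}": "A" for i in range(6)})

    def test_strong_shift_rejects_empty_set(self, rng):
        env = iv.EnvironmentAssignment(
            {f"s{i}": ("A" if i < 100 else "B") for i in range(200)}
        )
        ids = list(env.labels)
        Y = np.concatenate([rng.normal(0, 1, 100), rng.normal(10, 1, 100)])
        res = iv.test_subset(rng.normal(size=(200, 2)), Y, (), env, ids, alpha=0.05)
        assert not res.accepted

    def test_true_parents_accepted_near_level(self):
        """Under the invariant model the true set is accepted ~ (1-alpha)
        of the time; checked loosely here (tight check in acceptance)."""
        hits = 0
        reps = 60
        for seed in range(reps):
            s = iv.simulate_sem(
                p=3, t=1, parents_per_target=1, env_sizes=(100, 100),
                gamma_scale=1.0, intervention_scale=2.0,
                intervened_regulators="all", seed=seed,
            )
            env, ids = _env_of(s)
            true_idx = tuple(
                sorted(s.regulators.feature_ids.index(r)
                       for r in s.true_parents[s.targets.feature_ids[0]])
            )
            res = iv.test_subset(
                s.regulators.values.T, s.targets.values[0], true_idx, env, ids,
                alpha=0.05,
            )
            hits += res.accepted
        assert hits / reps >= 0.85


# ---------------------------------------------------------------------------
# parent estimation
# ---------------------------------------------------------------------------

class TestIcpParents:
    def test_matches_brute_force_oracle(self, rng):
        """Exhaustive search must agree exactly with an independent 2^p
        enumeration using textbook-formula tests."""
        for rep in range(12):
            p = int(rng.integers(2, 5))
            n = 40
            masks = [np.arange(2 * n) < n, np.arange(2 * n) >= n]
            X = rng.normal(size=(2 * n, p))
            X[masks[1]] *= rng.uniform(1, 2.5)
            gamma = rng.normal(size=p) * (rng.random(p) < 0.5)
            Y = X @ gamma + rng.normal(size=2 * n)
            env = iv.EnvironmentAssignment(
                {f"s{i}": ("A" if i < n else "B") for i in range(2 * n)}
            )
            ids = list(env.labels)
            res = iv.icp_parents(X, Y, env, ids, alpha=0.05, exhaustive=True)
            exp_accepted, exp_parents = oracle_icp(X, Y, masks, alpha=0.05)
            assert sorted(map(frozenset, res.accepted_sets)) == sorted(exp_accepted)
            assert res.parent_set == exp_parents

    def test_pure_noise_target_yields_empty_parents(self, rng):
        env = iv.EnvironmentAssignment(
            {f"s{i}": ("A" if i < 50 else "B") for i in range(100)}
        )
        ids = list(env.labels)
        X = rng.normal(size=(100, 3))
        Y = rng.normal(size=100)  # independent of X, invariant
        res = iv.icp_parents(X, Y, env, ids, exhaustive=True)
        assert () in [tuple(s) for s in res.accepted_sets]
        assert res.parent_set == frozenset()
        assert not res.model_rejected

    def test_outside_predictors_have_zero_score_and_bounds(self, tiny_study):
        s = tiny_study
        env, ids = _env_of(s)
        res = iv.icp_parents(
            s.regulators.values.T, s.targets.values[0], env, ids, exhaustive=True
        )
        in_any = set().union(*map(set, res.accepted_sets)) if res.accepted_sets else set()
        for j in range(s.regulators.n_features):
            if j not in in_any:
                assert res.scores[j] == 0.0
                assert tuple(res.coefficient_bounds[j]) == (0.0, 0.0)
            else:
                lo, hi = res.coefficient_bounds[j]
                assert lo <= res.scores[j] <= hi

    def test_alpha_monotonicity(self, tiny_study):
        """A smaller alpha never shrinks the accepted-set collection and the
        intersection is anti-monotone in it."""
        s = tiny_study
        env, ids = _env_of(s)
        X, Y = s.regulators.values.T, s.targets.values[1]
        res_loose = iv.icp_parents(X, Y, env, ids, alpha=0.01, exhaustive=True)
        res_tight = iv.icp_parents(X, Y, env, ids, alpha=0.2, exhaustive=True)
        loose = set(map(frozenset, res_loose.accepted_sets))
        tight = set(map(frozenset, res_tight.accepted_sets))
        assert tight <= loose
        if tight:
            assert res_loose.parent_set <= res_tight.parent_set

    def test_preselection_restricts_search(self, rng):
        n, p = 150, 12
        env = iv.EnvironmentAssignment(
            {f"s{i}": ("A" if i < 75 else "B") for i in range(n)}
        )
        ids = list(env.labels)
        X = rng.normal(size=(n, p))
        X[75:] *= 2.0
        Y = X[:, 0] - X[:, 1] + rng.normal(size=n)
        res = iv.icp_parents(X, Y, env, ids, preselect=4, max_set_size=2)
        searched = set().union(*(set(r.subset) for r in res.subset_results))
        assert len(searched) <= 4
        assert {0, 1} <= searched  # strongest predictors enter the lasso path first


# ---------------------------------------------------------------------------
# hidden ICP
# ---------------------------------------------------------------------------

class TestHiddenICP:
    def test_two_environment_closed_form(self, rng):
        s = iv.simulate_sem(
            p=3, t=1, parents_per_target=2, env_sizes=(300, 300),
            intervention_scale=2.0, intervened_regulators="all",
            hidden_dim=1, seed=2,
        )
        env, ids = _env_of(s)
        X, Y = s.regulators.values.T, s.targets.values[0]
        res = iv.hidden_icp_coefficients(X, Y, env, ids, n_boot=0)
        m = env.mask(env.environments[0], ids)
        G1, G2 = X[m].T @ X[m] / m.sum(), X[~m].T @ X[~m] / (~m).sum()
        g1, g2 = X[m].T @ Y[m] / m.sum(), X[~m].T @ Y[~m] / (~m).sum()
        closed = np.linalg.solve(G1 - G2, g1 - g2)
        np.testing.assert_allclose(res.coefficients, closed, atol=1e-8)

    def test_no_intervention_flags_degenerate(self, rng):
        n = 200
        env = iv.EnvironmentAssignment(
            {f"s{i}": ("A" if i < n else "B") for i in range(2 * n)}
        )
        ids = list(env.labels)
        X = np.tile(rng.normal(size=(n, 2)), (2, 1))  # identical in both envs
        Y = X[:, 0] + np.tile(rng.normal(size=n), 2)
        res = iv.hidden_icp_coefficients(X, Y, env, ids, n_boot=0)
        assert res.degenerate

    def test_null_gamma_intervals_cover_zero(self):
        covered = 0
        n_seeds = 12
        for seed in range(n_seeds):
            s = iv.simulate_sem(
                p=2, t=1, parents_per_target=0, env_sizes=(400, 400),
                gamma_scale=0.0, intervention_scale=2.0,
                intervened_regulators="all", hidden_dim=1, seed=seed,
            )
            env, ids = _env_of(s)
            res = iv.hidden_icp_coefficients(
                s.regulators.values.T, s.targets.values[0], env, ids,
                n_boot=60, seed=seed,
            )
            covered += all(
                lo <= 0 <= hi for lo, hi in res.conf_intervals
            )
        assert covered / n_seeds >= 0.8

    def test_bootstrap_deterministic_in_seed(self, tiny_study):
        s = tiny_study
        env, ids = _env_of(s)
        args = (s.regulators.values.T, s.targets.values[0], env, ids)
        a = iv.hidden_icp_coefficients(*args, n_boot=30, seed=5)
        b = iv.hidden_icp_coefficients(*args, n_boot=30, seed=5)
        np.testing.assert_array_equal(a.conf_intervals, b.conf_intervals)


# ---------------------------------------------------------------------------
# all-pairs scoring
# ---------------------------------------------------------------------------

class TestScoreAllPairs:
    def test_single_pair_reduces_to_single_target_result(self, rng):
        s = iv.simulate_sem(
            p=1, t=1, parents_per_target=1, env_sizes=(80, 80),
            intervention_scale=2.0, intervened_regulators="all", seed=4,
        )
        env, ids = _env_of(s)
        sm = iv.score_all_pairs(s.regulators, s.targets, s.env, method="hidden_icp")
        single = iv.hidden_icp_coefficients(
            s.regulators.values.T, s.targets.values[0], env, ids, n_boot=0
        )
        assert sm.scores.shape == (1, 1)
        assert sm.scores[0, 0] == pytest.approx(single.coefficients[0])

    def test_true_pairs_outscore_null_pairs(self, tiny_study):
        s = tiny_study
        sm = iv.score_all_pairs(s.regulators, s.targets, s.env, method="hidden_icp")
        true = s.true_pairs
        tr, nl = [], []
        for i, r in enumerate(sm.regulator_ids):
            for j, t in enumerate(sm.target_ids):
                (tr if (r, t) in true else nl).append(abs(sm.scores[i, j]))
        assert np.mean(tr) > np.mean(nl)

    def test_column_independence_under_target_permutation(self, tiny_study):
        s = tiny_study
        sm = iv.score_all_pairs(s.regulators, s.targets, s.env, method="hidden_icp")
        perm = list(reversed(s.targets.feature_ids))
        targets_perm = iv.ExpressionMatrix(s.targets.data.loc[perm])
        sm_perm = iv.score_all_pairs(s.regulators, targets_perm, s.env, method="hidden_icp")
        np.testing.assert_allclose(
            sm_perm.to_frame()[s.targets.feature_ids].to_numpy(), sm.scores
        )

    def test_sample_mismatch_fails_before_fitting(self, tiny_study, rng):
        s = tiny_study
        import pandas as pd

        other = iv.ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(2, 10)),
                         index=["t1", "t2"], columns=[f"x{i}" for i in range(10)])
        )
        with pytest.raises(ValueError, match="mismatch"):
            iv.score_all_pairs(s.regulators, other, s.env)

    def test_icp_method_zero_outside_accepted_sets(self, tiny_study):
        s = tiny_study
        sm = iv.score_all_pairs(
            s.regulators, s.targets, s.env, method="icp", exhaustive=True
        )
        assert sm.method == "icp"
        assert np.isfinite(sm.scores).all()
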