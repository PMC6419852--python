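import numpy as np
import pytest
from scipy import stats

import invarmir as iv


class TestSimulateSem:
    def test_regeneration_is_bit_identical(self):
        a = iv.simulate_sem(p=4, t=5, env_sizes=(20, 20), seed=13)
        b = iv.simulate_sem(p=4, t=5, env_sizes=(20, 20), seed=13)
        np.testing.assert_array_equal(a.regulators.values, b.regulators.values)
        np.testing.assert_array_equal(a.targets.values, b.targets.values)
        assert a.true_parents == b.true_parents
        assert a.env.labels == b.env.labels

    def test_different_seeds_differ(self):
        a = iv.simulate_sem(p=4, t=5, env_sizes=(20, 20), seed=13)
        b = iv.simulate_sem(p=4, t=5, env_sizes=(20, 20), seed=14)
        assert not np.array_equal(a.regulators.values, b.regulators.values)

    def test_zero_gamma_gives_empty_parent_sets(self):
        s = iv.simulate_sem(p=4, t=5, env_sizes=(20, 20), gamma_scale=0.0, seed=0)
        assert all(parents == {} for parents in s.true_parents.values())
        assert s.true_pairs == set()

    def test_null_intervention_leaves_environments_identical(self):
        """With intervention scale 1 and no hidden term, per-environment
        regulator variances agree (no identifiable signal)."""
        s = iv.simulate_sem(p=3, t=1, env_sizes=(2000, 2000),
                            intervention_scale=1.0, seed=5)
        ids = s.regulators.sample_ids
        m = s.env.mask(s.env.environments[0], ids)
        v1 = s.regulators.values[:, m].var(axis=1)
        v2 = s.regulators.values[:, ~m].var(axis=1)
        np.testing.assert_allclose(v1 / v2, 1.0, atol=0.15)

    def test_intervened_variance_ratio_matches_scale(self):
        s = iv.simulate_sem(p=6, t=1, env_sizes=(4000, 4000),
                            intervention_scale=2.0, intervened_regulators=[0, 1],
                            seed=7)
        ids = s.regulators.sample_ids
        m = s.env.mask(s.env.environments[0], ids)
        ratio = (s.regulators.values[:, ~m].var(axis=1)
                 / s.regulators.values[:, m].var(axis=1))
        np.testing.assert_allclose(ratio[:2], 4.0, rtol=0.15)   # sd x2 => var x4
        np.testing.assert_allclose(ratio[2:], 1.0, atol=0.1)

    def test_true_parent_ids_exist_and_matrices_share_samples(self):
        s = iv.simulate_sem(p=5, t=10, env_sizes=(15, 15, 15), seed=3)
        assert s.regulators.sample_ids == s.targets.sample_ids
        regs = set(s.regulators.feature_ids)
        for parents in s.true_parents.values():
            assert set(parents) <= regs

    def test_invalid_sizes_error(self):
        with pytest.raises(ValueError):
            iv.simulate_sem(p=0, t=1, env_sizes=(10, 10))
        with pytest.raises(ValueError):
            iv.simulate_sem(p=2, t=1, env_sizes=(10,))

    def test_residual_invariance_pvalues_roughly_uniform(self):
        """After subtracting the true parent contribution, the target
        residuals are environment-invariant, so the invariance p-value is
        ~Uniform(0,1) over replicates -- the property ICP exploits."""
        pvals = []
        for seed in range(120):
            s = iv.simulate_sem(p=3, t=1, parents_per_target=2,
                                env_sizes=(50, 50), intervention_scale=2.0,
                                intervened_regulators="all", seed=1000 + seed)
            tid = s.targets.feature_ids[0]
            resid = s.targets.values[0] - s.gamma_vector(tid) @ s.regulators.values
            resid = resid - resid.mean()
            pvals.append(iv.invariance_pvalue(
                resid, s.env, s.env.environments[0], s.regulators.sample_ids
            ))
        # Bonferroni-combined p-values are conservative (capped at 1), so
        # test uniformity only on the sub-unit part: no excess of small ps
        assert np.mean(np.asarray(pvals) < 0.05) < 0.12
        assert stats.kstest(pvals, "uniform").pvalue > 1e-4 or np.mean(pvals) > 0.4

    def test_heavy_tailed_noise_option(self):
        s = iv.simulate_sem(p=3, t=2, env_sizes=(500, 500), noise_dist="student_t",
                            seed=9)
        assert np.isfinite(s.targets.values).all()
        with pytest.raises(ValueError):
            iv.simulate_sem(p=2, t=1, env_sizes=(10, 10), noise_dist="cauchy")


class TestValidationFixtures:
    def test_zero_noise_db_is_exactly_truth(self):
        s = iv.simulate_sem(p=4, t=6, env_sizes=(15, 15), seed=21)
        _, db = iv.make_validation_fixtures(s, noise_rate=0.0)
        assert db.pairs == {(a.lower(), b.lower()) for a, b in s.true_pairs}

    def test_full_noise_doubles_db(self):
        s = iv.simulate_sem(p=4, t=6, env_sizes=(15, 15), seed=21)
        _, db = iv.make_validation_fixtures(s, noise_rate=1.0)
        assert len(db) == 2 * len(s.true_pairs)

    def test_true_pairs_almost_always_exceed_threshold(self):
        """|log2FC| for true pairs is |N(1, 0.2)|: crossing below 0.3 has
        Gaussian-tail probability ~2e-4, so large studies confirm nearly
        all true pairs."""
        s = iv.simulate_sem(p=20, t=120, parents_per_target=3,
                            env_sizes=(15, 15), seed=2)
        table, _ = iv.make_validation_fixtures(s, noise_rate=0.0)
        res = iv.confirm_by_transfection(sorted(s.true_pairs), table, threshold=0.3)
        n_true = len(s.true_pairs)
        expected_rate = 2 * stats.norm.sf((1.0 - 0.3) / 0.2)  # P(|N(1,.2)|<=.3)
        assert res.uncheckable_count == 0
        assert res.confirmed_count >= n_true * (1 - 10 * expected_rate) - 3

    def test_null_pairs_rarely_confirm(self):
        s = iv.simulate_sem(p=10, t=30, parents_per_target=1,
                            env_sizes=(15, 15), seed=4)
        table, _ = iv.make_validation_fixtures(s, noise_rate=0.0)
        null_pairs = [
            (r, t)
            for r in s.regulators.feature_ids
            for t in s.targets.feature_ids
            if (r, t) not in s.true_pairs
        ]
        res = iv.confirm_by_transfection(null_pairs, table, threshold=0.3)
        # P(|N(0, 0.15)| > 0.3) = 4.6%
        assert res.confirmed_count / len(null_pairs) < 0.10

    def test_fixtures_deterministic(self):
        s = iv.simulate_sem(p=3, t=4, env_sizes=(10, 10), seed=8)
        t1, d1 = iv.make_validation_fixtures(s, noise_rate=0.5)
        t2, d2 = iv.make_validation_fixtures(s, noise_rate=0.5)
        assert t1.log2fc == t2.log2fc
        assert d1.pairs == d2.pairs


def test_write_study_round_trips(tmp_path):
    s = iv.simulate_sem(p=3, t=4, env_sizes=(10, 10), seed=6)
    paths = iv.write_study(s, tmp_path / "study")
    regs = iv.read_expression_matrix(paths["regulators"])
    np.testing.assert_allclose(regs.values, s.regulators.values, atol=1e-12)
    env = iv.read_environment_labels(paths["environments"], min_size=2)
    assert env.labels == s.env.labels
    db = iv.GroundTruthDB.from_csv(paths["database"])
    assert len(db) > 0
    table = iv.TransfectionTable.from_csv(paths["transfection"])
    assert len(table) == 12
    import json

    manifest = json.loads((tmp_path / "study" / "manifest.json").read_text())
    assert manifest["seed"] == 6
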