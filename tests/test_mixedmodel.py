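"""REML, BLUP and prediction against independent algebraic oracles."""

import numpy as np
import pytest

from gfblup import (
    SimulationConfig,
    blup_solve,
    predict_gebv,
    reml_fit,
    restricted_loglik,
    simulate_feature_map,
    simulate_genotypes,
    simulate_phenotypes,
    summarize_partition,
)
from gfblup.grm import RelationshipMatrix
from gfblup.mixedmodel import VarianceComponents


def vanraden_grm(dosages, freqs=None):
    if freqs is None:
        freqs = dosages.mean(0) / 2
    w = (dosages - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))
    return w @ w.T / dosages.shape[1], w


@pytest.fixture(scope="module")
def one_grm_data():
    """Seeded single-component simulation (n=30) for the grid oracle."""
    rng = np.random.default_rng(30)
    dos = rng.binomial(2, rng.uniform(0.1, 0.5, 80), size=(30, 80)).astype(float)
    g, w = vanraden_grm(dos)
    u = w @ rng.normal(0, np.sqrt(1.2 / 80), 80)
    y = 1.0 + u + rng.normal(0, np.sqrt(0.8), 30)
    return y, g


class TestRestrictedLoglik:
    def test_iid_closed_form(self):
        y = np.array([1.0, 2.0, 3.0])
        n, s2 = 3, 1.0
        hand = -0.5 * (
            (n - 1) * np.log(2 * np.pi)
            + (n - 1) * np.log(s2)
            + np.log(n / s2)
            + ((y - y.mean()) ** 2).sum() / s2
        )
        assert restricted_loglik([s2], y, []) == pytest.approx(hand, rel=1e-12)

    def test_scale_equivariance(self, one_grm_data):
        y, g = one_grm_data
        c2 = 4.0
        base = restricted_loglik([1.0, 0.5], y, [g])
        scaled = restricted_loglik([c2, 0.5 * c2], 2.0 * y, [g])
        # scaling y by c and variances by c^2 shifts the likelihood by (n-1) log c
        assert scaled == pytest.approx(base - (y.size - 1) * np.log(2.0), rel=1e-10)

    def test_permutation_invariance(self, one_grm_data):
        y, g = one_grm_data
        perm = np.random.default_rng(1).permutation(y.size)
        a = restricted_loglik([0.9, 0.7], y, [g])
        b = restricted_loglik([0.9, 0.7], y[perm], [g[np.ix_(perm, perm)]])
        assert a == pytest.approx(b, rel=1e-12)

    def test_singular_v_raises(self):
        y = np.arange(5.0)
        with pytest.raises(ValueError):
            restricted_loglik([1.0, 0.0], y, [np.zeros((5, 5))], np.ones(5) * 0.0 + 1e-300)


class TestRemlFit:
    def test_residual_only_is_sample_variance(self):
        y = np.array([1.0, 2.0, 3.0])
        vc = reml_fit(y, [])
        assert vc.variances[0] == pytest.approx(1.0, rel=1e-6)  # unbiased variance
        fit = blup_solve(vc, y, [])
        assert fit.mu == pytest.approx(2.0, rel=1e-12)

    def test_agrees_with_grid_search_oracle(self, one_grm_data):
        """AI-REML optimum matches an exhaustive likelihood grid at 0.01."""
        y, g = one_grm_data
        vc = reml_fit(y, [g], names=["g", "e"])

        def grid_argmax(lo, hi, step):
            s_g = np.arange(lo[0], hi[0] + step / 2, step)
            s_e = np.arange(max(lo[1], step), hi[1] + step / 2, step)
            best, arg = -np.inf, None
            for a in s_g:
                for b in s_e:
                    ll = restricted_loglik([a, b], y, [g])
                    if ll > best:
                        best, arg = ll, (a, b)
            return arg

        top = 3.0 * np.var(y, ddof=1)
        coarse = grid_argmax((0.0, 0.05), (top, top), 0.05)
        fine = grid_argmax(
            (max(0.0, coarse[0] - 0.1), max(0.01, coarse[1] - 0.1)),
            (coarse[0] + 0.1, coarse[1] + 0.1),
            0.01,
        )
        assert vc["g"] == pytest.approx(fine[0], abs=0.011)
        assert vc["e"] == pytest.approx(fine[1], abs=0.011)

    def test_likelihood_not_below_start(self, one_grm_data):
        y, g = one_grm_data
        init = [0.1, 2.5]
        vc = reml_fit(y, [g], init=init)
        assert vc.loglik >= restricted_loglik(init, y, [g]) - 1e-9
        assert vc.converged

    @pytest.mark.parametrize("seed", [99, 100, 101])
    def test_gfblup_and_gblup_heritabilities_agree(self, seed):
        """Total genomic h2 is nearly identical under the 1- and 2-component models."""
        cfg = SimulationConfig(n_individuals=1000, n_variants=3000, n_populations=1,
                               h2=0.4, feature_share=0.3, n_genes=150, n_terms=5,
                               seed=seed)
        panels = simulate_genotypes(cfg)
        panel = panels["popA"]
        fmap, _ = simulate_feature_map(panel, cfg)
        phen, truth = simulate_phenotypes(panels, fmap, cfg)
        y = phen["drp"].to_numpy()
        d = (1 - phen["reliability"].to_numpy()) / phen["reliability"].to_numpy()
        from gfblup import compute_grm, partition_grms

        g_all = compute_grm(panel)
        g_f, g_r = partition_grms(panel, fmap.variant_indices(truth.focal_term), g_all=g_all)
        vc1 = reml_fit(y, [g_all.values], d, names=["g", "e"])
        vc2 = reml_fit(y, [g_f.values, g_r.values], d, names=["f", "r", "e"])
        h2_gblup = summarize_partition(vc1, g_all.m_used, 0).h2
        h2_gfblup = summarize_partition(vc2, g_f.m_used, g_r.m_used).h2
        assert h2_gfblup == pytest.approx(h2_gblup, abs=0.02)

    def test_nonconvergence_is_flagged(self, one_grm_data):
        y, g = one_grm_data
        vc = reml_fit(y, [g], max_iter=1, init=[3.0, 0.01])
        assert not vc.converged


class TestBlup:
    def test_zero_genetic_variance_gives_zero_blups(self, one_grm_data):
        y, g = one_grm_data
        vc = VarianceComponents(
            variances=np.array([0.0, 1.0]), names=["g", "e"],
            se=np.full(2, np.nan), loglik=0.0, converged=True, n_iter=0,
        )
        fit = blup_solve(vc, y, [g])
        np.testing.assert_allclose(fit.gebv, 0.0)

    def test_duplicated_individuals_get_equal_blups(self):
        dos = np.array([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0], [2, 1, 0, 0, 1],
                        [1, 2, 1, 0, 2]], dtype=float)
        g, _ = vanraden_grm(dos)
        g += 1e-6 * np.eye(4)
        y = np.array([1.0, 1.0, -0.5, 0.3])
        vc = VarianceComponents(
            variances=np.array([1.0, 0.5]), names=["g", "e"],
            se=np.full(2, np.nan), loglik=0.0, converged=True, n_iter=0,
        )
        fit = blup_solve(vc, y, [g])
        assert fit.gebv[0] == pytest.approx(fit.gebv[1], rel=1e-10)

    def test_single_component_matches_mme_oracle(self, one_grm_data):
        """Henderson's equations with C = [X Z; Z'X Z'Z + G^-1 lambda]."""
        y, g = one_grm_data
        g = g + 1e-6 * np.eye(y.size)
        s2g, s2e = 0.9, 0.7
        vc = VarianceComponents(
            variances=np.array([s2g, s2e]), names=["g", "e"],
            se=np.full(2, np.nan), loglik=0.0, converged=True, n_iter=0,
        )
        fit = blup_solve(vc, y, [g])
        n = y.size
        lam = s2e / s2g
        x = np.ones((n, 1))
        lhs = np.block(
            [[x.T @ x, x.T], [x, np.eye(n) + np.linalg.inv(g) * lam]]
        )
        rhs = np.r_[x.T @ y, y]
        sol = np.linalg.solve(lhs, rhs)
        assert fit.mu == pytest.approx(sol[0], abs=1e-8)
        np.testing.assert_allclose(fit.gebv, sol[1:], atol=1e-8)


class TestPredict:
    def _two_component_setup(self, n=120, n_target=40, seed=17):
        rng = np.random.default_rng(seed)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 400), size=(n + n_target, 400)).astype(float)
        freqs = dos.mean(0) / 2
        ids = np.array([f"i{i}" for i in range(n + n_target)], dtype=object)
        feat = np.arange(60)
        rest = np.arange(60, 400)
        mats = []
        for sub in (feat, rest):
            w = (dos[:, sub] - 2 * freqs[sub]) / np.sqrt(2 * freqs[sub] * (1 - freqs[sub]))
            vals = w @ w.T / sub.size + 1e-6 * np.eye(n + n_target)
            mats.append(RelationshipMatrix(vals, ids, sub, "obs", sub.size, 1e-6))
        y = rng.normal(0, 1, n)
        d = np.ones(n)
        vc = VarianceComponents(
            variances=np.array([0.4, 0.8, 0.9]), names=["f", "r", "e"],
            se=np.full(3, np.nan), loglik=0.0, converged=True, n_iter=0,
        )
        fit = blup_solve(vc, y, [m.values[:n, :n] for m in mats], d, training_ids=ids[:n])
        return fit, mats, ids[:n], ids[n:], y, d

    def test_identical_target_equals_training_prediction(self):
        fit, mats, train_ids, target_ids, y, d = self._two_component_setup()
        # make target 0 a genomic copy of training individual 0
        for m in mats:
            m.values[len(train_ids), :] = m.values[0, :]
            m.values[:, len(train_ids)] = m.values[:, 0]
            m.values[len(train_ids), len(train_ids)] = m.values[0, 0]
        pred = predict_gebv(fit, mats, train_ids, target_ids)
        assert pred["gebv"][0] == pytest.approx(fit.gebv[0], rel=1e-8)

    def test_zero_variances_give_zero_gebv(self):
        fit, mats, train_ids, target_ids, y, d = self._two_component_setup()
        fit.vc.variances[:2] = 0.0
        fit = blup_solve(fit.vc, y, [m.values[: y.size, : y.size] for m in mats], d,
                         training_ids=train_ids)
        pred = predict_gebv(fit, mats, train_ids, target_ids)
        np.testing.assert_allclose(pred["gebv"], 0.0)

    def test_block_formula_matches_joint_mme_oracle(self):
        """Conditional-mean prediction equals Henderson MME with missing records."""
        fit, mats, train_ids, target_ids, y, d = self._two_component_setup()
        pred = predict_gebv(fit, mats, train_ids, target_ids)
        n, n_all = y.size, y.size + target_ids.size
        s2f, s2r, s2e = fit.vc.variances
        z = np.hstack([np.eye(n), np.zeros((n, n_all - n))])
        rinv = np.diag(1.0 / (d * s2e))
        x = np.ones((n, 1))
        gfi = np.linalg.inv(mats[0].values) / s2f
        gri = np.linalg.inv(mats[1].values) / s2r
        ztr = z.T @ rinv
        lhs = np.block(
            [
                [x.T @ rinv @ x, x.T @ rinv @ z, x.T @ rinv @ z],
                [ztr @ x, ztr @ z + gfi, ztr @ z],
                [ztr @ x, ztr @ z, ztr @ z + gri],
            ]
        )
        rhs = np.r_[x.T @ rinv @ y, ztr @ y, ztr @ y]
        sol = np.linalg.solve(lhs, rhs)
        u_f = sol[1 : 1 + n_all]
        u_r = sol[1 + n_all :]
        np.testing.assert_allclose(pred["f"], u_f[n:], atol=1e-8)
        np.testing.assert_allclose(pred["r"], u_r[n:], atol=1e-8)
        np.testing.assert_allclose(pred["gebv"], (u_f + u_r)[n:], atol=1e-8)

    def test_unknown_target_rejected(self):
        fit, mats, train_ids, target_ids, *_ = self._two_component_setup()
        with pytest.raises(KeyError):
            predict_gebv(fit, mats, train_ids, np.array(["ghost"], dtype=object))


class TestEquivalences:
    def test_gblup_equals_snp_blup_ridge(self):
        """VanRaden equivalence: G-model GEBV = ridge-regression marker BLUP."""
        rng = np.random.default_rng(4)
        n, m = 80, 200
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        g, w = vanraden_grm(dos)
        y = rng.normal(0, 1, n)
        s2g, s2e = 0.6, 0.9
        vc = VarianceComponents(
            variances=np.array([s2g, s2e]), names=["g", "e"],
            se=np.full(2, np.nan), loglik=0.0, converged=True, n_iter=0,
        )
        fit = blup_solve(vc, y, [g])
        # SNP-BLUP: u ~ N(0, I s2g/m), gebv = W u_hat with matched shrinkage
        lam = s2e / (s2g / m)
        xc = np.hstack([np.ones((n, 1)), w])
        lhs = xc.T @ xc + lam * np.diag(np.r_[0.0, np.ones(m)])
        sol = np.linalg.solve(lhs, xc.T @ y)
        np.testing.assert_allclose(fit.gebv, w @ sol[1:], atol=1e-6)

    def test_gfblup_degenerates_to_gblup(self):
        """As the feature variance vanishes, GFBLUP GEBV approach GBLUP GEBV."""
        rng = np.random.default_rng(6)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(70, 300)).astype(float)
        g_all, _ = vanraden_grm(dos)
        g_f, _ = vanraden_grm(dos[:, :50])
        # remainder built from the identity m G = m_f G_f + m_R G_R
        g_r = (300 * g_all - 50 * g_f) / 250
        y = rng.normal(0, 1, 70)
        gebv_prev = None
        for eps in (1e-3, 1e-6):
            vc2 = VarianceComponents(np.array([eps, 1.0 * 250 / 250, 0.8]),
                                     ["f", "r", "e"], np.full(3, np.nan), 0.0, True, 0)
            fit2 = blup_solve(vc2, y, [g_f, g_r])
            vc0 = VarianceComponents(np.array([1.0, 0.8]), ["g", "e"],
                                     np.full(2, np.nan), 0.0, True, 0)
            fit0 = blup_solve(vc0, y, [g_r])
            diff = np.abs(fit2.gebv - fit0.gebv).max()
            if gebv_prev is not None:
                assert diff < gebv_prev
            gebv_prev = diff
        assert gebv_prev < 1e-4


class TestPartitionSummary:
    def test_ratio_examples(self):
        vc = VarianceComponents(np.array([2.0, 8.0, 1.0]), ["f", "r", "e"],
                                np.full(3, np.nan), 0.0, True, 0)
        s = summarize_partition(vc, 100, 900)
        assert s.h2_feature == pytest.approx(0.2)
        assert s.snp_f == pytest.approx(0.1)

    def test_snp_f_of_printed_counts(self):
        """586 feature variants out of 15,355,382 give SNP_f ~ 0.0038%."""
        vc = VarianceComponents(np.array([1.0, 1.0, 1.0]), ["f", "r", "e"],
                                np.full(3, np.nan), 0.0, True, 0)
        s = summarize_partition(vc, 586, 15_355_382 - 586)
        assert s.snp_f == pytest.approx(586 / 15_355_382, rel=1e-12)
        assert 0.00003 <= s.snp_f <= 0.00029  # the reported milk-trait range

    def test_equal_components_heritability(self):
        vc = VarianceComponents(np.array([1.0, 1.0, 1.0]), ["f", "r", "e"],
                                np.full(3, np.nan), 0.0, True, 0)
        assert summarize_partition(vc, 1, 1).h2 == pytest.approx(2 / 3)

    def test_undefined_h2f_reported_missing(self):
        vc = VarianceComponents(np.array([0.0, 0.0, 1.0]), ["f", "r", "e"],
                                np.full(3, np.nan), 0.0, True, 0)
        assert np.isnan(summarize_partition(vc, 1, 1).h2_feature)
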