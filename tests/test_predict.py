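"""Mixed-model prediction: REML, BLUP algebra, multi-kernel fits, CV harnesses."""

import warnings

import numpy as np
import pandas as pd
import pytest

from covcomb import (
    GBLUP,
    LabeledMatrix,
    MultiKernelGBLUP,
    ValidationError,
    cv_leave_dataset_out,
    cv_random_folds,
    gblup_predict,
    grm_vanraden,
    multikernel_reml,
    reml_spectral,
)
from covcomb.predict import MixedModelFit
from covcomb.synthetic import simulate_markers, simulate_phenotypes

from conftest import labeled_spd, random_spd


def sim_trait_kernel(n=200, n_markers=800, h2=0.5, seed=0):
    G = grm_vanraden(simulate_markers(n, n_markers, seed=seed))
    y = simulate_phenotypes(G, h2, seed=seed + 1000)
    return y, G


class TestRemlSpectral:
    def test_constant_y_gives_zero_variances(self, rng):
        k = labeled_spd(list("abcdef"), rng)
        y = pd.Series(3.14, index=k.labels)
        fit = reml_spectral(y, k)
        assert fit.var_components.tolist() == [0.0, 0.0]
        assert np.allclose(fit.genotype_effects, 0.0)

    def test_h2_recovery_in_simulation(self):
        ests = []
        for seed in range(6):
            y, G = sim_trait_kernel(n=250, h2=0.5, seed=seed)
            ests.append(reml_spectral(y, G).h2)
        assert abs(np.mean(ests) - 0.5) < 0.15

    def test_identity_kernel_not_identifiable(self):
        k = LabeledMatrix(list("abcd"), np.eye(4))
        y = pd.Series([1.0, 2.0, 0.5, 1.5], index=k.labels)
        with pytest.raises(ValidationError, match="identifiable"):
            reml_spectral(y, k)

    def test_blup_solves_mixed_model_equations(self, rng):
        """At a fixed variance ratio, GEBVs must solve Henderson's equations.

        Independent oracle: build the 2x2-block MME with X = 1 and Z = I
        and solve it directly with plain numpy.
        """
        from covcomb.predict import _blup_given_ratio

        k = labeled_spd(["a", "b", "c"], rng)
        y = np.array([1.0, -0.5, 0.7])
        lam = 2.0
        mu, ghat = _blup_given_ratio(y, k.values, lam)
        n = 3
        X = np.ones((n, 1))
        Kinv = np.linalg.inv(k.values)
        lhs = np.block([
            [X.T @ X, X.T],
            [X, np.eye(n) + Kinv / lam],
        ])
        rhs = np.concatenate([X.T @ y, y])
        sol = np.linalg.solve(lhs, rhs)
        assert mu == pytest.approx(sol[0], rel=1e-9)
        np.testing.assert_allclose(ghat, sol[1:], rtol=1e-9)

    def test_intercept_shift_only_moves_intercept(self, rng):
        y, G = sim_trait_kernel(n=80, h2=0.6, seed=3)
        f0 = reml_spectral(y, G)
        f1 = reml_spectral(y + 100.0, G)
        assert f1.fixed_effects[0] == pytest.approx(f0.fixed_effects[0] + 100.0,
                                                    abs=1e-6)
        np.testing.assert_allclose(f1.genotype_effects, f0.genotype_effects,
                                   atol=1e-6)


class TestGblupPredict:
    def test_identical_row_gets_identical_gebv(self, rng):
        # build a 4-genotype kernel where 'd' duplicates 'c'
        base = random_spd(3, rng)
        K = np.zeros((4, 4))
        K[:3, :3] = base
        K[3, :3] = base[2]
        K[:3, 3] = base[2]
        K[3, 3] = base[2, 2]
        k = LabeledMatrix(list("abcd"), K)
        fit = MixedModelFit(np.array([1.0, 1.0]), np.zeros(1),
                            pd.Series([0.3, -0.2, 0.9], index=list("abc")), 0.5)
        p = gblup_predict(fit, k, ["d"])
        assert p["d"] == pytest.approx(0.9, abs=1e-5)

    def test_unrelated_test_gets_prior_mean_zero(self, rng):
        K = np.eye(4)
        K[:3, :3] = random_spd(3, rng)
        k = LabeledMatrix(list("abcd"), K)
        fit = MixedModelFit(np.array([1.0, 1.0]), np.zeros(1),
                            pd.Series([0.3, -0.2, 0.9], index=list("abc")), 0.5)
        assert gblup_predict(fit, k, ["d"])["d"] == pytest.approx(0.0, abs=1e-9)

    def test_two_train_one_test_hand_solve(self):
        K = np.array([[1.0, 0.2, 0.5],
                      [0.2, 1.0, 0.4],
                      [0.5, 0.4, 1.0]])
        k = LabeledMatrix(list("abc"), K)
        ghat = np.array([0.6, -0.4])
        fit = MixedModelFit(np.array([1.0, 1.0]), np.zeros(1),
                            pd.Series(ghat, index=list("ab")), 0.5)
        expect = K[2, :2] @ np.linalg.solve(K[:2, :2], ghat)
        assert gblup_predict(fit, k, ["c"])["c"] == pytest.approx(expect, rel=1e-6)

    def test_unknown_test_label_named(self, rng):
        k = labeled_spd(list("ab"), rng)
        fit = MixedModelFit(np.array([1.0, 1.0]), np.zeros(1),
                            pd.Series([0.1], index=["a"]), 0.5)
        with pytest.raises(ValidationError, match="zzz"):
            gblup_predict(fit, k, ["zzz"])


class TestMultiKernel:
    def test_single_kernel_agrees_with_spectral(self):
        y, G = sim_trait_kernel(n=150, h2=0.4, seed=11)
        f1 = reml_spectral(y, G)
        f2 = multikernel_reml(y, [G])
        np.testing.assert_allclose(f1.var_components, f2.var_components,
                                   atol=1e-6)

    def test_null_second_kernel_estimated_near_zero(self, rng):
        y, G = sim_trait_kernel(n=150, h2=0.5, seed=21)
        noise = labeled_spd(G.labels, rng)  # unrelated kernel, no true effect
        fit = multikernel_reml(y, [G, noise])
        s_g, s_noise, s_e = fit.var_components
        assert s_noise < 0.2 * s_g

    def test_duplicate_kernels_warn_and_preserve_total(self):
        y, G = sim_trait_kernel(n=120, h2=0.5, seed=31)
        single = multikernel_reml(y, [G])
        with pytest.warns(UserWarning, match="identical"):
            dup = multikernel_reml(y, [G, G])
        total_single = single.var_components[0]
        total_dup = dup.var_components[0] + dup.var_components[1]
        assert total_dup == pytest.approx(total_single, rel=0.05)

    def test_variance_ratio_recovery(self):
        # two independent kernels with true variances 2:1
        ratios = []
        for seed in range(5):
            G1 = grm_vanraden(simulate_markers(200, 600, seed=seed))
            G2 = grm_vanraden(simulate_markers(200, 600, seed=seed + 100))
            rng = np.random.default_rng(seed)
            d1 = float(np.mean(np.diag(G1.values)))
            d2 = float(np.mean(np.diag(G2.values)))
            L1 = np.linalg.cholesky(G1.values / d1 + 1e-6 * np.eye(200))
            L2 = np.linalg.cholesky(G2.values / d2 + 1e-6 * np.eye(200))
            y = pd.Series(
                np.sqrt(2.0) * (L1 @ rng.standard_normal(200))
                + 1.0 * (L2 @ rng.standard_normal(200))
                + rng.standard_normal(200),
                index=G1.labels,
            )
            fit = multikernel_reml(y, [G1, G2])
            s1, s2, _ = fit.var_components
            ratios.append(s1 / max(s2, 1e-8))
        mean_ratio = np.mean(ratios)
        assert 1.0 < mean_ratio < 4.0  # true ratio 2, within a factor of 2

    def test_model_objects_wrap_functions(self):
        y, G = sim_trait_kernel(n=80, h2=0.5, seed=41)
        fit = GBLUP(y.iloc[:60], G).fit()
        assert "h2" in fit.summary()
        mfit = MultiKernelGBLUP(y.iloc[:60], [G]).fit()
        preds = MultiKernelGBLUP(y.iloc[:60], [G]).predict(mfit, y.index[60:])
        assert len(preds) == 20


class TestCrossValidation:
    def test_folds_disjoint_cover_and_seed_stable(self):
        y, G = sim_trait_kernel(n=60, h2=0.8, seed=51)
        r1 = cv_random_folds(y, G, n_folds=5, seed=7)
        r2 = cv_random_folds(y, G, n_folds=5, seed=7)
        assert r1.table["n_test"].sum() == 60
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert set(r1.predictions.index) == set(y.index)

    def test_near_noiseless_trait_predicts_well(self):
        # dense kernel: clone-like groups related 0.9, so every test genotype
        # has near-replicates in training; conditional accuracy ~0.93
        n, gsz = 120, 4
        K = np.zeros((n, n))
        for b in range(n // gsz):
            K[b * gsz:(b + 1) * gsz, b * gsz:(b + 1) * gsz] = 0.9
        np.fill_diagonal(K, 1.0)
        k = LabeledMatrix([f"g{i:03d}" for i in range(n)], K)
        y = simulate_phenotypes(k, 0.99, seed=62)
        res = cv_random_folds(y, k, n_folds=5, seed=1)
        assert res.pooled_accuracy > 0.8

    def test_tiny_fold_rejected(self):
        y, G = sim_trait_kernel(n=8, h2=0.5, seed=71)
        with pytest.raises(ValidationError, match="fold"):
            cv_random_folds(y, G, n_folds=4, seed=0)

    def _blocky(self, n_per=25, n_data=3, rho=0.6, h2=0.7, seed=5):
        n = n_per * n_data
        K = np.full((n, n), 0.02)
        for b in range(n_data):
            s = slice(b * n_per, (b + 1) * n_per)
            K[s, s] = rho
        np.fill_diagonal(K, 1.0)
        k = LabeledMatrix([f"g{i:03d}" for i in range(n)], K)
        y = simulate_phenotypes(k, h2, seed=seed)
        member = {l: f"d{i // n_per}" for i, l in enumerate(k.labels)}
        return y, k, member

    def test_identical_duplicated_datasets_score_equal(self):
        G = grm_vanraden(simulate_markers(20, 400, seed=8))
        y = simulate_phenotypes(G, 0.7, seed=9)
        y2 = pd.concat([y, y.rename(index=lambda s: s + "_dup")])
        n = len(y)
        K = G.values
        K2 = np.block([[K, K], [K, K]])
        # make the doubled kernel strictly valid (symmetric, PSD enough)
        k2 = LabeledMatrix(list(y2.index), K2 + 1e-6 * np.eye(2 * n))
        member = {l: ("d0" if not l.endswith("_dup") else "d1") for l in y2.index}
        res = cv_leave_dataset_out(y2, k2, member)
        accs = res.table.set_index("dataset")["accuracy"]
        assert accs["d0"] == pytest.approx(accs["d1"], abs=1e-8)

    def test_random_folds_beat_leave_dataset_out_on_structured_data(self):
        """Within-dataset relatives make random CV easier than across-dataset."""
        accs_r, accs_l = [], []
        for seed in range(3):
            y, k, member = self._blocky(seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                accs_r.append(cv_random_folds(y, k, n_folds=5, seed=seed).pooled_accuracy)
                accs_l.append(np.mean(
                    cv_leave_dataset_out(y, k, member).table["accuracy"]))
        assert np.mean(accs_r) > np.mean(accs_l)

    def test_disconnected_dataset_scores_near_zero(self):
        y, k, member = self._blocky(n_per=20, n_data=3, rho=0.6, h2=0.8, seed=9)
        # cut dataset d2 off from the rest of the kernel
        K = k.values.copy()
        K[40:, :40] = 0.0
        K[:40, 40:] = 0.0
        k_cut = LabeledMatrix(k.labels, K)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = cv_leave_dataset_out(y, k_cut, member)
        acc = res.table.set_index("dataset")["accuracy"]["d2"]
        assert abs(acc) < 0.45  # no information -> accuracy fluctuates around 0
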