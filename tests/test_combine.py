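"""The Wishart EM combiner: conditional blocks, updates, fixed points,
H-matrix equivalence, likelihood monotonicity and nu-invariance."""

import warnings

import numpy as np
import pytest
from scipy import stats

from covcomb import (
    CovarianceCombiner,
    EMConfig,
    LabeledMatrix,
    PartialSample,
    ValidationError,
    combine_em,
    hmatrix_oracle,
    wishart_loglik,
)
from covcomb.combine import blend_weighted, conditional_blocks, em_update, expected_completion
from covcomb.synthetic import OverlapDesign, random_overlap_design, sample_wishart_partials

from conftest import labeled_spd, partial, random_spd


def quiet_combine(samples, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return combine_em(samples, EMConfig(**kw))


class TestConditionalBlocks:
    def test_hand_example(self):
        psi = LabeledMatrix(["a", "b"], [[1, 0.5], [0.5, 2]])
        B, pbga = conditional_blocks(psi, ["a"])
        np.testing.assert_allclose(B, [[0.5]])
        np.testing.assert_allclose(pbga, [[1.75]])

    def test_diagonal_psi_gives_independence(self):
        psi = LabeledMatrix(["a", "b", "c"], np.diag([1.0, 2.0, 3.0]))
        B, pbga = conditional_blocks(psi, ["b"])
        np.testing.assert_allclose(B, 0.0)
        np.testing.assert_allclose(pbga, np.diag([1.0, 3.0]))

    def test_full_subset_degenerate(self, rng):
        psi = labeled_spd(["a", "b"], rng)
        B, pbga = conditional_blocks(psi, ["a", "b"])
        assert B.shape == (0, 2) and pbga.shape == (0, 0)


class TestExpectedCompletion:
    def test_hand_example(self):
        psi = LabeledMatrix(["a", "b"], [[1, 0.5], [0.5, 2]])
        s = partial(["a"], [[1.2]])
        out = expected_completion(psi, s, nu=10.0)
        # cross: 0.5 * 1.2; bottom: 10 * 1.75 + 0.25 * 1.2
        np.testing.assert_allclose(out, [[1.2, 0.6], [0.6, 17.8]])

    def test_full_coverage_returns_g(self, rng):
        psi = labeled_spd(["a", "b"], rng)
        G = random_spd(2, rng)
        out = expected_completion(psi, partial(["a", "b"], G), nu=7.0)
        np.testing.assert_allclose(out, G, atol=1e-12)

    def test_zero_cross_block_decouples(self):
        psi = LabeledMatrix(["a", "b"], np.diag([1.0, 2.0]))
        out = expected_completion(psi, partial(["a"], [[5.0]]), nu=3.0)
        np.testing.assert_allclose(out, [[5.0, 0.0], [0.0, 6.0]])


class TestBlendWeighted:
    @pytest.mark.parametrize("w,expect", [(1.0, 2.0), (0.0, 4.0), (0.5, 3.0)])
    def test_convex_blend(self, w, expect):
        psi = LabeledMatrix(["a"], [[0.4]])  # nu * psi_a = 4
        out = blend_weighted(partial(["a"], [[2.0]], weight=w), psi, nu=10.0)
        np.testing.assert_allclose(out, [[expect]])


class TestEMUpdate:
    def test_fully_observed_single_sample_is_g_over_nu(self, rng):
        psi = labeled_spd(list("abc"), rng)
        G = random_spd(3, rng)
        out = em_update(psi, [partial(list("abc"), G)], nu=50.0)
        np.testing.assert_allclose(out.values, G / 50.0, atol=1e-12)

    def test_disjoint_blockdiag_fixed_point(self, rng):
        G1, G2 = random_spd(2, rng), random_spd(3, rng)
        nu = 25.0
        psi = LabeledMatrix(
            list("abcde"),
            np.block([[G1, np.zeros((2, 3))], [np.zeros((3, 2)), G2]]) / nu,
        )
        out = em_update(psi, [partial(list("ab"), G1), partial(list("cde"), G2)], nu)
        np.testing.assert_allclose(out.values, psi.values, atol=1e-12)

    def test_duplicate_samples_equal_single(self, rng):
        psi = labeled_spd(list("abc"), rng)
        s = partial(list("ab"), random_spd(2, rng))
        one = em_update(psi, [s], nu=10.0)
        two = em_update(psi, [s, s], nu=10.0)
        np.testing.assert_allclose(one.values, two.values, atol=1e-13)


class TestWishartLoglik:
    def test_scalar_closed_form(self):
        # p=1, G=2, nu=2, Psi=1: W(2, 1) is chi^2_2 -> density exp(-1)/2
        ll = wishart_loglik([partial(["x"], [[2.0]])],
                            LabeledMatrix(["x"], [[1.0]]), nu=2.0)
        assert ll == pytest.approx(-1.0 - np.log(2.0), abs=1e-12)

    def test_additive_over_samples(self, rng):
        psi = labeled_spd(list("abc"), rng)
        s1 = partial(list("ab"), random_spd(2, rng))
        s2 = partial(list("c"), [[1.3]])
        assert wishart_loglik([s1, s2], psi, 10.0) == pytest.approx(
            wishart_loglik([s1], psi, 10.0) + wishart_loglik([s2], psi, 10.0)
        )

    def test_scalar_maximized_at_g_over_nu(self):
        g, nu = 2.7, 9.0
        s = [partial(["x"], [[g]])]
        best = g / nu
        ll_best = wishart_loglik(s, LabeledMatrix(["x"], [[best]]), nu)
        for c in (0.5, 0.9, 1.1, 2.0):
            ll = wishart_loglik(s, LabeledMatrix(["x"], [[best * c]]), nu)
            assert ll < ll_best

    def test_matches_scipy_wishart(self, rng):
        psi = labeled_spd(list("abc"), rng)
        G = random_spd(3, rng)
        nu = 11.5
        mine = wishart_loglik([partial(list("abc"), G)], psi, nu)
        ref = stats.wishart.logpdf(G, df=nu, scale=psi.values)
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_small_nu_sample_skipped_with_warning(self, rng):
        psi = labeled_spd(list("abc"), rng)
        s_big = partial(list("abc"), random_spd(3, rng))
        s_small = partial(["a"], [[1.0]])
        with pytest.warns(UserWarning, match="skipped"):
            ll = wishart_loglik([s_big, s_small], psi, nu=1.5)
        assert ll == pytest.approx(wishart_loglik([s_small], psi, 1.5))


class TestCombineEM:
    def test_identical_full_samples_return_g(self, rng):
        G = random_spd(4, rng)
        s = partial(list("abcd"), G)
        res = quiet_combine([s, s, s])
        np.testing.assert_allclose(res.sigma.values, G, atol=1e-10)
        assert res.converged and res.n_iter <= 2

    def test_nu_invariance(self, rng):
        design = random_overlap_design(10, 4, 6, seed=3)
        sigma = labeled_spd(design.labels, rng)
        samples = sample_wishart_partials(sigma, 60.0, design, seed=4)
        sigmas = [quiet_combine(samples, nu=nu).sigma.values
                  for nu in (100.0, 1000.0, 10000.0)]
        for s in sigmas[1:]:
            rel = np.linalg.norm(s - sigmas[0]) / np.linalg.norm(sigmas[0])
            assert rel <= 1e-6

    def test_one_step_from_a_equals_hmatrix(self, rng):
        labels = [f"g{i}" for i in range(8)]
        A = labeled_spd(labels, rng)
        sub = labels[2:6]
        G = LabeledMatrix(sub, random_spd(4, rng))
        res = quiet_combine([PartialSample(G)], init=A, max_iter=1, nu=500.0)
        H = hmatrix_oracle(A, G)
        np.testing.assert_allclose(
            res.sigma.reorder(labels).values, H.values, atol=1e-10
        )

    def test_disjoint_samples_converge_to_blockdiag(self, rng):
        G1, G2 = random_spd(3, rng), random_spd(2, rng)
        res = quiet_combine(
            [partial(list("abc"), G1), partial(list("de"), G2)],
            tol=1e-13, max_iter=300,
        )
        expect = np.block([[G1, np.zeros((3, 2))], [np.zeros((2, 3)), G2]])
        np.testing.assert_allclose(res.sigma.values, expect, atol=1e-8)

    def test_loglik_trace_monotone(self, rng):
        for trial in range(5):
            design = random_overlap_design(12, 5, 7, seed=trial)
            sigma = labeled_spd(design.labels, rng)
            samples = sample_wishart_partials(sigma, 40.0, design, seed=trial + 50)
            res = quiet_combine(samples, nu=40.0)
            t = np.array(res.loglik_trace)
            assert np.all(np.diff(t) >= -1e-8 * (1.0 + np.abs(t[:-1])))

    def test_permutation_equivariance(self, rng):
        design = random_overlap_design(9, 3, 6, seed=8)
        labels = design.labels
        sigma = labeled_spd(labels, rng)
        samples = sample_wishart_partials(sigma, 30.0, design, seed=9)
        res = quiet_combine(samples, nu=30.0)
        # relabel genotypes by a permutation map and re-run
        perm = {l: f"z{(i * 5 + 2) % 9}" for i, l in enumerate(labels)}
        relabeled = [
            PartialSample(LabeledMatrix([perm[l] for l in s.labels],
                                        s.kernel.values), s.weight)
            for s in samples
        ]
        res_p = quiet_combine(relabeled, nu=30.0)
        back = {v: k for k, v in perm.items()}
        orig_order = [back[l] for l in res_p.sigma.labels]
        np.testing.assert_allclose(
            res_p.sigma.values,
            res.sigma.reorder(orig_order).values,
            atol=1e-9,
        )

    def test_psd_preserved_empirically(self, rng):
        design = random_overlap_design(10, 4, 5, seed=21)
        sigma = labeled_spd(design.labels, rng)
        samples = sample_wishart_partials(sigma, 30.0, design, seed=22)
        res = quiet_combine(samples, nu=30.0)
        assert np.linalg.eigvalsh(res.sigma.values).min() >= -1e-6

    def test_weighted_zero_weight_sample_is_ignored_info(self, rng):
        # w=0 replaces the observation by the model's own prediction, so a
        # zero-weight sample must not move the estimate of a full sample
        G = random_spd(3, rng)
        s_full = partial(list("abc"), G)
        s_zero = partial(list("ab"), random_spd(2, rng) * 10, weight=0.0)
        res = quiet_combine([s_full, s_zero], tol=1e-12, max_iter=500)
        np.testing.assert_allclose(res.sigma.values, G, atol=1e-6)

    def test_nonconvergence_flagged(self, rng):
        G1, G2 = random_spd(3, rng), random_spd(2, rng)
        with pytest.warns(UserWarning, match="did not converge"):
            res = combine_em(
                [partial(list("abc"), G1), partial(list("de"), G2)],
                EMConfig(tol=1e-15, max_iter=3),
            )
        assert not res.converged and res.n_iter == 3

    def test_observed_mask_and_summary(self, rng):
        res = quiet_combine([partial(list("ab"), random_spd(2, rng)),
                             partial(list("bc"), random_spd(2, rng))])
        mask = res.observed_mask
        labels = res.sigma.labels
        ia, ic = labels.index("a"), labels.index("c")
        assert not mask[ia, ic]
        assert mask.diagonal().all()
        assert "genotypes (union)" in res.summary()

    def test_init_must_cover_union(self, rng):
        A = labeled_spd(["a", "b"], rng)
        s = partial(["a", "c"], random_spd(2, rng))
        with pytest.raises(ValidationError, match="cover"):
            CovarianceCombiner([s], EMConfig(init=A)).fit()

    def test_indefinite_init_rejected(self):
        bad = LabeledMatrix(["a", "b"], [[1.0, 2.0], [2.0, 1.0]])
        s = partial(["a", "b"], np.eye(2))
        with pytest.raises(ValidationError, match="positive definite"):
            CovarianceCombiner([s], EMConfig(init=bad)).fit()


class TestHMatrixOracle:
    def test_identity_a(self):
        A = LabeledMatrix(["1", "2"], np.eye(2))
        G = LabeledMatrix(["2"], [[2.0]])
        np.testing.assert_allclose(hmatrix_oracle(A, G).values,
                                   [[1, 0], [0, 2]])

    def test_hand_example(self):
        A = LabeledMatrix(["1", "2"], [[1, 0.5], [0.5, 1]])
        G = LabeledMatrix(["2"], [[1.5]])
        np.testing.assert_allclose(hmatrix_oracle(A, G).values,
                                   [[1.125, 0.75], [0.75, 1.5]])

    def test_g_equal_a22_returns_a(self, rng):
        A = labeled_spd(list("abcd"), rng)
        G = A.submatrix(["b", "d"])
        np.testing.assert_allclose(hmatrix_oracle(A, G).values, A.values,
                                   atol=1e-12)
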