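"""The RDM-matching auxiliary error: value, exact and subsampled gradients,
pair sampling, alpha schedules.  The gradient oracle throughout is central
finite differences of the error itself."""

import numpy as np
import pytest

from rdlearn.loss import (
    AlignmentError,
    AlphaSchedule,
    PairSet,
    all_pairs,
    alpha_at,
    combine_gradients,
    rdl_error,
    rdl_gradient_full,
    rdl_gradient_subsampled,
    sample_pairs,
)
from rdlearn.rdm import DISSIMILARITIES, RDM, ActivationMatrix, compute_rdm


def fd_gradient(F, target, d, h=1e-6):
    """Central-finite-difference oracle for the error gradient."""
    G = np.zeros_like(F)
    for i in range(F.shape[0]):
        for k in range(F.shape[1]):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, k] += h
            Fm[i, k] -= h
            G[i, k] = (rdl_error(Fp, target, d) - rdl_error(Fm, target, d)) / (2 * h)
    return G


WORKED_ACTS = np.array([[0.0, 0.0], [3.0, 4.0]])
WORKED_TARGET = RDM(np.array([[0.0, 20.0], [20.0, 0.0]]))


class TestError:
    def test_zero_when_student_matches_teacher(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(6, 4))
        target = compute_rdm(F)
        assert rdl_error(F, target) == 0.0

    def test_worked_single_pair_example(self):
        # RDM12 = 25, T12 = 20, prefactor 2/(2*1) = 1 -> error (25-20)^2 = 25
        assert rdl_error(WORKED_ACTS, WORKED_TARGET) == pytest.approx(25.0)

    def test_quadratic_in_discrepancy(self):
        rng = np.random.default_rng(1)
        F = rng.normal(size=(5, 3))
        D = compute_rdm(F).values
        delta = np.abs(rng.normal(size=D.shape))
        delta = (delta + delta.T) / 2
        np.fill_diagonal(delta, 0.0)
        e1 = rdl_error(F, RDM(D + delta))
        e2 = rdl_error(F, RDM(D + 2 * delta))
        assert e2 == pytest.approx(4 * e1, rel=1e-10)

    def test_mismatched_ids_raise(self):
        acts = ActivationMatrix(np.zeros((2, 2)) + [[0.0, 0.0], [1.0, 1.0]],
                                input_ids=("a", "b"))
        target = RDM(np.array([[0.0, 1.0], [1.0, 0.0]]), input_ids=("a", "c"))
        with pytest.raises(AlignmentError):
            rdl_error(acts, target)


class TestFullGradient:
    def test_zero_at_minimum(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(5, 3))
        assert np.all(rdl_gradient_full(F, compute_rdm(F)) == 0.0)

    def test_worked_example_matches_printed_constant(self):
        g = rdl_gradient_full(WORKED_ACTS, WORKED_TARGET)
        # 8/(n(n-1)) * (D12-T12) * (f(x1)-f(x2)) = 4*5*(-3,-4) = (-60,-80)
        np.testing.assert_allclose(g[0], [-60.0, -80.0])
        np.testing.assert_allclose(g[1], [60.0, 80.0])

    @pytest.mark.parametrize("d", DISSIMILARITIES)
    def test_matches_finite_differences(self, d):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(3, 6))
            F = rng.normal(size=(n, k))
            target = compute_rdm(rng.normal(size=(n, k)), d)
            G = rdl_gradient_full(F, target, d)
            num = fd_gradient(F, target, d)
            scale = max(np.abs(num).max(), 1e-8)
            assert np.abs(G - num).max() / scale < 1e-5


class TestPairSampling:
    def test_printed_pair_count_for_batch_128(self):
        ps = sample_pairs(128, 0.025, seed=0)
        assert ps.n_pairs == 406

    def test_pair_count_override(self):
        ps = sample_pairs(100, 0.05, seed=0, pair_count=500)
        assert ps.n_pairs == 500
        # the unrounded convention would give round(0.05 * 9900) = 495
        assert sample_pairs(100, 0.05, seed=0).n_pairs == 495

    def test_exhaustive_fraction(self):
        n = 7
        ps = sample_pairs(n, 1.0, seed=0)
        assert ps.n_pairs == n * (n - 1)
        assert ps.n_covered == n
        np.testing.assert_array_equal(ps.counts, 2 * (n - 1))

    def test_deterministic_given_seed(self):
        a = sample_pairs(30, 0.1, seed=99)
        b = sample_pairs(30, 0.1, seed=99)
        np.testing.assert_array_equal(a.pairs, b.pairs)
        assert not np.array_equal(a.pairs, sample_pairs(30, 0.1, seed=100).pairs)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_pairs(10, 0.0, seed=0)
        with pytest.raises(ValueError):
            sample_pairs(10, 0.001, seed=0)  # rounds to zero pairs
        with pytest.raises(ValueError):
            sample_pairs(1, 0.5, seed=0)
        with pytest.raises(ValueError):
            PairSet.from_pairs(4, [(0, 0)])  # self-pair
        with pytest.raises(ValueError):
            PairSet.from_pairs(4, [(0, 9)])  # out of range

    def test_expected_per_image_membership(self):
        # E|P_xi| = fraction * 2(n-1); empirical mean within 3 standard errors
        n, frac, draws = 12, 0.3, 2000
        m = round(frac * n * (n - 1))
        rng = np.random.default_rng(5)
        counts = np.array(
            [sample_pairs(n, frac, seed=rng).counts for _ in range(draws)],
            dtype=float,
        )
        expect = m * 2 / n  # each pair contributes 2 memberships over n images
        mean = counts.mean()
        se = counts.mean(axis=1).std(ddof=1) / np.sqrt(draws)
        assert abs(mean - expect) < 3 * se + 1e-9
        assert expect == pytest.approx(frac * 2 * (n - 1), rel=0.02)


class TestSubsampledGradient:
    def test_exhaustive_pairs_equal_full_gradient(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(3, 11))
            F = rng.normal(size=(n, 4))
            target = compute_rdm(rng.normal(size=(n, 4)))
            full = rdl_gradient_full(F, target)
            sub = rdl_gradient_subsampled(F, target, all_pairs(n))
            assert np.abs(full - sub).max() < 1e-10

    def test_unsampled_images_get_zero_rows(self):
        rng = np.random.default_rng(7)
        F = rng.normal(size=(6, 3))
        target = compute_rdm(rng.normal(size=(6, 3)))
        pairs = PairSet.from_pairs(6, [(0, 1), (1, 2)])  # images 3,4,5 unsampled
        g = rdl_gradient_subsampled(F, target, pairs)
        assert np.all(g[3:] == 0.0)
        assert np.any(g[:3] != 0.0)

    def test_zero_residual_on_sampled_pairs_gives_zero_gradient(self):
        rng = np.random.default_rng(8)
        F = rng.normal(size=(5, 3))
        target = compute_rdm(F)
        g = rdl_gradient_subsampled(F, target, sample_pairs(5, 0.5, seed=1))
        assert np.all(g == 0.0)

    def test_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        F = rng.normal(size=(8, 4))
        target = compute_rdm(rng.normal(size=(8, 4)))
        g1 = rdl_gradient_subsampled(F, target, sample_pairs(8, 0.3, seed=11))
        g2 = rdl_gradient_subsampled(F, target, sample_pairs(8, 0.3, seed=11))
        np.testing.assert_array_equal(g1, g2)


class TestCombineAndSchedules:
    def test_combine_gradients(self):
        rng = np.random.default_rng(10)
        g, a = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        np.testing.assert_array_equal(combine_gradients(g, a, 0.0), g)
        np.testing.assert_array_equal(combine_gradients(np.zeros_like(a), a, 1.0), a)
        lhs = combine_gradients(g, a, 1.0) - combine_gradients(g, a, 0.5)
        np.testing.assert_allclose(lhs, 0.5 * a, rtol=1e-12)
        with pytest.raises(ValueError):
            combine_gradients(g, a[:2], 1.0)

    def test_linear_schedule(self):
        sch = AlphaSchedule(0.5, 100, "linear_rdl")
        assert alpha_at(sch, 0) == 0.5
        assert alpha_at(sch, 50) == pytest.approx(0.25)
        assert alpha_at(sch, 100) == 0.0

    def test_multiplicative_dsn_schedule(self):
        sch = AlphaSchedule(1.0, 10, "multiplicative_dsn")
        assert alpha_at(sch, 0) == 1.0
        # 1 * (0.1 * (1 - 0/10)) * (0.1 * (1 - 1/10)) = 0.009
        assert alpha_at(sch, 2) == pytest.approx(0.009)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            alpha_at(AlphaSchedule(1.0, 10, "linear_rdl"), 11)
        with pytest.raises(ValueError):
            AlphaSchedule(-1.0, 10, "linear_rdl")
        with pytest.raises(ValueError):
            AlphaSchedule(1.0, 10, "exponential")
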