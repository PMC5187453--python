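"""RSA machinery: inter-RDM distances, bootstrap averaging, classical MDS,
and the exact McNemar test (checked against exhaustive enumeration)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rdlearn.analysis import (
    bootstrap_rdm_distances,
    classical_mds,
    mcnemar_exact,
    rdm_compare,
)
from rdlearn.rdm import RDM, compute_rdm, rdm_devectorize


class TestRdmCompare:
    def test_identical_rdms_distance_zero(self):
        rdm = compute_rdm(np.random.default_rng(0).normal(size=(6, 4)))
        assert rdm_compare(rdm, rdm, "correlation_distance") == pytest.approx(0.0, abs=1e-12)
        assert rdm_compare(rdm, rdm, "normalized_euclidean") == 0.0

    def test_correlation_distance_affine_invariant(self):
        a = compute_rdm(np.random.default_rng(1).normal(size=(5, 3)))
        b = RDM(np.where(np.eye(5), 0.0, 2.0 * a.values + 1.0))
        assert rdm_compare(a, b, "correlation_distance") == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_triangles(self):
        a = rdm_devectorize([1.0, 2.0, 3.0])
        b = rdm_devectorize([3.0, 2.0, 1.0])
        assert rdm_compare(a, b, "correlation_distance") == pytest.approx(2.0)

    def test_symmetry_and_validation(self):
        rng = np.random.default_rng(2)
        a = compute_rdm(rng.normal(size=(5, 3)))
        b = compute_rdm(rng.normal(size=(5, 3)))
        for metric in ("correlation_distance", "normalized_euclidean"):
            assert rdm_compare(a, b, metric) == rdm_compare(b, a, metric)
        c = compute_rdm(rng.normal(size=(6, 3)))
        with pytest.raises(ValueError):
            rdm_compare(a, c)
        with pytest.raises(ValueError):
            rdm_compare(a, b, "cosine")


class TestBootstrap:
    def test_degenerate_bootstrap_equals_direct_comparison(self):
        rng = np.random.default_rng(3)
        acts = {"m1": rng.normal(size=(12, 5)), "m2": rng.normal(size=(12, 5))}
        df = bootstrap_rdm_distances(acts, n_boot=1, sample_size=12, seed=0)
        direct = rdm_compare(compute_rdm(acts["m1"]), compute_rdm(acts["m2"]))
        assert df.loc["m1", "m2"] == pytest.approx(direct, rel=1e-12)
        assert df.loc["m1", "m1"] == 0.0

    def test_identical_sources_mean_distance_zero(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(30, 4))
        df = bootstrap_rdm_distances({"a": a, "b": a.copy()}, n_boot=5,
                                     sample_size=10, seed=1)
        assert df.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_seed_determinism_and_order_equivariance(self):
        rng = np.random.default_rng(5)
        acts = {k: rng.normal(size=(20, 4)) for k in ("x", "y", "z")}
        d1 = bootstrap_rdm_distances(acts, n_boot=4, sample_size=8, seed=9)
        d2 = bootstrap_rdm_distances(acts, n_boot=4, sample_size=8, seed=9)
        pd.testing.assert_frame_equal(d1, d2)
        rev = {k: acts[k] for k in ("z", "y", "x")}
        d3 = bootstrap_rdm_distances(rev, n_boot=4, sample_size=8, seed=9)
        assert d3.loc["x", "z"] == d1.loc["x", "z"]

    def test_insufficient_probe_items(self):
        with pytest.raises(ValueError):
            bootstrap_rdm_distances(
                {"a": np.zeros((5, 3)), "b": np.ones((5, 3))},
                n_boot=1, sample_size=10,
            )


class TestClassicalMds:
    def test_two_points_preserve_distance(self):
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        coords = classical_mds(D, dims=2)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(5.0)

    def test_right_triangle_embeds_exactly(self):
        D = np.array([[0.0, 3.0, 4.0],
                      [3.0, 0.0, 5.0],
                      [4.0, 5.0, 0.0]])
        coords = classical_mds(D, dims=2)
        for i in range(3):
            for j in range(3):
                dij = np.linalg.norm(coords[i] - coords[j])
                assert dij == pytest.approx(D[i, j], abs=1e-8)

    def test_planar_configurations_recovered(self):
        rng = np.random.default_rng(6)
        for m in (4, 5, 6):
            pts = rng.normal(size=(m, 2))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            coords = classical_mds(D, dims=2)
            Dhat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            np.testing.assert_allclose(Dhat, D, atol=1e-8)

    def test_truncation_never_stretches_euclidean_input(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 4))  # 4-D points squeezed into the plane
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(D, dims=2)
        Dhat = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        assert np.all(Dhat <= D + 1e-8)

    def test_sign_convention_deterministic(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        c1 = classical_mds(D)
        c2 = classical_mds(D)
        np.testing.assert_array_equal(c1, c2)
        first_nonzero = c1[np.abs(c1[:, 0]) > 1e-300, 0][0]
        assert first_nonzero > 0

    def test_deficient_rank_pads_with_warning(self):
        D = np.zeros((3, 3))
        with pytest.warns(RuntimeWarning):
            coords = classical_mds(D, dims=2)
        np.testing.assert_array_equal(coords, np.zeros((3, 2)))


def enumerate_mcnemar_p(n01, n10):
    """Exhaustive enumeration over all Binomial(m, 1/2) outcomes."""
    m = n01 + n10
    if m == 0:
        return 1.0
    k = min(n01, n10)
    tail = sum(math.comb(m, i) for i in range(k + 1)) / 2**m
    return min(1.0, 2.0 * tail)


class TestMcnemar:
    def test_no_discordant_pairs(self):
        a = np.array([True, False, True])
        assert mcnemar_exact(a, a).p_value == 1.0

    def test_worked_example_zero_five(self):
        a = np.array([False] * 5 + [True] * 5)
        b = np.array([True] * 5 + [True] * 5)
        res = mcnemar_exact(a, b)
        assert (res.n01, res.n10) == (5, 0)
        assert res.p_value == pytest.approx(0.0625)

    def test_agrees_with_enumeration_for_all_small_totals(self):
        for m in range(0, 21):
            for n01 in range(m + 1):
                n10 = m - n01
                a = np.array([True] * n10 + [False] * n01 + [True] * 3)
                b = np.array([False] * n10 + [True] * n01 + [True] * 3)
                res = mcnemar_exact(a, b)
                assert (res.n01, res.n10) == (n01, n10)
                assert res.p_value == pytest.approx(
                    enumerate_mcnemar_p(n01, n10), rel=1e-12
                )

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(8)
        a = rng.random(50) < 0.8
        b = rng.random(50) < 0.7
        assert mcnemar_exact(a, b).p_value == mcnemar_exact(b, a).p_value

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar_exact([True], [True, False])
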