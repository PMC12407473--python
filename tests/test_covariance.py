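"""Covariance construction: Longford recursion, gamma factor, LEAR, reduction."""

import time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glmpower import (
    ClusterHierarchy,
    ClusterLevel,
    NotPositiveDefiniteError,
    assemble_sigma,
    cluster_mean_variance_factor,
    cs_correlation,
    lear_correlation,
    longford_correlation,
    reduced_sigma,
    unstructured_sigma,
)


def _hier(sizes, iccs):
    return ClusterHierarchy(tuple(
        ClusterLevel(f"lvl{i}", k, r) for i, (k, r) in enumerate(zip(sizes, iccs))
    ))


# Strategy: random small hierarchies with mildly positive correlations so the
# result stays positive definite.
hierarchies = st.integers(1, 4).flatmap(
    lambda d: st.tuples(
        st.lists(st.integers(2, 6), min_size=d, max_size=d),
        st.lists(st.floats(0.0, 0.15), min_size=d, max_size=d),
    )
)


class TestLongford:
    def test_single_level_is_compound_symmetry(self):
        P = longford_correlation(_hier([3], [0.13]))
        assert np.allclose(P, cs_correlation(3, 0.13))

    def test_two_level_hand_expansion(self):
        # 2 members per subcluster, 2 subclusters: within-subcluster pairs
        # correlate at 0.3 + 0.1, cross-subcluster pairs at 0.1.
        P = longford_correlation(_hier([2, 2], [0.3, 0.1]))
        expected = np.array([
            [1.0, 0.4, 0.1, 0.1],
            [0.4, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.4],
            [0.1, 0.1, 0.4, 1.0],
        ])
        assert np.allclose(P, expected)

    def test_negative_rho_two_member_cluster_is_valid(self):
        P = longford_correlation(_hier([2], [-0.6]))
        assert np.allclose(P, [[1.0, -0.6], [-0.6, 1.0]])

    def test_unit_diagonal(self):
        P = longford_correlation(_hier([3, 2, 2], [0.05, 0.04, 0.02]))
        assert np.allclose(np.diag(P), 1.0)

    def test_non_pd_combination_rejected_with_inputs_named(self):
        with pytest.raises(NotPositiveDefiniteError, match=r"\(5, 4\)"):
            longford_correlation(_hier([5, 4], [-0.3, -0.2]))

    @given(hierarchies)
    @settings(max_examples=40, deadline=None)
    def test_entries_are_cumulative_sums_of_level_rhos(self, hk):
        sizes, iccs = hk
        h = _hier(sizes, iccs)
        P = longford_correlation(h)
        # two observations sharing only the outermost level correlate at rho_D
        assert np.isclose(P[0, -1], iccs[-1])
        # nearest neighbours share every level: sum of all rhos
        if h.total_size > 1:
            assert np.isclose(P[0, 1], sum(iccs))


class TestGammaFactor:
    def test_single_level_design_effect_over_cluster_size(self):
        g = cluster_mean_variance_factor(_hier([15], [0.13]))
        assert np.isclose(g, (1 + 14 * 0.13) / 15)
        assert np.isclose(g, 2.82 / 15)

    def test_two_level_hand_value(self):
        g = cluster_mean_variance_factor(_hier([2, 2], [0.3, 0.1]))
        assert np.isclose(g, 0.4)

    @pytest.mark.parametrize("sizes", [[4], [3, 2], [2, 2, 3]])
    def test_zero_rho_reduces_to_reciprocal_total(self, sizes):
        g = cluster_mean_variance_factor(_hier(sizes, [0.0] * len(sizes)))
        assert np.isclose(g, 1.0 / np.prod(sizes))

    @given(hierarchies)
    @settings(max_examples=40, deadline=None)
    def test_recursion_equals_mean_of_longford_entries(self, hk):
        """The closed-form gamma is the brute-force mean of P(D)'s entries."""
        sizes, iccs = hk
        h = _hier(sizes, iccs)
        brute = longford_correlation(h).mean()
        assert np.isclose(cluster_mean_variance_factor(h), brute, rtol=1e-12)


class TestLear:
    def test_zero_decay_is_compound_symmetry_at_min_distance(self):
        R = lear_correlation(0.5, 0.0, [0, 2, 5, 9])
        off = R[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.5**2)

    def test_example_grid_values(self):
        R = lear_correlation(0.6, 0.7, [0, 1, 3, 5])
        assert np.isclose(R[0, 1], 0.6)            # distance 1 = d_min
        assert np.isclose(R[0, 3], 0.6**1.7)        # distance 5 = d_max
        assert np.isclose(R[1, 2], 0.6**(1 + 0.7 * 1 / 4))  # distance 2

    def test_two_timepoints_degenerate_grid(self):
        R = lear_correlation(0.6, 0.7, [0, 4])
        assert np.isclose(R[0, 1], 0.6**4)

    def test_duplicate_timings_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            lear_correlation(0.6, 0.7, [0, 0, 1])


class TestUnstructuredSigma:
    def test_identity_correlation_gives_diagonal_variances(self):
        S = unstructured_sigma(np.eye(2), [2.0, 3.0])
        assert np.allclose(S, np.diag([4.0, 9.0]))

    def test_bivariate_imaging_block(self):
        S = unstructured_sigma([[1, 0.53], [0.53, 1]], [0.3, 0.3])
        assert np.allclose(np.diag(S), 0.09)
        assert np.isclose(S[0, 1], 0.0477)

    def test_trivariate_score_block(self):
        R = [[1, .9, .2], [.9, 1, .4], [.2, .4, 1]]
        S = unstructured_sigma(R, [4.4, 4.2, 0.6])
        assert np.isclose(S[0, 1], 16.632)

    def test_non_pd_correlation_rejected(self):
        R = [[1, 0.99, -0.99], [0.99, 1, 0.9], [-0.99, 0.9, 1]]
        with pytest.raises(NotPositiveDefiniteError):
            unstructured_sigma(R, [1, 1, 1])


class TestAssembleAndReduce:
    def test_kron_dimension(self):
        So = np.eye(8)
        Sr = cs_correlation(10, 0.2)
        assert assemble_sigma(So, Sr).shape == (80, 80)

    def test_scalar_blocks(self):
        assert np.allclose(assemble_sigma(np.array([[4.0]])), [[4.0]])

    def test_hand_kron_expansion(self):
        So = np.diag([1.0, 2.0])
        Sc = cs_correlation(2, 0.5)
        S = assemble_sigma(So, None, Sc)
        expected = np.array([
            [1.0, 0.5, 0.0, 0.0],
            [0.5, 1.0, 0.0, 0.0],
            [0.0, 0.0, 2.0, 1.0],
            [0.0, 0.0, 1.0, 2.0],
        ])
        assert np.allclose(S, expected)

    def test_dimension_cap(self):
        with pytest.raises(ValueError, match="cap"):
            assemble_sigma(np.eye(200), np.eye(200))

    def test_cluster_average_reduction_matches_explicit_product(self):
        # variance 1.21, CS(15, 0.13), averaging contrast
        Sc = 1.21 * cs_correlation(15, 0.13)
        u = np.full((15, 1), 1 / 15)
        explicit = u.T @ Sc @ u
        assert np.isclose(explicit[0, 0], 0.22748)
        blockwise = reduced_sigma([(None, np.atleast_2d(Sc))])
        assert np.allclose(blockwise, explicit)

    def test_identity_contrasts_reduce_to_full_sigma(self):
        So = unstructured_sigma([[1, .3], [.3, 1]], [1.0, 2.0])
        Sr = cs_correlation(3, 0.4)
        full = assemble_sigma(So, Sr)
        red = reduced_sigma([(np.eye(2), So), (np.eye(3), Sr)])
        assert np.allclose(red, full)

    @given(
        st.integers(2, 4), st.integers(2, 4),
        st.floats(0.0, 0.4), st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=30, deadline=None)
    def test_blockwise_equals_naive_on_random_contrasts(self, p1, p2, rho, seed):
        """(U1 (x) U2)' (S1 (x) S2) (U1 (x) U2) factorizes blockwise."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((p1, p1))
        S1 = A @ A.T + p1 * np.eye(p1)
        S2 = cs_correlation(p2, rho)
        U1 = rng.standard_normal((p1, 2))
        U2 = rng.standard_normal((p2, 1))
        naive = np.kron(U1, U2).T @ np.kron(S1, S2) @ np.kron(U1, U2)
        block = reduced_sigma([(U1, S1), (U2, S2)])
        assert np.allclose(block, naive, rtol=1e-10, atol=1e-12)

    def test_gamma_path_never_materializes_huge_cluster(self):
        """Averaging over a 10,000-member cluster is as fast as over 3."""
        big = _hier([10_000], [0.05])
        small = _hier([3], [0.05])
        t0 = time.perf_counter()
        g_big = reduced_sigma([(np.eye(2), np.eye(2)), (None, big)])
        t_big = time.perf_counter() - t0
        g_small = reduced_sigma([(np.eye(2), np.eye(2)), (None, small)])
        assert g_big.shape == g_small.shape == (2, 2)
        assert t_big < 1.0  # closed form, not a 10^8-entry matrix
        assert np.isclose(
            g_big[0, 0], cluster_mean_variance_factor(big)
        )

    def test_materializing_huge_cluster_is_refused(self):
        with pytest.raises(ValueError, match="cap"):
            longford_correlation(_hier([10_000, 2], [0.05, 0.01]))


class TestProducedMatricesArePD:
    @given(hierarchies)
    @settings(max_examples=25, deadline=None)
    def test_longford_smallest_eigenvalue_positive(self, hk):
        sizes, iccs = hk
        P = longford_correlation(_hier(sizes, iccs))
        eig = np.linalg.eigvalsh(P)
        assert eig[0] > 1e-10 * eig[-1]
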