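"""Power engine: McKeon df, noncentrality, exact reductions, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from glmpower import (
    GLHProblem,
    ReducedGLH,
    hlt_noncentrality,
    hlt_power,
    hypothesis_delta,
    mckeon_df,
)


class TestMcKeonDf:
    def test_two_sample_case_recovers_exact_t_df(self):
        df1, df2 = mckeon_df(1, 1, 38)
        assert df1 == 1
        assert np.isclose(df2, 38.0)

    @pytest.mark.parametrize("a", [2, 3, 4])
    @pytest.mark.parametrize("nu_e", [10, 50])
    def test_univariate_reduction_b_equals_one(self, a, nu_e):
        df1, df2 = mckeon_df(a, 1, nu_e)
        assert df1 == a
        assert np.isclose(df2, nu_e)

    @pytest.mark.parametrize("b", [2, 3, 4])
    def test_hotelling_tsq_reduction_a_equals_one(self, b):
        # a = 1: the HLT is Hotelling's T^2, whose exact F has df2 = nu_e - b + 1
        nu_e = 40
        _, df2 = mckeon_df(1, b, nu_e)
        assert np.isclose(df2, nu_e - b + 1)

    def test_two_by_two_hand_computation(self):
        df1, df2 = mckeon_df(2, 2, 10)
        assert df1 == 4
        assert np.isclose(df2, 4 + 6 * 40 / 41)

    def test_too_few_error_df_rejected(self):
        with pytest.raises(ValueError, match="nu_e"):
            mckeon_df(1, 3, 4)


class TestDeltaAndNoncentrality:
    def test_two_group_cluster_mean_difference(self):
        C = np.array([[1.0, -1.0]])
        B = np.column_stack([np.full(15, 1.24), np.full(15, 0.73)]).T
        U = np.full((15, 1), 1 / 15)
        D = hypothesis_delta(C, B, U)
        assert np.allclose(D, [[0.51]])

    def test_zero_means_zero_delta(self):
        D = hypothesis_delta(np.eye(2), np.zeros((2, 3)), np.eye(3))
        assert np.allclose(D, 0)

    def test_time_by_treatment_interaction_arithmetic(self):
        means = np.array([[3.6, 2.8, 0.9], [4.5, 4.3, 3.0]])
        U = np.array([[1.0, 0.0], [-1.0, 1.0], [0.0, -1.0]])
        D = hypothesis_delta(np.array([[1.0, -1.0]]), means, U)
        assert np.allclose(D, [[0.6, 0.6]])

    def test_two_sample_closed_form(self):
        # lambda = delta^2 / (sigma^2 (1/n1 + 1/n2))
        omega = hlt_noncentrality(
            np.array([[0.51]]), np.array([[0.1]]), np.array([[0.22748]])
        )
        assert np.isclose(omega, 0.51**2 / (0.22748 * 0.1))

    def test_zero_delta_gives_zero(self):
        assert hlt_noncentrality(np.zeros((2, 2)), np.eye(2), np.eye(2)) == 0.0

    def test_identity_toy_trace(self):
        omega = hlt_noncentrality(np.eye(2), np.eye(2), np.eye(2))
        assert np.isclose(omega, 2.0)


def _two_sample_problem(n1, n2, mu1, mu2, sd, alpha=0.05):
    return ReducedGLH(
        Delta=np.array([[mu1 - mu2]]),
        M=np.array([[1 / n1 + 1 / n2]]),
        Sigma_star=np.array([[sd**2]]),
        nu_e=n1 + n2 - 2,
        alpha=alpha,
    )


class TestExactReductions:
    @given(
        n1=st.integers(4, 60), n2=st.integers(4, 60),
        delta=st.floats(0.1, 3.0), sd=st.floats(0.2, 4.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_a_b_one_equals_noncentral_t_power(self, n1, n2, delta, sd):
        """For a = b = 1 the approximation IS the exact two-sided t-test power."""
        res = hlt_power(_two_sample_problem(n1, n2, delta, 0.0, sd))
        nu = n1 + n2 - 2
        ncp = delta / (sd * np.sqrt(1 / n1 + 1 / n2))
        tcrit = stats.t.isf(0.025, nu)
        lower = stats.nct.cdf(-tcrit, nu, ncp)
        if np.isnan(lower):  # underflow far in the tail; the term is < 1e-15
            lower = 0.0
        exact = stats.nct.sf(tcrit, nu, ncp) + lower
        assert np.isclose(res.power, exact, rtol=0, atol=1e-12)

    @given(seed=st.integers(0, 2**31 - 1), b=st.integers(2, 4))
    @settings(max_examples=40, deadline=None)
    def test_s_one_equals_exact_hotelling_tsq_power(self, seed, b):
        """For a = 1 the approximation matches the exact noncentral T^2 F."""
        rng = np.random.default_rng(seed)
        n = 30
        A = rng.standard_normal((b, b))
        Sigma_star = A @ A.T + b * np.eye(b)
        Delta = rng.standard_normal((1, b))
        red = ReducedGLH(Delta=Delta, M=np.array([[4 / n]]),
                         Sigma_star=Sigma_star, nu_e=n - 2)
        res = hlt_power(red)
        lam = (Delta @ np.linalg.solve(Sigma_star, Delta.T)).item() * n / 4
        fcrit = stats.f.isf(0.05, b, n - 2 - b + 1)
        exact = stats.ncf.sf(fcrit, b, n - 2 - b + 1, lam)
        assert np.isclose(res.power, exact, rtol=0, atol=1e-12)

    def test_null_power_equals_alpha(self):
        res = hlt_power(_two_sample_problem(10, 10, 1.0, 1.0, 2.0, alpha=0.07))
        assert res.omega == 0.0
        assert np.isclose(res.power, 0.07)


class TestMonotonicityAndInvariance:
    def test_power_increases_with_n_and_tends_to_one(self):
        powers = [
            hlt_power(_two_sample_problem(n, n, 0.5, 0.0, 1.0)).power
            for n in (5, 10, 20, 40, 80, 1000)
        ]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_power_increases_with_omega(self):
        base = _two_sample_problem(10, 10, 0.0, 0.0, 1.0)
        powers = [
            hlt_power(
                ReducedGLH(Delta=np.array([[d]]), M=base.M,
                           Sigma_star=base.Sigma_star, nu_e=base.nu_e)
            ).power
            for d in (0.0, 0.2, 0.5, 1.0, 2.0)
        ]
        assert all(b > a for a, b in zip(powers, powers[1:]))
        assert np.isclose(powers[0], 0.05)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_full_rank_contrast_transformations(self, seed):
        """Replacing C by T C and U by U S (T, S full rank) leaves power alone."""
        rng = np.random.default_rng(seed)
        q, p, a, b, n = 3, 4, 2, 2, 24
        XtX = np.diag(rng.integers(5, 12, q).astype(float))
        XtX *= n / np.trace(XtX)  # not integer counts, but full-rank and PD
        B = rng.standard_normal((q, p))
        A = rng.standard_normal((p, p))
        Sigma = A @ A.T + p * np.eye(p)
        C = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        U = rng.standard_normal((p, b))
        red = ReducedGLH(
            Delta=C @ B @ U,
            M=C @ np.linalg.solve(XtX, C.T),
            Sigma_star=U.T @ Sigma @ U,
            nu_e=21,
        )
        T = rng.standard_normal((a, a)) + 3 * np.eye(a)
        S = rng.standard_normal((b, b)) + 3 * np.eye(b)
        C2, U2 = T @ C, U @ S
        red2 = ReducedGLH(
            Delta=C2 @ B @ U2,
            M=C2 @ np.linalg.solve(XtX, C2.T),
            Sigma_star=U2.T @ Sigma @ U2,
            nu_e=21,
        )
        assert np.isclose(hlt_power(red).power, hlt_power(red2).power,
                          rtol=1e-9, atol=1e-12)


class TestGLHProblemValidation:
    def test_rank_deficient_contrast_rejected(self):
        with pytest.raises(ValueError, match="full row rank"):
            GLHProblem(
                XtX=np.diag([5.0, 5.0]),
                B=np.zeros((2, 2)),
                Sigma=np.eye(2),
                C=np.array([[1.0, -1.0], [2.0, -2.0]]),
                U=np.eye(2),
                Theta0=np.zeros((2, 2)),
            )

    def test_full_problem_and_reduced_route_agree(self, example3):
        full = hlt_power(example3.to_problem())
        red = hlt_power(example3.reduce())
        assert np.isclose(full.power, red.power, rtol=1e-12)
        assert np.isclose(full.omega, red.omega, rtol=1e-12)
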