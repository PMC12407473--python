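"""Analytic power for the general linear hypothesis in the multivariate model.

The hypothesis H0: C B U = Theta0 about the multivariate linear model
Y = X B + E, with rows of E i.i.d. N_p(0, Sigma), is tested with the
Hotelling-Lawley trace.  Both the null and noncentral distributions of the
trace are approximated by an F with McKeon degrees of freedom; the
approximation is exact whenever s = min(a, b) = 1, where it collapses to the
noncentral F of Hotelling's T^2 (and, for a = b = 1, of the two-sample t).

Power depends on the six matrices (X'X, B, Sigma, C, U, Theta0) only through
the reduced quantities

    Delta  = C B U - Theta0            (a x b)
    M      = C (X'X)^{-1} C'           (a x a)
    Sigma* = U' Sigma U                (b x b)

so designs with enormous cluster blocks can be solved without ever
materializing the full p x p covariance (see ``glmpower.design``).

The noncentrality is the unscaled trace

    omega = tr( Sigma*^{-1} Delta' M^{-1} Delta ),

carried into a noncentral F(ab, df2_McKeon, omega).  Candidate df2-dependent
rescalings of the trace were rejected during validation: the unscaled form is
the one that is exact for s = 1 and matches the Monte Carlo oracle for s >= 2
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .covariance import check_positive_definite

__all__ = [
    "GLHProblem",
    "ReducedGLH",
    "PowerResult",
    "hypothesis_delta",
    "mckeon_df",
    "hlt_noncentrality",
    "hlt_power",
]


def _rank(mat: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(mat))


@dataclass(frozen=True)
class GLHProblem:
    """The six-matrix specification of a multivariate power problem.

    Attributes
    ----------
    XtX : (q, q) design crossproduct; diagonal of cell counts under
        cell-mean coding.
    B : (q, p) matrix of predicted cell means.
    Sigma : (p, p) within-ISU error covariance.
    C : (a, q) between-ISU contrast, full row rank.
    U : (p, b) within-ISU contrast, full column rank.
    Theta0 : (a, b) null value of C B U.
    alpha : type I error rate.
    """

    XtX: np.ndarray
    B: np.ndarray
    Sigma: np.ndarray
    C: np.ndarray
    U: np.ndarray
    Theta0: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        XtX = np.atleast_2d(np.asarray(self.XtX, dtype=float))
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        C = np.atleast_2d(np.asarray(self.C, dtype=float))
        U = np.atleast_2d(np.asarray(self.U, dtype=float))
        Theta0 = np.atleast_2d(np.asarray(self.Theta0, dtype=float))
        for name, val in (
            ("XtX", XtX), ("B", B), ("Sigma", Sigma),
            ("C", C), ("U", U), ("Theta0", Theta0),
        ):
            object.__setattr__(self, name, val)
        q, p = B.shape
        if XtX.shape != (q, q):
            raise ValueError(f"XtX shape {XtX.shape} does not conform to B {B.shape}")
        if Sigma.shape != (p, p):
            raise ValueError(f"Sigma shape {Sigma.shape} does not conform to p={p}")
        if C.shape[1] != q:
            raise ValueError(f"C has {C.shape[1]} columns, expected q={q}")
        if U.shape[0] != p:
            raise ValueError(f"U has {U.shape[0]} rows, expected p={p}")
        a, b = C.shape[0], U.shape[1]
        if Theta0.shape != (a, b):
            raise ValueError(f"Theta0 shape {Theta0.shape}, expected ({a}, {b})")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if _rank(C) != a:
            raise ValueError("C must have full row rank")
        if _rank(U) != b:
            raise ValueError("U must have full column rank")
        # Cell-mean coding guarantees full-rank X; a rank-deficient crossproduct
        # is a construction bug, not something to pseudo-invert around.
        if np.linalg.matrix_rank(XtX) != q:
            raise ValueError("X'X must be full rank (cell-mean coding)")

    @property
    def n_total(self) -> int:
        return int(round(np.trace(self.XtX)))

    @property
    def a(self) -> int:
        return self.C.shape[0]

    @property
    def b(self) -> int:
        return self.U.shape[1]

    @property
    def nu_e(self) -> int:
        return self.n_total - self.XtX.shape[0]

    def reduce(self) -> "ReducedGLH":
        """Project the six-matrix problem down to (Delta, M, Sigma*)."""
        check_positive_definite(self.Sigma, "Sigma")
        Delta = hypothesis_delta(self.C, self.B, self.U, self.Theta0)
        M = self.C @ np.linalg.solve(self.XtX, self.C.T)
        Sigma_star = self.U.T @ self.Sigma @ self.U
        return ReducedGLH(
            Delta=Delta, M=M, Sigma_star=Sigma_star,
            nu_e=self.nu_e, alpha=self.alpha,
        )


@dataclass(frozen=True)
class ReducedGLH:
    """Contrast-projected power problem: everything hlt_power needs.

    ``Delta`` is a x b, ``M = C (X'X)^{-1} C'`` is a x a, ``Sigma_star``
    is b x b, and ``nu_e = N - q`` the error degrees of freedom.
    """

    Delta: np.ndarray
    M: np.ndarray
    Sigma_star: np.ndarray
    nu_e: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("Delta", "M", "Sigma_star"):
            object.__setattr__(
                self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            )
        a, b = self.Delta.shape
        if self.M.shape != (a, a):
            raise ValueError(f"M shape {self.M.shape}, expected ({a}, {a})")
        if self.Sigma_star.shape != (b, b):
            raise ValueError(
                f"Sigma_star shape {self.Sigma_star.shape}, expected ({b}, {b})"
            )

    @property
    def a(self) -> int:
        return self.Delta.shape[0]

    @property
    def b(self) -> int:
        return self.Delta.shape[1]


@dataclass(frozen=True)
class PowerResult:
    """Outcome of an analytic power computation."""

    power: float
    df1: float
    df2: float
    omega: float
    s: int
    f_crit: float


def hypothesis_delta(
    C: np.ndarray, B: np.ndarray, U: np.ndarray, Theta0: np.ndarray | float = 0.0
) -> np.ndarray:
    """Effect matrix Delta = C B U - Theta0 (a x b)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    theta = C @ B @ U
    Theta0 = np.broadcast_to(np.asarray(Theta0, dtype=float), theta.shape)
    return theta - Theta0


def mckeon_df(a: int, b: int, nu_e: float) -> tuple[float, float]:
    """McKeon degrees of freedom for the Hotelling-Lawley trace F approximation.

    Returns ``(df1, df2)`` with ``df1 = a b`` and

        df2 = 4 + (a b + 2) t1 / t2,
        t1  = nu_e^2 - nu_e (2b + 3) + b (b + 3),
        t2  = nu_e (a + b + 1) - (a + 2b + b^2 - 1).

    For ``b = 1`` this reduces exactly to ``df2 = nu_e`` (the univariate F);
    for ``a = 1`` it reduces to ``df2 = nu_e - b + 1`` (Hotelling's T^2).
    """
    if a < 1 or b < 1:
        raise ValueError("a and b must be positive")
    if nu_e <= b + 1:
        raise ValueError(
            f"error degrees of freedom nu_e={nu_e} must exceed b+1={b + 1}"
        )
    t1 = nu_e**2 - nu_e * (2 * b + 3) + b * (b + 3)
    t2 = nu_e * (a + b + 1) - (a + 2 * b + b**2 - 1)
    if t2 <= 0:
        raise ValueError(
            f"degenerate small-sample design: McKeon denominator t2={t2} <= 0"
        )
    return float(a * b), 4.0 + (a * b + 2.0) * t1 / t2


def hlt_noncentrality(
    Delta: np.ndarray, M: np.ndarray, Sigma_star: np.ndarray
) -> float:
    """Noncentrality omega = tr(Sigma*^{-1} Delta' M^{-1} Delta).

    For a = b = 1 this equals the exact two-sample noncentrality
    delta^2 / (sigma^2 (1/n1 + 1/n2)).
    """
    Delta = np.atleast_2d(np.asarray(Delta, dtype=float))
    M = np.atleast_2d(np.asarray(M, dtype=float))
    Sigma_star = np.atleast_2d(np.asarray(Sigma_star, dtype=float))
    check_positive_definite(M, "M = C (X'X)^{-1} C'")
    check_positive_definite(Sigma_star, "Sigma* = U' Sigma U")
    inner = Delta.T @ np.linalg.solve(M, Delta)
    omega = float(np.trace(np.linalg.solve(Sigma_star, inner)))
    return max(omega, 0.0)


def hlt_power(problem: GLHProblem | ReducedGLH) -> PowerResult:
    """Analytic Hotelling-Lawley trace power via the McKeon F approximation.

    Accepts either the full six-matrix :class:`GLHProblem` or a
    :class:`ReducedGLH`; the full form is projected first, so both routes
    produce identical numbers.
    """
    red = problem.reduce() if isinstance(problem, GLHProblem) else problem
    a, b = red.a, red.b
    df1, df2 = mckeon_df(a, b, red.nu_e)
    omega = hlt_noncentrality(red.Delta, red.M, red.Sigma_star)
    f_crit = float(stats.f.isf(red.alpha, df1, df2))
    if omega == 0.0:
        power = red.alpha
    else:
        power = float(stats.ncf.sf(f_crit, df1, df2, omega))
    return PowerResult(
        power=power, df1=df1, df2=df2, omega=omega, s=min(a, b), f_crit=f_crit
    )
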