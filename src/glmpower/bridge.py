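"""Transforms between the multivariate model and the reversible mixed model.

A balanced mixed model with complete data, ISU-constant covariates, and a
common error covariance can be rewritten losslessly as a multivariate linear
model — and vice versa.  Power is computed on the multivariate side; this
module provides the bookkeeping that maps one formulation onto the other
(vec/Kronecker identities) and a checklist for the three reversibility
conditions.  Only the population-average form of the mixed model is
represented: power depends on the marginal error covariance alone, so the
random-effects decomposition is never instantiated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .power import GLHProblem

__all__ = [
    "MixedFormulation",
    "ReversibilityReport",
    "multivariate_to_mixed",
    "check_reversibility",
]


def _vec(mat: np.ndarray) -> np.ndarray:
    """Column-major stacking of a matrix into a vector."""
    return np.asarray(mat, dtype=float).flatten(order="F")


@dataclass(frozen=True)
class MixedFormulation:
    """Population-average mixed-model form of a multivariate problem.

    ``ym`` (N p x 1, absent when no data matrix was supplied), ``Xm``
    (N p x q p), ``beta_m`` (q p,), ``Cm`` (a b x q p), ``theta_m`` and
    ``theta_0m`` (a b,).  The error covariance is I_N (x) Sigma by
    construction; it is not stored.
    """

    Xm: np.ndarray
    beta_m: np.ndarray
    Cm: np.ndarray
    theta_m: np.ndarray
    theta_0m: np.ndarray
    ym: np.ndarray | None = None


def multivariate_to_mixed(
    problem: GLHProblem,
    Y: np.ndarray | None = None,
    X: np.ndarray | None = None,
) -> MixedFormulation:
    """Rewrite Y = X B + E, H0: C B U = Theta0 in stacked mixed-model form.

    Uses the identities ``ym = vec(Y')``, ``Xm = X (x) I_p``,
    ``beta_m = vec(B')``, ``Cm = C (x) U'``, ``theta_m = vec(Theta')``.
    When ``X`` is omitted, a cell-mean design matrix is rebuilt from the
    diagonal of X'X (rows grouped by cell).

    The bridge is pure reformatting: ``Cm @ beta_m`` equals
    ``vec((C B U)')`` exactly, and no power number changes on the way
    through.
    """
    p = problem.B.shape[1]
    if X is None:
        counts = np.diag(problem.XtX).round().astype(int)
        X = np.repeat(np.eye(len(counts)), counts, axis=0)
    Xm = np.kron(X, np.eye(p))
    beta_m = _vec(problem.B.T)
    Cm = np.kron(problem.C, problem.U.T)
    theta = problem.C @ problem.B @ problem.U
    return MixedFormulation(
        Xm=Xm,
        beta_m=beta_m,
        Cm=Cm,
        theta_m=_vec(theta.T),
        theta_0m=_vec(problem.Theta0.T),
        ym=None if Y is None else _vec(np.asarray(Y, dtype=float).T),
    )


@dataclass(frozen=True)
class ReversibilityReport:
    """Verdicts on the three sufficient conditions for reversibility."""

    complete_data: bool
    isu_constant_covariates: bool
    common_error_covariance: bool

    @property
    def reversible(self) -> bool:
        return (
            self.complete_data
            and self.isu_constant_covariates
            and self.common_error_covariance
        )

    def explain(self) -> str:
        lines = []
        for label, ok, why in (
            ("complete data", self.complete_data,
             "no missing outcomes or predictors"),
            ("ISU-constant covariates", self.isu_constant_covariates,
             "every covariate takes one value per independent sampling unit"),
            ("common error covariance", self.common_error_covariance,
             "same covariance (hence equal cluster sizes) for every ISU"),
        ):
            lines.append(f"[{'ok' if ok else 'FAIL'}] {label}: {why}")
        verdict = "reversible" if self.reversible else "NOT reversible"
        lines.append(f"=> model is {verdict}")
        return "\n".join(lines)


def check_reversibility(
    missing_fraction: float = 0.0,
    covariates_vary_within_isu: bool = False,
    equal_cluster_sizes: bool = True,
    common_error_covariance: bool = True,
) -> ReversibilityReport:
    """Check the three sufficient conditions for a reversible mixed model.

    This reports rather than throws; callers that compute power should
    refuse (or explicitly override) non-reversible data descriptions, since
    complete-data power overstates the truth once data go missing or
    clusters become unequal.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    return ReversibilityReport(
        complete_data=missing_fraction == 0.0,
        isu_constant_covariates=not covariates_vary_within_isu,
        common_error_covariance=common_error_covariance and equal_cluster_sizes,
    )
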