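"""Error-covariance construction for clustered, longitudinal, multivariate designs.

The within independent-sampling-unit (ISU) covariance is a Kronecker product

    Sigma_y = Sigma_o  (x)  Sigma_r  (x)  Sigma_c

of an unstructured multivariate-outcome block ``Sigma_o`` (which carries the
measurement variances), a repeated-measures correlation block ``Sigma_r``
(unstructured, compound symmetric, or linear-exponent autoregressive), and a
nested-cluster correlation block ``Sigma_c`` built by the Longford variance
components recursion.

Cluster correlations are entered *incrementally*: two members sharing their
lowest common cluster at level ``d`` correlate at the sum of the per-level
rhos from level ``d`` outward.  This is what the recursion literally computes;
tools that ask for marginal (total) within-level correlations need their
inputs differenced before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ClusterLevel",
    "ClusterHierarchy",
    "Unstructured",
    "CompoundSymmetric",
    "LEAR",
    "AR1",
    "longford_correlation",
    "cluster_mean_variance_factor",
    "lear_correlation",
    "cs_correlation",
    "unstructured_sigma",
    "assemble_sigma",
    "reduced_sigma",
    "check_positive_definite",
]

#: Relative eigenvalue floor below which a covariance block is rejected.
PD_RTOL = 1e-10

#: Default cap on the dimension of any materialized covariance block.
MAX_BLOCK_DIM = 10_000


class NotPositiveDefiniteError(ValueError):
    """A covariance or correlation block failed the positive-definite check."""


def check_positive_definite(mat: np.ndarray, name: str = "matrix") -> None:
    """Raise ``NotPositiveDefiniteError`` unless ``mat`` is symmetric PD.

    PD is judged against a relative floor: the smallest eigenvalue must
    exceed ``PD_RTOL`` times the largest.  Near-singular blocks are rejected
    loudly rather than silently regularized.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, rtol=1e-12, atol=1e-12):
        raise NotPositiveDefiniteError(f"{name} is not symmetric")
    eig = np.linalg.eigvalsh(mat)
    if eig[0] <= PD_RTOL * max(eig[-1], 0.0) or eig[-1] <= 0:
        raise NotPositiveDefiniteError(
            f"{name} is not positive definite "
            f"(eigenvalue range [{eig[0]:.3e}, {eig[-1]:.3e}])"
        )


# ---------------------------------------------------------------------------
# Nested clustering (Longford variance components)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterLevel:
    """One level of nesting: ``size`` members, incremental correlation ``icc``."""

    name: str
    size: int
    icc: float

    def __post_init__(self) -> None:
        if not 2 <= self.size <= MAX_BLOCK_DIM:
            raise ValueError(
                f"cluster level {self.name!r}: size must be in [2, {MAX_BLOCK_DIM}], "
                f"got {self.size}"
            )
        if not -1.0 < self.icc < 1.0:
            raise ValueError(
                f"cluster level {self.name!r}: icc must be in (-1, 1), got {self.icc}"
            )


@dataclass(frozen=True)
class ClusterHierarchy:
    """D nested levels of clustering, innermost (level 1) first.

    ``levels[0]`` is the lowest level (members within the smallest cluster)
    and ``levels[-1]`` the outermost grouping inside one independent sampling
    unit.  Total within-ISU cluster dimension is the product of the sizes.
    """

    levels: tuple[ClusterLevel, ...]

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if not 1 <= len(levels) <= 10:
            raise ValueError(f"hierarchy must have 1..10 levels, got {len(levels)}")

    @property
    def depth(self) -> int:
        return len(self.levels)

    @property
    def total_size(self) -> int:
        """k*(D): product of the per-level sizes."""
        return math.prod(lv.size for lv in self.levels)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(lv.size for lv in self.levels)

    @property
    def iccs(self) -> tuple[float, ...]:
        return tuple(lv.icc for lv in self.levels)


def longford_correlation(hierarchy: ClusterHierarchy) -> np.ndarray:
    """Materialize the Longford correlation matrix P(D) for one ISU.

    Built by the recursion ``P(d) = I_{k_d} (x) P(d-1) + rho_d (11' - I)``
    with ``P(0) = 1``, so two observations whose lowest common cluster is at
    level ``d`` correlate at ``rho_d + rho_{d+1} + ... + rho_D``.  The result
    has unit diagonal and is verified positive definite.
    """
    if hierarchy.total_size > MAX_BLOCK_DIM:
        raise ValueError(
            f"cluster dimension {hierarchy.total_size} exceeds the "
            f"{MAX_BLOCK_DIM}-element materialization cap; use the averaged "
            "(gamma) reduction instead"
        )
    P = np.ones((1, 1))
    for lv in hierarchy.levels:
        k = P.shape[0] * lv.size
        P = np.kron(np.eye(lv.size), P) + lv.icc * (np.ones((k, k)) - np.eye(k))
    try:
        check_positive_definite(P, "Longford correlation")
    except NotPositiveDefiniteError as exc:
        raise NotPositiveDefiniteError(
            f"Longford correlation is not positive definite for sizes "
            f"{hierarchy.sizes} with iccs {hierarchy.iccs}"
        ) from exc
    return P


def cluster_mean_variance_factor(hierarchy: ClusterHierarchy) -> float:
    """Variance factor gamma of the mean of all observations in one ISU.

    Computed by the recursion ``gamma_d = gamma_{d-1}/k_d + rho_d (1 - 1/k*(d))``
    with ``gamma_0 = 1``; this is the Spearman-Brown prophecy factor extended
    to nested levels.  For a single level it equals the design effect
    ``1 + (k-1) rho`` divided by the cluster size.  It also equals the mean of
    all entries of :func:`longford_correlation`, but costs O(D) rather than
    O(k*(D)^2), which is what makes averaging contrasts over huge clusters
    cheap.
    """
    gamma = 1.0
    kstar = 1
    for lv in hierarchy.levels:
        kstar *= lv.size
        gamma = gamma / lv.size + lv.icc * (1.0 - 1.0 / kstar)
    if gamma <= 0:
        raise NotPositiveDefiniteError(
            f"cluster-mean variance factor is non-positive ({gamma:.3e}) for "
            f"sizes {hierarchy.sizes} with iccs {hierarchy.iccs}"
        )
    return gamma


# ---------------------------------------------------------------------------
# Repeated-measures structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Unstructured:
    """Unstructured correlation over the repeated measures."""

    correlation: np.ndarray

    def matrix(self, timings: Sequence[float]) -> np.ndarray:
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (len(timings), len(timings)):
            raise ValueError(
                f"unstructured correlation is {R.shape}, expected "
                f"({len(timings)}, {len(timings)})"
            )
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        check_positive_definite(R, "repeated-measures correlation")
        return R


@dataclass(frozen=True)
class CompoundSymmetric:
    """Exchangeable correlation ``rho`` between every pair of measures."""

    rho: float

    def matrix(self, timings: Sequence[float]) -> np.ndarray:
        k = len(timings)
        R = cs_correlation(k, self.rho)
        check_positive_definite(R, "compound-symmetric correlation")
        return R


@dataclass(frozen=True)
class LEAR:
    """Linear-exponent autoregressive correlation.

    Correlation between measures at distance d is
    ``rho_base ** (d_min + delta_decay * (d - d_min) / (d_max - d_min))``
    where ``d_min``/``d_max`` are the smallest and largest pairwise distances
    on the measurement grid.  ``delta_decay = 0`` recovers compound symmetry
    at ``rho_base ** d_min``; equally spaced timings with ``delta_decay``
    chosen suitably recover AR(1).
    """

    rho_base: float
    delta_decay: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_base < 1.0:
            raise ValueError(f"rho_base must be in (0, 1), got {self.rho_base}")
        if self.delta_decay < 0:
            raise ValueError(f"delta_decay must be >= 0, got {self.delta_decay}")

    def matrix(self, timings: Sequence[float]) -> np.ndarray:
        return lear_correlation(self.rho_base, self.delta_decay, timings)


@dataclass(frozen=True)
class AR1:
    """First-order autoregressive correlation, ``rho ** |t_j - t_k|``."""

    rho: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")

    def matrix(self, timings: Sequence[float]) -> np.ndarray:
        t = np.asarray(timings, dtype=float)
        R = self.rho ** np.abs(t[:, None] - t[None, :])
        check_positive_definite(R, "AR(1) correlation")
        return R


RepeatedStructure = Unstructured | CompoundSymmetric | LEAR | AR1


def cs_correlation(k: int, rho: float) -> np.ndarray:
    """k x k compound-symmetric correlation matrix."""
    return (1.0 - rho) * np.eye(k) + rho * np.ones((k, k))


def lear_correlation(
    rho_base: float, delta_decay: float, timings: Sequence[float]
) -> np.ndarray:
    """LEAR correlation matrix over an arbitrary measurement grid.

    With two timepoints (or a degenerate grid where every pairwise distance
    is equal) the exponent is simply ``d_min``.
    """
    t = np.asarray(timings, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least two timings")
    if np.unique(t).size != t.size:
        raise ValueError("timings must be distinct")
    if not 0.0 < rho_base < 1.0:
        raise ValueError(f"rho_base must be in (0, 1), got {rho_base}")
    if delta_decay < 0:
        raise ValueError(f"delta_decay must be >= 0, got {delta_decay}")
    dist = np.abs(t[:, None] - t[None, :])
    off = dist[~np.eye(t.size, dtype=bool)]
    d_min, d_max = off.min(), off.max()
    if d_max == d_min:
        expo = np.full_like(dist, d_min)
    else:
        expo = d_min + delta_decay * (dist - d_min) / (d_max - d_min)
    R = rho_base**expo
    np.fill_diagonal(R, 1.0)
    check_positive_definite(R, "LEAR correlation")
    return R


# ---------------------------------------------------------------------------
# Assembly and contrast reduction
# ---------------------------------------------------------------------------


def unstructured_sigma(
    correlations: np.ndarray, sds: Sequence[float]
) -> np.ndarray:
    """Scale a correlation matrix R into a covariance: diag(sds) R diag(sds)."""
    R = np.asarray(correlations, dtype=float)
    s = np.asarray(sds, dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard deviations must be positive")
    if R.shape != (s.size, s.size):
        raise ValueError(
            f"correlation matrix is {R.shape}, expected ({s.size}, {s.size})"
        )
    if not np.allclose(np.diag(R), 1.0):
        raise ValueError("correlation matrix must have unit diagonal")
    check_positive_definite(R, "outcome correlation")
    return s[:, None] * R * s[None, :]


def assemble_sigma(
    sigma_o: np.ndarray | None = None,
    sigma_r: np.ndarray | None = None,
    sigma_c: np.ndarray | None = None,
    max_dim: int = MAX_BLOCK_DIM,
) -> np.ndarray:
    """Kronecker-assemble Sigma_y = Sigma_o (x) Sigma_r (x) Sigma_c.

    Absent blocks are omitted from the product.  The dimension of the result
    is capped at ``max_dim``; designs that exceed the cap should stay in
    reduced (contrast-projected) form via :func:`reduced_sigma`.
    """
    blocks = [b for b in (sigma_o, sigma_r, sigma_c) if b is not None]
    if not blocks:
        raise ValueError("at least one covariance block is required")
    dim = math.prod(b.shape[0] for b in blocks)
    if dim > max_dim:
        raise ValueError(
            f"assembled covariance dimension {dim} exceeds the cap {max_dim}; "
            "use reduced_sigma instead of materializing"
        )
    out = np.asarray(blocks[0], dtype=float)
    for b in blocks[1:]:
        out = np.kron(out, b)
    return out


def reduced_sigma(
    blocks: Sequence[tuple[np.ndarray | None, np.ndarray | ClusterHierarchy]],
) -> np.ndarray:
    """Contrast-reduced covariance Sigma* = (x)_j  U_j' Sigma_j U_j.

    ``blocks`` is a sequence of ``(U_j, Sigma_j)`` pairs in Kronecker order
    (outcomes, repeated measures, clusters).  Each projected factor is small,
    so the product never materializes the full within-ISU covariance.

    Two special forms keep the cluster factor O(1) in cluster size:

    * ``Sigma_j`` may be a :class:`ClusterHierarchy`; then ``U_j`` must be
      ``None`` (meaning the averaging column over all members) and the factor
      is the closed-form scalar gamma from
      :func:`cluster_mean_variance_factor`, since for the averaging contrast
      ``u`` one has ``u' P(D) u = 1' P(D) 1 / k*(D)^2 = gamma``.
    * ``U_j = None`` with a plain matrix ``Sigma_j`` averages explicitly.
    """
    out = np.ones((1, 1))
    for U, Sigma in blocks:
        if isinstance(Sigma, ClusterHierarchy):
            if U is not None:
                raise ValueError(
                    "a ClusterHierarchy block implies the averaging contrast; "
                    "pass U=None or materialize with longford_correlation"
                )
            factor = np.array([[cluster_mean_variance_factor(Sigma)]])
        else:
            Sigma = np.asarray(Sigma, dtype=float)
            if U is None:
                k = Sigma.shape[0]
                factor = np.array([[Sigma.sum() / k**2]])
            else:
                U = np.asarray(U, dtype=float)
                if U.shape[0] != Sigma.shape[0]:
                    raise ValueError(
                        f"contrast block has {U.shape[0]} rows but covariance "
                        f"block is {Sigma.shape[0]}-dimensional"
                    )
                factor = U.T @ Sigma @ U
        out = np.kron(out, factor)
    return out
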