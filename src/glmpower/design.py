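"""Declarative study designs and their translation into power problems.

A :class:`StudyDesign` collects four things:

* the between-ISU structure — crossed factors with per-cell allocation
  ratios and (optionally) a total number of independent sampling units;
* the within-ISU structure — multivariate outcomes, a repeated-measures
  grid, and a nested cluster hierarchy (any subset may be present);
* a table of predicted cell means, one row per design cell and one column
  per (outcome, time) coordinate — cluster members are exchangeable, so
  means are constant across them and carry no member coordinate;
* the hypothesis — which between effect is tested, and how each within
  dimension is contrasted (averaged, kept, or differenced).

Cell-mean coding is used throughout: the design matrix has one indicator
column per cell, so X'X is the diagonal of cell counts and trivially full
rank.  Effect contrasts use successive differences; power is invariant to
any other full-rank coding spanning the same space.

``reduce()`` builds the projected problem (Delta, M, Sigma*) blockwise and
never materializes the cluster correlation when the hypothesis averages over
cluster members, so 10,000-member clusters cost the same as 3-member ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .covariance import (
    ClusterHierarchy,
    RepeatedStructure,
    assemble_sigma,
    longford_correlation,
    reduced_sigma,
    unstructured_sigma,
)
from .power import GLHProblem, ReducedGLH

__all__ = [
    "BetweenStructure",
    "WithinStructure",
    "CellMeans",
    "HypothesisSpec",
    "StudyDesign",
    "expand_groups",
    "build_between_contrast",
    "build_within_contrast",
    "design_crossproduct",
    "difference_contrast",
    "averaging_vector",
]

WithinSelection = Literal["average", "identity", "successive-difference"]


def difference_contrast(k: int) -> np.ndarray:
    """(k-1) x k successive-difference contrast rows (level j minus level j+1)."""
    if k < 2:
        raise ValueError("need at least two levels to difference")
    D = np.zeros((k - 1, k))
    for j in range(k - 1):
        D[j, j] = 1.0
        D[j, j + 1] = -1.0
    return D


def averaging_vector(k: int) -> np.ndarray:
    """Length-k equal-weight averaging vector (entries 1/k)."""
    return np.full(k, 1.0 / k)


# ---------------------------------------------------------------------------
# Between-ISU structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetweenStructure:
    """Crossed between-ISU factors with per-cell allocation ratios.

    ``factors`` is a sequence of ``(name, level_labels)`` pairs; design cells
    are the Cartesian product of the levels, ordered with the first factor
    varying slowest.  ``allocation_ratios`` gives the relative cell sizes
    (positive integers, one per cell).  ``total_isus`` may be left unset when
    the design will be solved for sample size.
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    allocation_ratios: tuple[int, ...]
    total_isus: int | None = None

    def __post_init__(self) -> None:
        factors = tuple((str(n), tuple(levels)) for n, levels in self.factors)
        ratios = tuple(int(r) for r in self.allocation_ratios)
        object.__setattr__(self, "factors", factors)
        object.__setattr__(self, "allocation_ratios", ratios)
        if not factors:
            raise ValueError("at least one between-ISU factor is required")
        for name, levels in factors:
            if len(levels) < 1:
                raise ValueError(f"factor {name!r} has no levels")
        if len(ratios) != self.n_cells:
            raise ValueError(
                f"{len(ratios)} allocation ratios for {self.n_cells} design cells"
            )
        if any(r < 1 for r in ratios):
            raise ValueError("allocation ratios must be positive integers")
        if self.total_isus is not None:
            expand_groups(ratios, self.total_isus)  # validates divisibility

    @property
    def n_cells(self) -> int:
        return math.prod(len(levels) for _, levels in self.factors)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    def cell_counts(self) -> tuple[int, ...]:
        if self.total_isus is None:
            raise ValueError("total_isus is not set")
        return expand_groups(self.allocation_ratios, self.total_isus)

    def with_total(self, total_isus: int) -> "BetweenStructure":
        return BetweenStructure(self.factors, self.allocation_ratios, total_isus)


def expand_groups(
    allocation_ratios: Sequence[int], total_isus: int
) -> tuple[int, ...]:
    """Per-cell ISU counts: ratio x (total / sum(ratios)).

    Raises a ``ValueError`` naming the nearest feasible totals when
    ``total_isus`` is not a multiple of the ratio sum.
    """
    ratios = [int(r) for r in allocation_ratios]
    if not ratios or any(r < 1 for r in ratios):
        raise ValueError("allocation ratios must be positive integers")
    step = sum(ratios)
    if total_isus < step or total_isus % step:
        below = (total_isus // step) * step
        above = below + step
        feasible = f"{below} or {above}" if below >= step else f"{above}"
        raise ValueError(
            f"total of {total_isus} ISUs cannot be split in ratio "
            f"{tuple(ratios)}: the total must be a positive multiple of "
            f"{step} (nearest feasible: {feasible})"
        )
    m = total_isus // step
    return tuple(r * m for r in ratios)


def design_crossproduct(between: BetweenStructure) -> np.ndarray:
    """X'X under cell-mean coding: the diagonal matrix of cell counts."""
    return np.diag(np.asarray(between.cell_counts(), dtype=float))


# ---------------------------------------------------------------------------
# Within-ISU structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WithinStructure:
    """Within-ISU dimensions: outcomes x repeated measures x cluster members.

    ``outcomes`` names the multivariate responses (at least one);
    ``outcome_sds`` are their standard deviations, and ``outcome_correlation``
    their correlation matrix (identity if omitted).  ``timings`` and
    ``repeated`` describe the repeated-measures grid and its correlation
    structure; ``clusters`` the nested hierarchy.  Repeated-measure and
    cluster blocks are pure correlations — all measurement variance lives in
    the outcome block.
    """

    outcomes: tuple[str, ...]
    outcome_sds: tuple[float, ...]
    outcome_correlation: np.ndarray | None = None
    timings: tuple[float, ...] | None = None
    repeated: RepeatedStructure | None = None
    clusters: ClusterHierarchy | None = None

    def __post_init__(self) -> None:
        outcomes = tuple(self.outcomes)
        sds = tuple(float(s) for s in self.outcome_sds)
        object.__setattr__(self, "outcomes", outcomes)
        object.__setattr__(self, "outcome_sds", sds)
        if not outcomes:
            raise ValueError("at least one outcome is required")
        if len(sds) != len(outcomes):
            raise ValueError(
                f"{len(sds)} standard deviations for {len(outcomes)} outcomes"
            )
        if any(s <= 0 for s in sds):
            raise ValueError("outcome standard deviations must be positive")
        if (self.timings is None) != (self.repeated is None):
            raise ValueError("timings and repeated structure go together")
        if self.timings is not None:
            t = tuple(float(x) for x in self.timings)
            object.__setattr__(self, "timings", t)
            if len(t) < 2 or any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("timings must be strictly increasing, length >= 2")

    @property
    def n_outcomes(self) -> int:
        return len(self.outcomes)

    @property
    def n_times(self) -> int:
        return 1 if self.timings is None else len(self.timings)

    @property
    def cluster_size(self) -> int:
        return 1 if self.clusters is None else self.clusters.total_size

    @property
    def dimension(self) -> int:
        """Total within-ISU dimension p = outcomes x times x members."""
        return self.n_outcomes * self.n_times * self.cluster_size

    def sigma_o(self) -> np.ndarray:
        R = self.outcome_correlation
        if R is None:
            R = np.eye(self.n_outcomes)
        return unstructured_sigma(R, self.outcome_sds)

    def sigma_r(self) -> np.ndarray | None:
        if self.repeated is None:
            return None
        return self.repeated.matrix(self.timings)


@dataclass(frozen=True)
class CellMeans:
    """Predicted means: q cells x (outcome, time) coordinates.

    Columns are ordered outcome-major (all times of outcome 1, then outcome
    2, ...), matching the Kronecker order of the covariance assembly.  Means
    are constant across cluster members (exchangeability), so the member
    coordinate is implicit.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(vals)):
            raise ValueError("cell means must be finite")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class HypothesisSpec:
    """What is tested: a between-ISU effect against within-ISU contrasts.

    ``between`` selects the rows of C: ``"grand-mean"``, a single factor name
    (main effect), or a tuple of factor names (interaction).  The within
    selections choose the contrast block per dimension: ``"average"`` (a
    single equal-weight column), ``"identity"``, or
    ``"successive-difference"``.  ``theta_null`` defaults to the zero matrix;
    grand-mean tests must supply it explicitly.
    """

    between: str | tuple[str, ...]
    outcomes: WithinSelection = "identity"
    repeated: WithinSelection = "average"
    clusters: WithinSelection = "average"
    theta_null: np.ndarray | None = None


def _between_blocks(
    between: BetweenStructure, hyp: HypothesisSpec
) -> list[np.ndarray]:
    """Per-factor contrast blocks, Kronecker order = factor declaration order."""
    if hyp.between == "grand-mean":
        selected: tuple[str, ...] = ()
        if hyp.theta_null is None:
            raise ValueError(
                "grand-mean tests require an explicit theta_null "
                "(the grand mean is not zero under any interesting null)"
            )
    elif isinstance(hyp.between, str):
        selected = (hyp.between,)
    else:
        selected = tuple(hyp.between)
    names = between.factor_names
    unknown = set(selected) - set(names)
    if unknown:
        raise ValueError(f"unknown factor(s) {sorted(unknown)}; have {list(names)}")
    blocks = []
    for name, levels in between.factors:
        k = len(levels)
        if name in selected:
            if k < 2:
                raise ValueError(f"factor {name!r} has one level; nothing to test")
            blocks.append(difference_contrast(k))
        else:
            blocks.append(averaging_vector(k)[None, :])
    return blocks


def build_between_contrast(
    between: BetweenStructure, hyp: HypothesisSpec
) -> np.ndarray:
    """Between-ISU contrast C (a x q): Kronecker product of per-factor blocks.

    Tested factors contribute successive-difference rows; untested factors an
    equal-weight averaging row.  The grand-mean selection averages every
    factor (a = 1) and requires an explicit ``theta_null``.
    """
    C = np.ones((1, 1))
    for block in _between_blocks(between, hyp):
        C = np.kron(C, block)
    return C


def _within_block(selection: WithinSelection, k: int) -> np.ndarray:
    if selection == "average":
        return averaging_vector(k)[:, None]
    if selection == "identity":
        return np.eye(k)
    if selection == "successive-difference":
        return difference_contrast(k).T
    raise ValueError(f"unknown within selection {selection!r}")


def build_within_contrast(
    within: WithinStructure, hyp: HypothesisSpec
) -> np.ndarray:
    """Within-ISU contrast U (p x b): Kronecker product over present dimensions.

    Note this materializes the cluster block; for the O(1) large-cluster
    path use :meth:`StudyDesign.reduce`, which keeps averaging contrasts
    implicit.
    """
    U = np.ones((1, 1))
    U = np.kron(U, _within_block(hyp.outcomes, within.n_outcomes))
    if within.timings is not None:
        U = np.kron(U, _within_block(hyp.repeated, within.n_times))
    if within.clusters is not None:
        U = np.kron(U, _within_block(hyp.clusters, within.cluster_size))
    return U


# ---------------------------------------------------------------------------
# The full study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """A complete declarative power/sample-size problem."""

    between: BetweenStructure
    within: WithinStructure
    means: CellMeans
    hypothesis: HypothesisSpec
    alpha: float = 0.05
    title: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        q = self.between.n_cells
        ot = self.within.n_outcomes * self.within.n_times
        if self.means.values.shape != (q, ot):
            raise ValueError(
                f"means table is {self.means.values.shape}, expected "
                f"({q} cells, {ot} outcome-by-time columns)"
            )

    @property
    def n_total(self) -> int | None:
        return self.between.total_isus

    @property
    def n_observations(self) -> int:
        """Total units of observation: ISUs x cluster members x times x outcomes
        counts each measured value once; the headline bookkeeping number is
        ISUs x cluster members (rows of the long-format data per time)."""
        if self.between.total_isus is None:
            raise ValueError("total_isus is not set")
        return self.between.total_isus * self.within.cluster_size

    def with_total(self, total_isus: int) -> "StudyDesign":
        return StudyDesign(
            between=self.between.with_total(total_isus),
            within=self.within,
            means=self.means,
            hypothesis=self.hypothesis,
            alpha=self.alpha,
            title=self.title,
        )

    def _theta0(self, a: int, b: int) -> np.ndarray:
        if self.hypothesis.theta_null is None:
            return np.zeros((a, b))
        t0 = np.atleast_2d(np.asarray(self.hypothesis.theta_null, dtype=float))
        if t0.shape != (a, b):
            raise ValueError(f"theta_null shape {t0.shape}, expected ({a}, {b})")
        return t0

    def _contrast_ot(self) -> np.ndarray:
        """Within contrast over the (outcome, time) coordinates only."""
        U = _within_block(self.hypothesis.outcomes, self.within.n_outcomes)
        if self.within.timings is not None:
            U = np.kron(U, _within_block(self.hypothesis.repeated, self.within.n_times))
        return U

    def reduce(self) -> ReducedGLH:
        """Blockwise (Delta, M, Sigma*) — O(1) in cluster size when averaging.

        Cluster members are exchangeable and the means table has no member
        coordinate, so when the cluster contrast is the averaging column the
        cluster factor of Sigma* collapses to the closed-form gamma scalar
        and the cluster factor of B U to 1.  Identity or difference cluster
        contrasts force materialization of the Longford block.
        """
        C = build_between_contrast(self.between, self.hypothesis)
        XtX = design_crossproduct(self.between)
        M = C @ np.linalg.solve(XtX, C.T)

        U_ot = self._contrast_ot()
        blocks: list[tuple[np.ndarray | None, np.ndarray | ClusterHierarchy]] = [
            (
                _within_block(self.hypothesis.outcomes, self.within.n_outcomes),
                self.within.sigma_o(),
            )
        ]
        if self.within.timings is not None:
            blocks.append(
                (
                    _within_block(self.hypothesis.repeated, self.within.n_times),
                    self.within.sigma_r(),
                )
            )
        delta_ot = C @ self.means.values @ U_ot
        if self.within.clusters is not None:
            if self.hypothesis.clusters == "average":
                blocks.append((None, self.within.clusters))
                # averaging column against member-constant means: factor 1
            else:
                Pc = longford_correlation(self.within.clusters)
                Uc = _within_block(self.hypothesis.clusters, self.within.cluster_size)
                blocks.append((Uc, Pc))
                # member-constant means: the cluster factor of B U is 1' Uc
                ones = np.ones((1, self.within.cluster_size))
                delta_ot = np.kron(delta_ot, ones @ Uc)
        a, b = delta_ot.shape
        Delta = delta_ot - self._theta0(a, b)
        Sigma_star = reduced_sigma(blocks)
        if Sigma_star.shape[0] != b:
            raise AssertionError("blockwise Sigma* does not conform to Delta")
        nu_e = self.between.total_isus - self.between.n_cells
        return ReducedGLH(
            Delta=Delta, M=M, Sigma_star=Sigma_star, nu_e=nu_e, alpha=self.alpha
        )

    def to_problem(self) -> GLHProblem:
        """Materialize the full six-matrix problem (for simulation/auditing).

        Expands the means table across cluster members and Kronecker-builds
        the full Sigma; guarded by the covariance dimension cap, so huge
        clusters must stay in reduced form.
        """
        XtX = design_crossproduct(self.between)
        C = build_between_contrast(self.between, self.hypothesis)
        U = build_within_contrast(self.within, self.hypothesis)
        k = self.within.cluster_size
        B = np.kron(self.means.values, np.ones((1, k)))
        sigma_c = (
            longford_correlation(self.within.clusters)
            if self.within.clusters is not None
            else None
        )
        Sigma = assemble_sigma(self.within.sigma_o(), self.within.sigma_r(), sigma_c)
        a, b = C.shape[0], U.shape[1]
        return GLHProblem(
            XtX=XtX,
            B=B,
            Sigma=Sigma,
            C=C,
            U=U,
            Theta0=self._theta0(a, b),
            alpha=self.alpha,
        )
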