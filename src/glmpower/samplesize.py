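"""Sample-size search: invert the power function over the feasible lattice.

Allocation ratios restrict the feasible totals to multiples of their sum
(a 2:1 two-arm design can only enrol totals divisible by 3).  Power is
monotone nondecreasing in the total, so the smallest adequate total is found
by doubling to bracket the target and then bisecting on the lattice.  A
rule-of-thumb dropout inflation divides the complete-data total by
(1 - loss/100) and rounds up to the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

from .design import StudyDesign
from .power import hlt_power

__all__ = ["SampleSizeResult", "solve_n", "inflate_for_dropout"]


@dataclass(frozen=True)
class SampleSizeResult:
    """Smallest feasible total meeting the power target."""

    n_total: int
    achieved_power: float
    target_power: float
    iterations: int
    feasible_step: int


def _power_at(design: StudyDesign, n: int) -> float:
    return hlt_power(design.with_total(n).reduce()).power


def solve_n(
    design: StudyDesign,
    target_power: float,
    n_max: int = 1_000_000,
) -> SampleSizeResult:
    """Smallest total ISU count whose analytic power reaches ``target_power``.

    The search walks the lattice of multiples of ``sum(allocation_ratios)``,
    starting from the smallest total with enough error degrees of freedom,
    doubling until the target is bracketed, then bisecting.  Raises if the
    target cannot be reached by ``n_max`` (reporting the power there), or if
    power is found to decrease along the lattice (which would indicate an
    approximation pathology rather than a real design).
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target power must be in (0, 1), got {target_power}")
    if target_power <= design.alpha:
        raise ValueError(
            f"target power {target_power} does not exceed alpha {design.alpha}"
        )
    step = sum(design.between.allocation_ratios)
    q = design.between.n_cells
    b = design.with_total(step).reduce().b  # b does not depend on the total
    # Smallest lattice point with nu_e > b + 1.
    lo = step
    while lo - q <= b + 1:
        lo += step
        if lo > n_max:
            raise ValueError(f"no feasible total with enough df below n_max={n_max}")

    iterations = 0
    p_lo = _power_at(design, lo)
    iterations += 1
    if p_lo >= target_power:
        return SampleSizeResult(lo, p_lo, target_power, iterations, step)

    # Doubling bracket on the lattice.
    hi = lo
    p_hi = p_lo
    while p_hi < target_power:
        new_hi = (min(hi * 2, n_max) // step) * step
        if new_hi <= hi:
            raise ValueError(
                f"target power {target_power} unreachable below n_max={n_max} "
                f"(power at N={hi} is {p_hi:.4f})"
            )
        p_new = _power_at(design, new_hi)
        iterations += 1
        if p_new < p_hi - 1e-9:
            raise RuntimeError(
                "power decreased along the feasible lattice "
                f"({p_hi:.6f} at N={hi} -> {p_new:.6f} at N={new_hi}); "
                "approximation pathology"
            )
        lo, p_lo, hi, p_hi = hi, p_hi, new_hi, p_new
        if hi >= n_max and p_hi < target_power:
            raise ValueError(
                f"target power {target_power} unreachable below n_max={n_max} "
                f"(power at N={hi} is {p_hi:.4f})"
            )

    # Bisection on lattice indices: power(lo) < target <= power(hi).
    i_lo, i_hi = lo // step, hi // step
    while i_hi - i_lo > 1:
        i_mid = (i_lo + i_hi) // 2
        p_mid = _power_at(design, i_mid * step)
        iterations += 1
        if p_mid >= target_power:
            i_hi = i_mid
        else:
            i_lo = i_mid
    n = i_hi * step
    achieved = _power_at(design, n)
    return SampleSizeResult(n, achieved, target_power, iterations, step)


def inflate_for_dropout(
    n: int, loss_pct: float, feasible_step: int = 1
) -> int:
    """Inflate a complete-data total for an anticipated loss-to-followup.

    Divides by (1 - loss_pct/100), then rounds up to the next multiple of
    ``feasible_step`` — always up, as befits a conservative design.
    """
    if not 0.0 <= loss_pct < 100.0:
        raise ValueError(f"loss percentage must be in [0, 100), got {loss_pct}")
    if n < 1 or feasible_step < 1:
        raise ValueError("n and feasible_step must be positive")
    raw = ceil(n / (1.0 - loss_pct / 100.0))
    return ceil(raw / feasible_step) * feasible_step
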