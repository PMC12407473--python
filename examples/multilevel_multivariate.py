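"""Three literacy curricula, three outcome scores, two levels of nesting.

45 schools are randomized equally to three programs; each school has 4
classrooms of 5 students, with incremental intraclass correlations 0.04
(students within classrooms) and 0.07 (classrooms within schools).  Each
student contributes three correlated difference scores.  The hypothesis is
the MANOVA null: no program differences on any combination of the scores.
"""

import numpy as np

from glmpower import (
    BetweenStructure,
    CellMeans,
    ClusterHierarchy,
    ClusterLevel,
    HypothesisSpec,
    StudyDesign,
    WithinStructure,
    cluster_mean_variance_factor,
    hlt_power,
    longford_correlation,
)

hierarchy = ClusterHierarchy((
    ClusterLevel("student", 5, 0.04),
    ClusterLevel("classroom", 4, 0.07),
))

# The 20 x 20 within-school correlation: classmates correlate at
# 0.04 + 0.07, students in different classrooms of one school at 0.07.
P = longford_correlation(hierarchy)
print(f"within-school correlation block: {P.shape[0]}x{P.shape[1]}, "
      f"classmates {P[0, 1]:.2f}, cross-classroom {P[0, 5]:.2f}")
gamma = cluster_mean_variance_factor(hierarchy)
print(f"variance factor of a school mean: gamma = {gamma:.4f} "
      f"(vs 1/20 = {1 / 20:.4f} if students were independent)")

design = StudyDesign(
    title="Early literacy, multivariate outcome",
    between=BetweenStructure(
        factors=(("program", ("intervention", "monolingual", "bilingual")),),
        allocation_ratios=(1, 1, 1),
        total_isus=45,
    ),
    within=WithinStructure(
        outcomes=("score_a", "score_b", "score_c"),
        outcome_sds=(4.4, 4.2, 0.6),
        outcome_correlation=np.array([
            [1.0, 0.9, 0.2],
            [0.9, 1.0, 0.4],
            [0.2, 0.4, 1.0],
        ]),
        clusters=hierarchy,
    ),
    means=CellMeans([
        [0.3, 0.3, 0.3],
        [0.1, 0.1, 0.1],
        [0.1, 0.1, 0.1],
    ]),
    hypothesis=HypothesisSpec(between="program", outcomes="identity",
                              clusters="average"),
    alpha=0.05,
)

res = hlt_power(design.reduce())
print(f"MANOVA power with 15 schools per arm: {res.power:.3f} "
      f"(df1={res.df1:g}, df2={res.df2:.2f}, omega={res.omega:.2f})")
# Averaging the 20 students reduces each school to one trivariate response;
# the between-program contrast has rank 2, so the trace statistic compares a
# 2x3 effect against a 3x3 covariance scaled by gamma.
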