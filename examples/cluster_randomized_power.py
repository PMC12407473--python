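"""Power for a cluster-randomized trial, built from scratch.

Two arms of 20 workplaces each, 15 workers per workplace, intracluster
correlation 0.13, per-worker SD 1.1, predicted means 1.24 (control) vs 0.73
(trained).  The test is a two-group comparison of workplace means.
"""

from glmpower import (
    BetweenStructure,
    CellMeans,
    ClusterHierarchy,
    ClusterLevel,
    HypothesisSpec,
    StudyDesign,
    WithinStructure,
    hlt_power,
)

design = StudyDesign(
    title="Workplace training program",
    between=BetweenStructure(
        factors=(("treatment", ("control", "training")),),
        allocation_ratios=(1, 1),
        total_isus=40,
    ),
    within=WithinStructure(
        outcomes=("drinks_per_day",),
        outcome_sds=(1.1,),
        clusters=ClusterHierarchy((ClusterLevel("worker", 15, 0.13),)),
    ),
    means=CellMeans([[1.24], [0.73]]),
    hypothesis=HypothesisSpec(between="treatment", clusters="average"),
    alpha=0.05,
)

result = hlt_power(design.reduce())
print(f"N = {design.between.total_isus} workplaces, "
      f"{design.n_observations} workers observed")
print(f"noncentrality omega = {result.omega:.3f}   "
      f"df = ({result.df1:g}, {result.df2:g})")
print(f"power = {result.power:.3f}")
# The design effect 1 + 14 x 0.13 = 2.82 inflates the variance of each
# workplace mean; with 20 workplaces per arm the 0.51-drink difference is
# still detected with ~91% probability at the 5% level.
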