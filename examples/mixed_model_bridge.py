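"""The reversible-model bridge: one problem, two formulations.

Power is computed on the multivariate side, but the study will be analysed
as a linear mixed model.  This script shows the lossless transformation
between the two for a small design, and the three conditions under which the
mixed model is 'reversible' (so that multivariate power applies to it).
"""

import numpy as np

from glmpower import check_reversibility, load_example, multivariate_to_mixed

design = load_example("example1")
problem = design.to_problem()

mixed = multivariate_to_mixed(problem)
q, p = problem.B.shape
print(f"multivariate form: B is {q}x{p}, C is {problem.C.shape[0]}x{q}, "
      f"U is {p}x{problem.U.shape[1]}")
print(f"mixed form: beta_m has {mixed.beta_m.size} entries, "
      f"C_m is {mixed.Cm.shape[0]}x{mixed.Cm.shape[1]}")

# The hypothesis is the same object in both notations:
theta_via_mixed = mixed.Cm @ mixed.beta_m
theta_via_mv = (problem.C @ problem.B @ problem.U).T.flatten(order="F")
print("theta agrees across formulations:",
      np.allclose(theta_via_mixed, theta_via_mv))

print()
print("clean design (complete data, equal clusters):")
print(check_reversibility().explain())
print()
print("after declaring unequal cluster sizes:")
print(check_reversibility(equal_cluster_sizes=False).explain())
# A non-reversible model (missing data, unequal clusters) means the
# complete-data power computed here is an upper bound on the truth.
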