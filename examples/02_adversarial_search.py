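"""Adversarial worst-case search within the parameter uncertainty box.

A real-coded genetic algorithm co-optimizes two complete 43-parameter
models inside ±0.50 mm (geometry) / ±5 % (material) bounds around the
reference, maximizing the weighted-L1 separation of their
moment/rotation curves.  The initial population is seeded with two
copies of the reference (objective 0.00 by construction), so the best
objective can only improve from there.

A shortened run (population 20, 10 generations) is used here so the
example finishes in seconds; the headline analysis uses 86/100.
"""

import numpy as np

from ankleuq import (
    GAConfig,
    PerturbationBounds,
    displacement_stats,
    range_of_motion,
    run_adversarial,
)
from ankleuq.fixtures import default_ankle_fixture

model = default_ankle_fixture()
report = run_adversarial(
    model,
    PerturbationBounds(geometry_delta=0.50, material_rel=0.05),
    GAConfig(population_size=20, generations=10, rng_seed=1),
)

b = report.breakdown
print(f"best objective h = {b.h:.2f}  "
      f"(weighted L1 = {b.l1_term:.2f} deg, not_passed = {b.not_passed})")
print("generation trace (best h):",
      np.round(report.ga_result.best_trace, 1))

dt_a = report.sweep_a.angular_displacement
dt_b = report.sweep_b.angular_displacement
print("\n                      A (deg)   B (deg)     avg  abs_diff  rel_diff%")
for label, a, bb in [
    ("max plantarflexion", dt_a[-1], dt_b[-1]),
    ("max dorsiflexion  ", dt_a[0], dt_b[0]),
    ("range of motion   ", range_of_motion(report.sweep_a),
     range_of_motion(report.sweep_b)),
]:
    st = displacement_stats(a, bb).rounded(2)
    print(f"{label}  {a:8.2f}  {bb:8.2f}  {st.avg:7.2f}  "
          f"{st.abs_diff:8.2f}  {st.rel_diff:8.2f}")

print("\nBoth models sit inside the same small uncertainty box, yet their")
print("angular displacements differ by the abs_diff column — the worst-case")
print("output spread the bounds admit, which a one-at-a-time scan misses.")
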