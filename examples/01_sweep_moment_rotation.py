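"""Solve the planar ankle model across the default load schedule.

Builds the shipped synthetic ankle (six exponential ligament cables plus
a conforming Hertzian contact pair), solves static equilibrium at each
external moment from -5 to +5 Nm, and prints the moment/rotation curve.
Negative moments drive dorsiflexion, positive moments plantarflexion;
angular displacement is measured from the zero-load equilibrium.
"""

import numpy as np

from ankleuq import default_ankle_fixture, range_of_motion, sweep_loads

model = default_ankle_fixture()
sweep = sweep_loads(model)

print("M_ext (Nm)  dtheta (deg)  F_contact (N)  converged")
for m, dt, forces, ok in zip(
    sweep.moments, sweep.angular_displacement, sweep.element_forces,
    sweep.converged,
):
    print(f"{m:10.2f}  {dt:12.2f}  {forces[-1]:13.1f}  {ok}")

print(f"\nrange of motion: {range_of_motion(sweep):.2f} deg "
      f"({sweep.not_passed} step(s) failed the residual condition)")
print("A healthy model converges at every step; the asymmetry between the")
print("+5 and -5 Nm rows reflects the stiffer anterior ligament group.")
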