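# Methods

## Mechanical model

Two rigid bodies in the sagittal plane: the tibia/fibula is fixed and
defines the global frame; the talus/calcaneus moves with pose
`(tx, ty, θ)` (mm, mm, rad), its frame coinciding with the global frame
at the reference pose.  Points on the moving body transform by rotation
then translation.  `θ` is stored unwrapped so displacement differences
are well defined.

**Ligaments.** Six tension-only cables, one per ligament (ATT, TC, PTT,
ATF, CF, PTF), each a straight line between one attachment on each
body.  Force magnitude `F = a(exp(b·ε) − 1)` for engineering strain
`ε = (L − L₀)/L₀ > 0`, zero otherwise.  The slack length `L₀` is *not*
a free parameter: it is the attachment distance at the model's own
reference pose, recomputed per parameter set, so perturbing an
attachment changes both the line of action and the slack.  Typical
fixture values: `a` 8–12 N, `b` 17–20 (dimensionless).

**Contact.** One conforming internal sphere-in-sphere Hertzian pair:
the inner sphere (radius `R_in`, moving body) rides inside an outer
sphere (radius `R_in + c`, fixed body) with clearance `c = 0.5 mm`, a
configuration constant.  Penetration is `δ = d − c` with `d` the
center distance; when engaged the force `F = (4/3)E*√R_eff δ^{3/2}`
with `R_eff = R_in(R_in + c)/c` and `1/E* = 2(1 − ν²)/E` (both surfaces
share `E`, `ν`), acts on the moving body along the line from its center
toward the fixed center.  The conforming-pair reading is what the
five-parameter geometric encoding (two centers + one radius) fixes; no
alternative external-contact mode is provided.

**Statics.** The residual is the net load on the moving body:
`(Fx, Fy)` in N plus the moment about the moving body's reference point.
The moment (N·mm) is converted to N·m and divided by a characteristic
length of 0.01 m so all three residual components are force-like and
comparable; the residual then equals the negative gradient of the total
potential (elastic energy minus external-moment work) up to that
scaling, which the tests verify against quadrature-plus-finite-difference
oracles.  Equilibria are found with `scipy.optimize.least_squares`
(method `lm`, analytic Jacobian, library-default tolerances).  A solve
is *accepted* only if the sum of absolute scaled residual components is
below 1·10⁻¹⁰; because the default termination tolerances can stop
earlier than that, a solve that misses the condition is polished once
with `ftol = xtol = gtol = 1e−15` before the flag is decided.  An
unaccepted solve returns its pose with `converged = False` and is never
an exception.

**Load sweep.** Default schedule −5.00…+5.00 Nm in 11 equal steps
(negative = dorsiflexion, positive = plantarflexion).  0 Nm is solved
first from the reference pose; the remaining steps march outward in
both directions, each warm-started from its inward neighbour (a failed
step still seeds the warm start but increments `not_passed`).  Angular
displacement is reported in degrees relative to the zero-load
equilibrium, so Δθ(0) = 0 identically, and the result is independent of
the order the schedule lists its moments in.

## Adversarial objective

An 86-element decision vector holds two complete 43-parameter models
(canonical order: 24 ligament attachment coordinates, 5 contact
geometry, 12 ligament material, 2 contact material; then the same for
the second model).  The objective is

    h = − Σᵢ w₁ᵢ |Δθ_A,i − Δθ_B,i| + 10.00 · not_passed,

one weight per load step with the endpoints weighted 2 and all interior
steps 1, `not_passed` summed over both structures (0–22 on the default
schedule).  A half whose model cannot even be constructed (negative
stiffness, coincident attachments) scores all of its steps as failed
and contributes a flat curve to the L1 term; the penalty (110) dwarfs
any realizable L1 value, so such vectors are strongly dominated rather
than fatal.  Two identical, fully converging halves give exactly
`h = 0`.

## Genetic algorithm

Real-coded, box-bounded minimization.  Per generation: the elite
fraction (5 %) is copied with cached objectives — at least one elite is
always kept, so the best trace is non-increasing for any population
size; the crossover fraction (80 %) is bred from roulette-selected
parents with blx-α (α = 0.5, children clipped to bounds); the mutation
fraction (15 %) applies non-uniform mutation to roulette-selected
individuals.  Roulette fitness for minimization is
`f = (h_worst − h) + 1e−9·max(1, |h_worst|)`, the floor keeping every
individual selectable.  Non-uniform mutation moves a component toward a
bound by `y·(1 − r^{(1−t/T)^b})` with shape `b = 3` and per-component
probability `1/n`; both are exposed in `GAConfig` since the canonical
operator leaves them open.  All randomness flows through one seeded
`numpy` generator and evaluation is sequential, so runs are
bit-reproducible; no parallel evaluation is attempted for that reason.

Defaults mirror the headline analysis: population 86, 100 generations,
fractions 5/80/15 %.  The uncertainty box is ±0.50 mm on every
geometric entry and ±5 % relative on every material entry (interval
order corrected for negative nominals), identical for both halves, and
the initial population contains one injected solution of two reference
copies — with elitism this pins the best objective at or below 0.00
from generation zero.

## One-at-a-time baseline

Each of the 43 parameters is set to its bound in turn, both signs
(86 runs); each perturbed model is swept and scored against the
unperturbed reference with the same objective (reference as the fixed
second structure, its failures included in `not_passed`).  The most
negative of the 86 values is the baseline the adversarial search must
beat.

## Reporting conventions

Displacement pairs are summarized as `avg = (A+B)/2`,
`abs_diff = |A−B|`, `rel_diff = abs_diff/|avg|·100 %` (undefined at
`avg = 0`, reported as NaN); tables round to 2 decimals.  Range of
motion is Δθ at the maximal moment minus Δθ at the minimal moment.  The
per-element force comparison reports, for each ligament and the
contact, the maximum over load steps of `|F_A − F_B|` and the relative
difference at that step with the same avg denominator.

## Synthetic fixture

The subject-specific parameter set behind the planar ankle models this
procedure targets is not published, so the package ships a synthetic
43-parameter fixture calibrated to the qualitative regime instead:
range of motion 59.97° under ±5 Nm, plantarflexion (+32.96°) exceeding
dorsiflexion (−27.02°), monotone moment/rotation curve, convergence at
all 11 steps, and full convergence for 50/50 sampled models jittered by
the analysis bounds (0.5 mm / 5 %).  Two calibration choices matter:

* the fixed contact center sits 2.2 mm below the moving one, preloading
  the conforming contact.  This keeps the contact engaged under any
  ±0.5 mm perturbation and pulls the cable network taut at zero load;
  without preload the reference pose is an exact zero-residual point
  with all cables slack, where the equilibrium problem is locally flat
  and Levenberg–Marquardt stalls on the first loaded step;
* the anterior cable group is stiffer than the posterior one, which
  produces the dorsiflexion/plantarflexion asymmetry.

What the fixture does **not** emulate: subject-specific geometry,
multi-bundle or wrapping ligaments, toe-region refinements of the
force-strain law, out-of-plane motion, and the absolute objective
values reported for the original model.  Passing tests therefore
demonstrate the correctness and the qualitative behaviour of the
procedure, not quantitative agreement with any particular ankle.

## Numerical choices

* Geometry is kept in mm and forces in N throughout; the Hertz constant
  folds the mm→m conversions.
* The ligament exponent is capped at 60 so wild solver trial steps stay
  finite; the cap is far beyond any physical strain.
* Cable force directions are zeroed for slack cables, making the
  residual exactly zero (not merely small) in fully slack
  configurations.
* The analytic residual Jacobian is used for speed and robustness and
  is itself tested against central differences.
* Stable argsort ties and a stable elite ordering keep runs
  deterministic under objective ties.

## Problem sizes

The test suite runs the GA-vs-OAT comparison at population 40 and
50 generations over 5 seeds — the fixture's adversarial margin
(h ≈ −120 vs OAT ≈ −31 already at much smaller budgets) makes larger
runs unnecessary for the qualitative claim — and shorter runs
(population ≤ 20, ≤ 10 generations) wherever only contract properties
are exercised.  The packaged defaults (86/100) remain those of the
headline analysis.

## Known limitations

Planar statics only; no dynamics, no 3-D kinematics, no wrapping or
multi-bundle ligaments, no cartilage meshes.  The OAT baseline and the
GA share the solver, so a systematic solver bias would affect both
arms equally.  `rel_diff` is unstable when `avg` approaches zero, which
is why it is flagged rather than clamped.
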