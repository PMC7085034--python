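"""Synthetic ankle fixture and randomized model generators.

The reference parameter set of the prior planar ankle model that this
package's uncertainty procedure targets is not publicly available, so the
package ships a synthetic stand-in: a hand-calibrated 43-parameter planar
model that reproduces the qualitative regime of such models — full
convergence over the default ±5 Nm schedule, a range of motion of roughly
60 deg, and plantarflexion exceeding dorsiflexion in magnitude.  All
coordinates are in mm in the sagittal plane: x points anteriorly, y
proximally (toward the tibia); the fixed tibia/fibula frame is global and
the talus/calcaneus frame coincides with it at the reference pose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    N_GEOMETRY,
    ContactPairSpec,
    JointModel,
    LigamentSpec,
    Pose2D,
)

__all__ = ["FixtureMetadata", "default_ankle_fixture", "random_plausible_model"]


@dataclass(frozen=True)
class FixtureMetadata:
    name: str
    description: str
    expected_rom_band: tuple[float, float]  # deg, under the default ±5 Nm sweep
    provenance: str


DEFAULT_FIXTURE_METADATA = FixtureMetadata(
    name="synthetic-planar-ankle-v1",
    description=(
        "Synthetic planar talocrural model: six exponential cables "
        "(ATT, TC, PTT, ATF, CF, PTF) and one conforming sphere-in-sphere "
        "cartilage contact, calibrated to ~60 deg range of motion under "
        "±5 Nm with plantarflexion dominant."
    ),
    expected_rom_band=(40.0, 80.0),
    provenance=(
        "Hand-calibrated synthetic parameter set; not derived from any "
        "published subject-specific model."
    ),
)

# name -> (attach_moving, attach_fixed, stiffness_coeff N, shape_coeff).
# Anterior cables (positive x) restrain dorsiflexion, posterior cables
# plantarflexion; the anterior set is slightly stiffer, which gives the
# dorsiflexion/plantarflexion asymmetry.
_FIXTURE_LIGAMENTS = {
    "ATT": ((14.0, -6.0), (6.0, 18.0), 8.0, 20.0),
    "TC": ((2.0, -16.0), (2.0, 20.0), 12.0, 18.0),
    "PTT": ((-12.0, -8.0), (-5.0, 18.0), 8.0, 20.0),
    "ATF": ((20.0, -4.0), (10.0, 14.0), 10.0, 18.0),
    "CF": ((-8.0, -18.0), (-4.0, 16.0), 10.0, 18.0),
    "PTF": ((-20.0, -6.0), (-10.0, 14.0), 10.0, 17.0),
}


def default_ankle_fixture() -> JointModel:
    """The package's versioned synthetic 43-parameter ankle model."""
    ligaments = tuple(
        LigamentSpec(name, am, af, a, b)
        for name, (am, af, a, b) in _FIXTURE_LIGAMENTS.items()
    )
    # The fixed (outer) sphere center sits 2.2 mm below the moving (inner)
    # one, so the conforming contact is preloaded and stays engaged even
    # under worst-case ±0.5 mm geometric perturbations; the preload keeps
    # the cable network taut at zero load, which the static solver needs.
    contact = ContactPairSpec(
        center_moving=(0.0, 0.0),
        center_fixed=(0.0, -2.2),
        radius_inner=20.0,
        clearance=0.5,
        youngs_modulus=2.0,
        poissons_ratio=0.4,
    )
    return JointModel(ligaments, contact, Pose2D())


def random_plausible_model(
    rng: np.random.Generator,
    geometry_jitter: float = 0.5,
    material_jitter: float = 0.05,
) -> JointModel:
    """Default fixture with bounded uniform perturbations.

    Geometry entries move by up to ±``geometry_jitter`` mm, material
    entries by up to ±``material_jitter`` relative; with jitter at the
    default uncertainty bounds (0.5 mm, 5%) almost all samples still
    converge over the full default schedule.
    """
    base = default_ankle_fixture()
    v = base.flatten()
    v[:N_GEOMETRY] += rng.uniform(-geometry_jitter, geometry_jitter, N_GEOMETRY)
    v[N_GEOMETRY:] *= 1.0 + rng.uniform(
        -material_jitter, material_jitter, v.size - N_GEOMETRY
    )
    return base.unflatten(v)
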