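"""Adversarial objective: weighted-L1 separation of two co-encoded models.

Two complete 43-parameter models A and B are packed into one 86-element
decision vector.  The objective is the negated weighted L1 distance
between their moment/angular-displacement curves, plus a penalty of
``PENALTY_WEIGHT`` per load step at which either model failed the static
solver's acceptance condition:

    h = - sum_i w1_i |dtheta_A_i - dtheta_B_i| + w2 * not_passed

with w1 = 2 at the first and last load step and 1 elsewhere, and
w2 = 10.00.  Minimizing h maximizes the curve separation while steering
the search away from parameter sets the solver cannot equilibrate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .model import (
    N_PARAMS,
    InvalidParameterError,
    JointModel,
    LoadSchedule,
    SingularGeometryError,
    SweepResult,
    sweep_loads,
)

__all__ = [
    "N_DECISION",
    "PENALTY_WEIGHT",
    "EncodingError",
    "ObjectiveBreakdown",
    "split",
    "endpoint_weights",
    "weighted_l1",
    "objective_from_sweeps",
    "objective",
    "make_objective",
]

logger = logging.getLogger(__name__)

#: length of the decision vector (two full parameter sets)
N_DECISION = 2 * N_PARAMS

#: per-failed-load-step penalty weight (w2)
PENALTY_WEIGHT = 10.0


class EncodingError(ValueError):
    """Malformed decision vector."""


@dataclass(frozen=True)
class ObjectiveBreakdown:
    """Objective value and its two constituents: h = -l1_term + penalty."""

    h: float
    l1_term: float
    not_passed: int

    @property
    def penalty(self) -> float:
        return PENALTY_WEIGHT * self.not_passed


def split(dv: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Split an 86-element decision vector into the A and B halves."""
    v = np.asarray(dv, dtype=float)
    if v.shape != (N_DECISION,):
        raise EncodingError(
            f"decision vector must have {N_DECISION} entries, got {v.shape}"
        )
    return v[:N_PARAMS].copy(), v[N_PARAMS:].copy()


def endpoint_weights(m_steps: int) -> np.ndarray:
    """Per-load-step weights: 2 at both schedule endpoints, 1 between."""
    if m_steps < 2:
        raise EncodingError("need at least 2 load steps for endpoint weights")
    w = np.ones(m_steps)
    w[0] = w[-1] = 2.0
    return w


def weighted_l1(
    curve_a: Sequence[float],
    curve_b: Sequence[float],
    weights: Sequence[float],
) -> float:
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (a.shape == b.shape == w.shape):
        raise EncodingError("curves and weights must have matching lengths")
    return float(np.sum(w * np.abs(a - b)))


def objective_from_sweeps(
    sweep_a: SweepResult, sweep_b: SweepResult
) -> ObjectiveBreakdown:
    """Score two already-computed sweeps with the adversarial objective."""
    w = endpoint_weights(len(sweep_a.moments))
    l1 = weighted_l1(
        sweep_a.angular_displacement, sweep_b.angular_displacement, w
    )
    n_fail = sweep_a.not_passed + sweep_b.not_passed
    return ObjectiveBreakdown(
        h=-l1 + PENALTY_WEIGHT * n_fail, l1_term=l1, not_passed=n_fail
    )


def _sweep_or_fail(
    params: np.ndarray, template: JointModel, schedule: LoadSchedule
) -> tuple[np.ndarray, int]:
    """Curve and failure count for one half; a model that cannot even be
    constructed (degenerate geometry, invalid materials) scores all of
    its load steps as failed with a flat curve."""
    try:
        sw = sweep_loads(template.unflatten(params), schedule)
    except (InvalidParameterError, SingularGeometryError):
        return np.zeros(len(schedule)), len(schedule)
    return sw.angular_displacement, sw.not_passed


def objective(
    dv: Sequence[float],
    template: JointModel,
    schedule: LoadSchedule | None = None,
) -> ObjectiveBreakdown:
    """Evaluate the adversarial objective for one decision vector.

    ``template`` supplies the non-free configuration (contact clearance,
    reference pose) shared by both encoded models.
    """
    sched = schedule or LoadSchedule.default()
    pa, pb = split(dv)
    curve_a, fail_a = _sweep_or_fail(pa, template, sched)
    curve_b, fail_b = _sweep_or_fail(pb, template, sched)
    l1 = weighted_l1(curve_a, curve_b, endpoint_weights(len(sched)))
    n_fail = fail_a + fail_b
    out = ObjectiveBreakdown(
        h=-l1 + PENALTY_WEIGHT * n_fail, l1_term=l1, not_passed=n_fail
    )
    logger.debug(
        "objective h=%.4f l1=%.4f not_passed=%d", out.h, out.l1_term, n_fail
    )
    return out


def make_objective(
    template: JointModel, schedule: LoadSchedule | None = None
) -> Callable[[np.ndarray], float]:
    """Scalar objective closure for the genetic algorithm."""
    sched = schedule or LoadSchedule.default()
    return lambda dv: objective(dv, template, sched).h
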