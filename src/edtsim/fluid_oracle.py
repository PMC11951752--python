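"""Deterministic fluid approximation of the laboratory EDT queue.

Treats arrivals and service as continuous flows: the queue drains at the
capacity rate ``c`` per week while non-empty, fed by an effective arrival
rate ``lambda_eff`` (what remains of referral demand after the screening
step).  The construction yields closed-form waiting-time trajectories used
as an independent analytic cross-check on the discrete-event simulation:

* backlog patients (initial mass ``B``) are served first, so a patient
  served at time ``t <= B/c`` waited ``t`` weeks (plus any accrued credit);
* afterwards the patient served at ``t`` arrived at ``(c*t - B)/lambda_eff``,
  so ``wait(t) = t - (c*t - B)/lambda_eff``;
* if ``lambda_eff < c`` the queue empties at ``t* = B/(c - lambda_eff)`` and
  waits are zero thereafter (residual stochastic queueing delay in this
  underloaded regime is deliberately ignored).

Windowed means integrate ``wait(t)`` weighted by the service rate (``c``
while the queue persists, ``lambda_eff`` afterwards) with exact piecewise
algebra — no numeric quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .pathway_des import ScenarioConfig

__all__ = [
    "FluidState",
    "effective_rate",
    "fluid_state_for",
    "fluid_window_wait",
]


@dataclass(frozen=True)
class FluidState:
    """Effective load on the laboratory queue in the fluid picture."""

    lambda_eff: float
    capacity: float
    backlog: float
    accrued_weeks: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_eff < 0:
            raise ValueError(f"lambda_eff must be >= 0, got {self.lambda_eff}")
        if self.capacity <= 0:
            raise ValueError(f"capacity must be positive, got {self.capacity}")
        if self.backlog < 0:
            raise ValueError(f"backlog must be >= 0, got {self.backlog}")

    @property
    def clearance_week(self) -> float:
        """Week at which the queue empties; infinite when lambda_eff >= capacity."""
        if self.lambda_eff < self.capacity:
            return self.backlog / (self.capacity - self.lambda_eff)
        return math.inf


def effective_rate(config: ScenarioConfig, group_params: Sequence) -> float:
    """Effective weekly arrival rate into the laboratory EDT queue.

    Unscreened groups (including D, always) contribute their full rate; a
    screened group g contributes ``lam_g * (p_g*Se + (1-p_g)*(1-Sp))`` — the
    flagged fraction.  Scaled by ``demand_scale``.
    """
    scr = config.screening
    lam = 0.0
    for gp in group_params:
        if (
            config.screening_enabled
            and gp.screenable
            and gp.group in scr.screened_groups
            and gp.p_abnormal is not None
        ):
            p = gp.p_abnormal
            lam += gp.weekly_rate * (
                p * scr.sensitivity + (1.0 - p) * (1.0 - scr.specificity)
            )
        else:
            lam += gp.weekly_rate
    return config.demand_scale * lam


def fluid_state_for(config: ScenarioConfig, group_params: Sequence) -> FluidState:
    """Fluid load implied by a scenario configuration."""
    return FluidState(
        lambda_eff=effective_rate(config, group_params),
        capacity=float(config.capacity_per_week),
        backlog=float(config.backlog),
        accrued_weeks=config.backlog_accrued_weeks,
    )


def fluid_window_wait(state: FluidState, window) -> float:
    """Mean fluid wait of patients served within ``window`` = (start, end].

    Returns 0.0 when no fluid mass is served in the window.
    """
    w0, w1 = float(window[0]), float(window[1])
    if not (0.0 <= w0 < w1):
        raise ValueError(f"window must satisfy 0 <= start < end, got ({w0}, {w1})")
    lam, c, B = state.lambda_eff, state.capacity, state.backlog
    t_backlog = B / c
    t_clear = state.clearance_week

    # Segments: (t0, t1, a, b, rate) with wait(t) = a + b*t served at `rate`.
    segments = []
    if t_backlog > 0:
        segments.append((0.0, t_backlog, state.accrued_weeks, 1.0, c))
    if lam > 0 and t_clear > t_backlog:
        segments.append((t_backlog, t_clear, B / lam, 1.0 - c / lam, c))
    if math.isfinite(t_clear):
        segments.append((t_clear, math.inf, 0.0, 0.0, lam))

    mass = 0.0
    wait_mass = 0.0
    for t0, t1, a, b, rate in segments:
        lo, hi = max(t0, w0), min(t1, w1)
        if hi <= lo or rate <= 0:
            continue
        mass += rate * (hi - lo)
        wait_mass += rate * (a * (hi - lo) + b * (hi * hi - lo * lo) / 2.0)
    if mass <= 0:
        return 0.0
    return wait_mass / mass
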