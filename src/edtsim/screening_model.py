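"""Hand-held ERG screening step at the point of referral.

A binary diagnostic screen with sensitivity ``Se`` (probability a truly
abnormal patient is flagged) and specificity ``Sp`` (probability a truly
normal patient is cleared).  Flagged patients proceed to the laboratory EDT
queue; cleared patients leave the pathway.  Screening is instantaneous and
capacity-unconstrained: the device is cheap and usable at referring centres,
so no screening queue is modelled.

Borderline device readings are not modelled — the screen is strictly binary,
and false negatives do not re-enter the pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "ScreeningParams",
    "ScreenOutcome",
    "screen_patient",
    "expected_screen_counts",
]

_SCREENABLE = frozenset({"A", "B", "C"})


@dataclass(frozen=True)
class ScreeningParams:
    sensitivity: float = 0.95
    specificity: float = 0.95
    screened_groups: frozenset = frozenset({"A", "B", "C"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "screened_groups", frozenset(self.screened_groups))
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v!r}")
        bad = self.screened_groups - _SCREENABLE
        if bad:
            raise ValueError(
                "screened_groups may only contain A, B, C (group D referrals are "
                f"primarily for VEP and cannot be screened): got {sorted(bad)}"
            )


@dataclass(frozen=True)
class ScreenOutcome:
    """Result of one screen: whether the patient proceeds, and its confusion class."""

    flagged: bool
    confusion_class: str  # one of "TP", "FP", "TN", "FN"


def screen_patient(
    true_abnormal: bool, params: ScreeningParams, rand_draw: float
) -> ScreenOutcome:
    """Apply the screen to one patient given a uniform(0, 1) draw.

    An abnormal patient is flagged iff ``rand_draw < Se``; a normal patient
    is cleared iff ``rand_draw < Sp`` (i.e. flagged with probability 1-Sp).
    """
    if not (0.0 <= rand_draw < 1.0):
        raise ValueError(f"rand_draw must be in [0, 1), got {rand_draw!r}")
    if true_abnormal:
        flagged = rand_draw < params.sensitivity
        cls = "TP" if flagged else "FN"
    else:
        flagged = rand_draw >= params.specificity
        cls = "FP" if flagged else "TN"
    return ScreenOutcome(flagged=flagged, confusion_class=cls)


def expected_screen_counts(
    params: ScreeningParams,
    group_params: Sequence,
    horizon_weeks: float,
) -> dict[str, float]:
    """Closed-form expected screening counts over a horizon.

    For each screened group g with weekly rate lam_g and abnormality
    probability p_g, over T weeks:

    * screened      = sum T * lam_g
    * TP            = sum T * lam_g * p_g * Se
    * FN            = sum T * lam_g * p_g * (1 - Se)
    * FP            = sum T * lam_g * (1 - p_g) * (1 - Sp)
    * TN            = sum T * lam_g * (1 - p_g) * Sp
    * flagged       = TP + FP      (proceed to the laboratory EDT queue)
    * screened_out  = FN + TN      (leave the pathway)
    """
    if horizon_weeks < 0:
        raise ValueError(f"horizon_weeks must be >= 0, got {horizon_weeks}")
    se, sp = params.sensitivity, params.specificity
    screened = tp = fn = fp = tn = 0.0
    for gp in group_params:
        if gp.group not in params.screened_groups or not gp.screenable:
            continue
        mass = gp.weekly_rate * horizon_weeks
        p = gp.p_abnormal
        screened += mass
        tp += mass * p * se
        fn += mass * p * (1.0 - se)
        fp += mass * (1.0 - p) * (1.0 - sp)
        tn += mass * (1.0 - p) * sp
    return {
        "screened": screened,
        "flagged": tp + fp,
        "screened_out": fn + tn,
        "TP": tp,
        "FN": fn,
        "FP": fp,
        "TN": tn,
    }
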