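"""Scoring rules of the dyadic button-press task.

Cooperation and communication blocks reward simultaneous responses: a trial
succeeds when the absolute response-time difference stays within a margin of
error E = (RT_a' + RT_b') / 8 computed from adjusted response times.
Responses faster than 1.6 s are adjusted through RT' = (e^RT - 1) / 2.5,
which narrows the margin for fast responders while staying continuous to
within 1.2% at the breakpoint ((e^1.6 - 1)/2.5 = 1.5812).  Competition
rewards the faster valid responder.  Time-outs (> 6 s) and premature
responses are invalid and carry a larger deduction than an ordinary failure.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass
from typing import Callable, Optional

__all__ = [
    "TrialOutcome",
    "adjust_rt",
    "margin_of_error",
    "judge_cooperation",
    "judge_competition",
    "judge_solo",
    "block_accuracy",
]

#: Response-time breakpoint (s) below which the adjustment kicks in.
RT_BREAKPOINT = 1.6
#: Time-out limit (s); slower responses are invalid.
TIMEOUT = 6.0
#: Points deducted for an invalid trial (time-out / premature response);
#: deliberately larger than the -1 of an ordinary failure.
INVALID_PENALTY = 2


@dataclass(frozen=True)
class TrialOutcome:
    """Judged result of one trial with the points awarded to each member."""

    judged: str  # "success" | "failure" | "invalid" | "tie"
    points_a: int
    points_b: int
    rt_difference: Optional[float] = None
    margin: Optional[float] = None


def adjust_rt(rt: float) -> float:
    """Adjusted response time: identity above 1.6 s, (e^rt - 1)/2.5 at/below.

    The breakpoint itself takes the adjusted value (e^1.6 - 1)/2.5 = 1.5812,
    within 1.2% of the identity, so the transition has no noticeable cut-off.
    """
    if not rt > 0:
        raise ValueError(f"response time must be positive, got {rt}")
    if rt > RT_BREAKPOINT:
        return float(rt)
    return (math.exp(rt) - 1.0) / 2.5


def margin_of_error(
    rt_a: float, rt_b: float, adjust: Callable[[float], float] = adjust_rt
) -> float:
    """Margin of error E = (RT_a' + RT_b') / 8 for simultaneity judgement.

    ``adjust`` is pluggable so alternative readings of the adjustment rule
    can be explored.
    """
    return (adjust(rt_a) + adjust(rt_b)) / 8.0


def _invalid(rt: Optional[float], premature: bool, timeout: float) -> bool:
    return premature or rt is None or rt > timeout


def judge_cooperation(
    rt_a: Optional[float],
    rt_b: Optional[float],
    timeout: float = TIMEOUT,
    premature_a: bool = False,
    premature_b: bool = False,
    strict: bool = False,
    invalid_penalty: int = INVALID_PENALTY,
) -> TrialOutcome:
    """Judge a cooperation/communication trial.

    Success (both +1) when both responses are valid and |RT_a - RT_b| falls
    within the margin of error; failure (both -1) otherwise.  An invalid
    response (time-out, premature, or missing) costs that member
    ``invalid_penalty`` points and the trial is judged invalid; a valid
    partner in an invalid trial takes the ordinary failure deduction.

    ``strict`` switches the margin comparison from <= to <.
    """
    bad_a = _invalid(rt_a, premature_a, timeout)
    bad_b = _invalid(rt_b, premature_b, timeout)
    if bad_a or bad_b:
        return TrialOutcome(
            judged="invalid",
            points_a=-invalid_penalty if bad_a else -1,
            points_b=-invalid_penalty if bad_b else -1,
            rt_difference=None if (rt_a is None or rt_b is None) else abs(rt_a - rt_b),
        )
    margin = margin_of_error(rt_a, rt_b)
    diff = abs(rt_a - rt_b)
    ok = diff < margin if strict else diff <= margin
    pts = 1 if ok else -1
    return TrialOutcome(
        judged="success" if ok else "failure",
        points_a=pts,
        points_b=pts,
        rt_difference=diff,
        margin=margin,
    )


def judge_competition(
    rt_a: Optional[float],
    rt_b: Optional[float],
    timeout: float = TIMEOUT,
    premature_a: bool = False,
    premature_b: bool = False,
    invalid_penalty: int = INVALID_PENALTY,
) -> TrialOutcome:
    """Judge a competition trial: faster valid responder +1, slower -1.

    An invalid responder loses with the larger deduction; exact ties score 0
    for both (a probability-zero event for continuous response times).
    """
    bad_a = _invalid(rt_a, premature_a, timeout)
    bad_b = _invalid(rt_b, premature_b, timeout)
    diff = None if (rt_a is None or rt_b is None) else abs(rt_a - rt_b)
    if bad_a and bad_b:
        return TrialOutcome("invalid", -invalid_penalty, -invalid_penalty, diff)
    if bad_a:
        return TrialOutcome("invalid", -invalid_penalty, 1, diff)
    if bad_b:
        return TrialOutcome("invalid", 1, -invalid_penalty, diff)
    if rt_a == rt_b:
        return TrialOutcome("tie", 0, 0, 0.0)
    if rt_a < rt_b:
        return TrialOutcome("success", 1, -1, diff)
    return TrialOutcome("success", -1, 1, diff)


def judge_solo(
    rt: Optional[float],
    timeout: float = TIMEOUT,
    premature: bool = False,
    invalid_penalty: int = INVALID_PENALTY,
) -> TrialOutcome:
    """Judge a solo trial: any valid response within the time-out earns +1.

    The watching partner neither responds nor scores (points_b = 0).
    """
    if _invalid(rt, premature, timeout):
        return TrialOutcome("invalid", -invalid_penalty, 0)
    return TrialOutcome("success", 1, 0)


def block_accuracy(trials: Sequence[TrialOutcome], condition: str | None = None) -> float:
    """Proportion of successful trials in a block."""
    if len(trials) == 0:
        raise ValueError("block accuracy undefined for an empty trial list")
    return sum(t.judged == "success" for t in trials) / len(trials)
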