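"""Burn-in filtering, reward-scheme scoring and the trade-off indices.

The voluntary quality/quantity trade-off is quantified per participant
from the per-condition mixture fits:

    SDT = (SD_low - SD_high) / SD_low      (relative sharpening)
    PT  = (P_low  - P_high)  / P_low       (relative drop in retention)
    GT  = SDT + PT                          (general trade-off)

Positive SDT/PT indicate a trade-off in the task-required direction:
more precise but fewer retained items under the high-precision reward
scheme.
"""

from __future__ import annotations

import warnings

from .errors import EstimationError

__all__ = ["apply_burn_in", "score_response", "tradeoff_indices"]

# Reward scheme (points). Boundaries read literally: "less than 60"
# strict, 60..100 inclusive earns nothing, "more than 100" strict;
# high precision: "less than 20" strict.
LOW_HIT_THRESHOLD = 60.0
LOW_PENALTY_THRESHOLD = 100.0
HIGH_HIT_THRESHOLD = 20.0
LOW_HIT_POINTS = 4
LOW_PENALTY_POINTS = -2
HIGH_HIT_POINTS = 6
STARTING_SCORE = 100

DEFAULT_BURN_IN = 80


def apply_burn_in(trials, n_skip: int = DEFAULT_BURN_IN):
    """Drop the first ``n_skip`` trials of each condition block.

    Early trials are contaminated by strategy formation under the
    feedback scheme, so analysis keeps only trials with
    ``trial_index > n_skip`` within each condition. With 280-trial
    blocks and the default skip of 80, exactly the last 200 trials
    per condition remain. Idempotent once applied.
    """
    if n_skip < 0:
        raise ValueError("n_skip must be >= 0")
    kept = [t for t in trials if t.trial_index > n_skip]
    if trials and not kept:
        warnings.warn(
            f"burn-in of {n_skip} trials removed every trial "
            f"(block length {len(trials)})",
            stacklevel=2,
        )
    return kept


def score_response(offset_deg: float, condition: str) -> int:
    """Points awarded for a response at ``offset_deg`` under a condition.

    Low precision: +4 below 60 deg, 0 from 60 to 100 deg, -2 above
    100 deg (wild guess). High precision: +6 below 20 deg, else 0.
    """
    if not 0.0 <= offset_deg <= 180.0:
        raise ValueError(f"offset_deg must be in [0, 180], got {offset_deg}")
    if condition == "low_precision":
        if offset_deg < LOW_HIT_THRESHOLD:
            return LOW_HIT_POINTS
        if offset_deg > LOW_PENALTY_THRESHOLD:
            return LOW_PENALTY_POINTS
        return 0
    if condition == "high_precision":
        return HIGH_HIT_POINTS if offset_deg < HIGH_HIT_THRESHOLD else 0
    raise ValueError(f"unknown condition {condition!r}")


def tradeoff_indices(
    sd_low: float,
    sd_high: float,
    p_low: float,
    p_high: float,
    weight: float = 1.0,
) -> tuple[float, float, float]:
    """Compute (SDT, PT, GT) from per-condition precision and retention.

    ``weight`` scales PT's contribution to GT (default 1: equal
    weighting, GT = SDT + PT).
    """
    if sd_low <= 0:
        raise EstimationError("SDT undefined: sd_low (denominator) must be > 0")
    if p_low <= 0:
        raise EstimationError("PT undefined: p_low (denominator) must be > 0")
    sdt = (sd_low - sd_high) / sd_low
    pt = (p_low - p_high) / p_low
    gt = sdt + weight * pt
    return sdt, pt, gt
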