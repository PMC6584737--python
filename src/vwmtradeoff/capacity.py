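"""Cowan's K capacity estimation and median-split grouping.

For single-probe change detection at set size N, capacity is estimated
as K = N * (H - F) with H the hit rate (P("change" | changed)) and F the
false-alarm rate (P("change" | unchanged)). Negative K is preserved
(not floored) and flagged, so simulation recovery stays unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import ChangeDetectionTrial
from .errors import EstimationError

__all__ = ["CapacityEstimate", "hit_fa_rates", "cowans_k", "median_split"]


@dataclass(frozen=True)
class CapacityEstimate:
    """Cowan's K for one participant, with its ingredient rates."""

    participant_id: str
    set_size: int
    h: float
    f: float
    k: float
    group: str = "unassigned"
    low_quality: bool = False


def hit_fa_rates(trials: list[ChangeDetectionTrial]) -> tuple[float, float]:
    """Hit and false-alarm rates from change-detection trials."""
    changed = [t.response_change for t in trials if t.changed]
    unchanged = [t.response_change for t in trials if not t.changed]
    if not changed or not unchanged:
        raise EstimationError(
            "need at least one changed and one unchanged trial to estimate H and F"
        )
    return float(np.mean(changed)), float(np.mean(unchanged))


def cowans_k(set_size: int, h: float, f: float) -> float:
    """Cowan's K = N * (H - F). May be negative when F > H."""
    if not (0.0 <= h <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError("H and F must be proportions in [0, 1]")
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    return float(set_size) * (h - f)


def estimate_capacity(trials: list[ChangeDetectionTrial]) -> CapacityEstimate:
    """Estimate Cowan's K for one participant's trials (single set size)."""
    sizes = {t.set_size for t in trials}
    if len(sizes) != 1:
        raise EstimationError(f"trials mix set sizes {sorted(sizes)}")
    n = sizes.pop()
    h, f = hit_fa_rates(trials)
    k = cowans_k(n, h, f)
    return CapacityEstimate(
        participant_id=trials[0].participant_id,
        set_size=n,
        h=h,
        f=f,
        k=k,
        low_quality=k < 0,
    )


def median_split(ks: dict[str, float] | list[float]) -> dict[str, str]:
    """Assign participants to low/high capacity groups at the sample median.

    K strictly above the median goes to ``high``, strictly below to
    ``low``. Ties at the median are assigned in stable participant
    order, alternating low/high starting with whichever group is
    smaller (low first on an exact balance), so group sizes stay as
    equal as the ties allow; a warning lists the tied IDs.
    """
    if isinstance(ks, dict):
        ids = list(ks.keys())
        values = np.asarray([ks[i] for i in ids], dtype=float)
    else:
        ids = [str(i) for i in range(len(ks))]
        values = np.asarray(ks, dtype=float)
    if len(ids) < 2:
        raise EstimationError("median split needs at least two participants")
    med = float(np.median(values))
    groups: dict[str, str] = {}
    tied = [pid for pid, v in zip(ids, values) if v == med]
    n_low = int(np.sum(values < med))
    n_high = int(np.sum(values > med))
    for pid, v in zip(ids, values):
        if v < med:
            groups[pid] = "low"
        elif v > med:
            groups[pid] = "high"
    if tied:
        warnings.warn(
            f"K ties at the median ({med}) for participants {tied}; "
            "assigning alternately to balance group sizes",
            stacklevel=2,
        )
        for pid in tied:
            groups[pid] = "low" if n_low <= n_high else "high"
            if groups[pid] == "low":
                n_low += 1
            else:
                n_high += 1
    return groups
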