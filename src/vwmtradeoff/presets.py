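"""Preset cohort specs emulating the two study conditions.

Both presets share the session structure (26 participants, 100
change-detection trials at set size 6, 280 recall trials per precision
condition at set size 4) and the capacity distribution (truncated
normal, mean 2.65, SD 0.9 — chosen so a median split reproduces group
means near 3.4 and 1.9 items). They differ only in the exposure regime:

* ``exp1_spec``: long exposure (500 ms, 125 ms/item). Capacity is
  linked to the true trade-off with slope alpha = 0.15 above a
  threshold k0 = 1.5 items.
* ``exp2_spec``: short exposure (200 ms, 50 ms/item). No capacity
  linkage (alpha = 0); both conditions share identical parameters.
"""

from __future__ import annotations

from .datamodel import CohortSpec

__all__ = ["exp1_spec", "exp2_spec"]


def exp1_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Long-exposure preset: capacity-linked voluntary trade-off."""
    params = dict(
        n_participants=26,
        regime="long_duration",
        alpha=0.15,
        k0=1.5,
        exposure_ms=500.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)


def exp2_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Short-exposure preset: no capacity-trade-off linkage."""
    params = dict(
        n_participants=26,
        regime="short_duration",
        alpha=0.0,
        k0=1.5,
        exposure_ms=200.0,
        seed=seed,
    )
    params.update(overrides)
    return CohortSpec(**params)
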