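"""Core domain types for recall / change-detection trials and results.

Angles are stored in degrees in [0, 360); signed errors in (-180, 180].
The colour space is treated as a plain 360-point circle — the colour
index is the analysis currency, no colorimetric rendering is involved.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

from .angles import circular_offset
from .errors import ConfigError

Condition = Literal["low_precision", "high_precision"]
CONDITIONS: tuple[str, str] = ("low_precision", "high_precision")

Regime = Literal["long_duration", "short_duration"]


@dataclass(frozen=True)
class RecallTrial:
    """One continuous-report trial: remember four colours, report one.

    ``offset_deg`` is the absolute circular difference between response
    and target (the "Offset" feedback value); ``score`` is the reward
    points this trial earned under its condition's feedback scheme.
    """

    participant_id: str
    condition: str
    trial_index: int
    target_deg: float
    nontargets_deg: tuple[float, float, float]
    response_deg: float
    offset_deg: float
    score: int

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        expected = circular_offset(self.response_deg, self.target_deg)
        if abs(expected - self.offset_deg) > 1e-6:
            raise ValueError(
                f"offset_deg {self.offset_deg} inconsistent with "
                f"response/target (expected {expected})"
            )


@dataclass(frozen=True)
class ChangeDetectionTrial:
    """One single-probe change-detection trial at set size ``set_size``."""

    participant_id: str
    set_size: int
    changed: bool
    response_change: bool

    def __post_init__(self):
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")


@dataclass(frozen=True)
class MixtureFit:
    """Fitted mixture-model parameters for one participant x condition.

    ``p_mem`` is the retention probability P = 1 - G (standard model) or
    P = 1 - G - B (swap model). ``loglik`` uses densities per degree, so
    values are comparable to the uniform baseline n*log(1/360).
    """

    model: str
    guess_rate: float
    kappa: float
    sd_deg: float
    swap_rate: float
    p_mem: float
    loglik: float
    n_trials: int

    def __post_init__(self):
        if self.model not in ("standard", "swap"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.guess_rate <= 1.0:
            raise ValueError("guess_rate must be in [0, 1]")
        if self.guess_rate + self.swap_rate > 1.0 + 1e-9:
            raise ValueError("guess_rate + swap_rate must not exceed 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-participant capacity, per-condition fits, trade-off indices."""

    participant_id: str
    k: float
    group: str
    sd_low: float
    sd_high: float
    p_low: float
    p_high: float
    sdt: float
    pt: float
    gt: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Simulation truth for one participant (recovery-test sidecar)."""

    participant_id: str
    true_k: float
    true_p: dict[str, float]
    true_sd_deg: dict[str, float]
    true_swap_rate: dict[str, float]
    true_sdt: float
    true_pt: float
    true_gt: float
    u: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    The cohort emulates a two-session study: a change-detection session
    (set size ``set_size``, ``n_cd_trials`` trials) and a colour-recall
    session with ``n_recall_trials`` trials per precision condition.
    Capacity K is drawn per participant from a truncated normal;
    ``regime`` controls whether capacity maps onto a true voluntary
    trade-off (``long_duration``: true GT = max(0, alpha*(K - k0))) or
    the two conditions share identical parameters (``short_duration``).
    """

    n_participants: int = 26
    regime: str = "long_duration"
    capacity_mean: float = 2.65
    capacity_sd: float = 0.9
    capacity_min: float = 0.5
    capacity_max: float = 5.5
    alpha: float = 0.15
    k0: float = 1.5
    baseline_p: float = 0.75
    baseline_sd_deg: float = 30.0
    swap_rate: float = 0.0
    set_size: int = 6
    n_cd_trials: int = 100
    n_recall_trials: int = 280
    u: float = 0.5
    exposure_ms: float = 500.0
    recall_set_size: int = 4
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.regime not in ("long_duration", "short_duration"):
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for name in ("n_cd_trials", "n_recall_trials", "set_size"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0.0 <= self.u <= 1.0:
            raise ConfigError("u must be a probability in [0, 1]")
        if not 0.0 < self.baseline_p <= 1.0:
            raise ConfigError("baseline_p must be in (0, 1]")
        if self.baseline_sd_deg <= 0:
            raise ConfigError("baseline_sd_deg must be > 0")
        if not 0.0 <= self.swap_rate <= 1.0 - self.baseline_p:
            raise ConfigError("swap_rate must be in [0, 1 - baseline_p]")
        if self.capacity_sd <= 0 or self.capacity_min >= self.capacity_max:
            raise ConfigError("invalid capacity distribution parameters")
        if self.capacity_max > self.set_size:
            raise ConfigError("capacity_max cannot exceed change-detection set size")
        if self.regime == "short_duration" and self.alpha != 0.0:
            raise ConfigError(
                "short_duration regime requires alpha = 0 (no capacity-linked trade-off)"
            )

    @property
    def effective_alpha(self) -> float:
        return 0.0 if self.regime == "short_duration" else self.alpha

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigError(f"unknown cohort spec fields: {sorted(unknown)}")
        return cls(**d)
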