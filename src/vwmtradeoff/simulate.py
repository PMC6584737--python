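"""Synthetic cohorts with known ground truth.

Two generators mirror the two experimental sessions:

* Change detection: an item-slot model in which the probed item is
  "stored" with probability min(k, N)/N. Stored probes are answered
  correctly; unstored probes draw a "change" response with guess
  probability u. This is exactly the model under which Cowan's
  K = N(H - F) is unbiased: E[H] = k/N + (1 - k/N)u and
  E[F] = (1 - k/N)u, so E[N(H - F)] = k.

* Continuous report: per trial, a target and three non-targets are drawn
  on the colour circle with at least 30 degrees pairwise separation
  (rejection sampling); the response is the target plus von Mises noise
  with probability P, a uniformly chosen non-target plus the same noise
  with probability B (swap), and uniform otherwise.

A cohort couples the two sessions: capacity K_i is drawn from a
truncated normal, and in the ``long_duration`` regime each participant's
true trade-off magnitude is g_i = max(0, alpha * (K_i - k0)), split
equally between a relative SD sharpening and a relative P drop so the
true GT equals g_i. In the ``short_duration`` regime both conditions
share identical parameters (true GT = 0 for everyone). Per-participant
RNG streams are derived from the cohort seed and the participant index,
so generation is reproducible trial-for-trial.
"""

from __future__ import annotations

import numpy as np

from .angles import circular_offset, signed_error
from .datamodel import (
    CONDITIONS,
    ChangeDetectionTrial,
    CohortSpec,
    GroundTruth,
    RecallTrial,
)
from .errors import ConfigError
from .mixture import sd_to_kappa
from .tradeoff import score_response

__all__ = ["simulate_change_detection", "simulate_recall", "simulate_cohort"]

MIN_SEPARATION_DEG = 30.0
_MAX_REJECTION_ATTEMPTS = 10_000


def simulate_change_detection(
    true_k: float,
    set_size: int,
    n_trials: int,
    u: float,
    seed,
    participant_id: str = "sim",
) -> list[ChangeDetectionTrial]:
    """Simulate single-probe change detection under the item-slot model.

    Half the trials (rounded down) are change trials. ``seed`` may be an
    int or a numpy Generator.
    """
    if not 0.0 <= true_k <= set_size:
        raise ValueError(f"true_k must be in [0, {set_size}], got {true_k}")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be a probability in [0, 1]")
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    p_store = min(true_k, set_size) / set_size
    n_change = n_trials // 2
    changed = np.zeros(n_trials, dtype=bool)
    changed[:n_change] = True
    rng.shuffle(changed)
    stored = rng.random(n_trials) < p_store
    guess_change = rng.random(n_trials) < u
    # stored probe -> truthful answer; unstored -> guess "change" w.p. u
    response = np.where(stored, changed, guess_change)
    return [
        ChangeDetectionTrial(
            participant_id=participant_id,
            set_size=set_size,
            changed=bool(c),
            response_change=bool(r),
        )
        for c, r in zip(changed, response)
    ]


def _draw_item_colors(rng: np.random.Generator, n_items: int) -> np.ndarray:
    """Draw n_items colours with pairwise circular separation >= 30 deg."""
    return _draw_item_colors_batch(rng, n_items, 1)[0]


def _draw_item_colors_batch(
    rng: np.random.Generator, n_items: int, n_trials: int
) -> np.ndarray:
    """Rejection-sample an (n_trials, n_items) colour array.

    Each row satisfies the pairwise 30-degree minimum separation; rows
    failing the constraint are redrawn in batches until all are filled.
    """
    if n_items * MIN_SEPARATION_DEG >= 360.0:
        raise ConfigError(
            f"cannot place {n_items} colours with {MIN_SEPARATION_DEG} deg separation"
        )
    out = np.empty((n_trials, n_items))
    pending = np.arange(n_trials)
    iu = np.triu_indices(n_items, k=1)
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        cols = rng.uniform(0.0, 360.0, size=(pending.size, n_items))
        d = circular_offset(cols[:, :, None], cols[:, None, :])
        ok = np.all(d[:, iu[0], iu[1]] >= MIN_SEPARATION_DEG, axis=1)
        out[pending[ok]] = cols[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise ConfigError("rejection sampling for item colours failed to converge")


def simulate_recall(
    true_p: float,
    true_sd_deg: float,
    true_swap_rate: float,
    n_trials: int,
    condition: str,
    seed,
    participant_id: str = "sim",
    n_items: int = 4,
) -> list[RecallTrial]:
    """Simulate continuous-report trials from mixture-model ground truth."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not 0.0 <= true_p <= 1.0 or true_swap_rate < 0:
        raise ValueError("true_p and true_swap_rate must be probabilities")
    if true_p + true_swap_rate > 1.0 + 1e-12:
        raise ValueError("true_p + true_swap_rate must not exceed 1")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if true_sd_deg <= 0:
        raise ValueError("true_sd_deg must be > 0")
    rng = np.random.default_rng(seed)
    kappa = sd_to_kappa(true_sd_deg)
    cols = _draw_item_colors_batch(rng, n_items, n_trials)
    targets, nontargets = cols[:, 0], cols[:, 1:]
    comp = rng.random(n_trials)
    lure_idx = rng.integers(n_items - 1, size=n_trials)
    noise = np.rad2deg(rng.vonmises(0.0, kappa, size=n_trials))
    uniform = rng.uniform(0.0, 360.0, size=n_trials)
    is_mem = comp < true_p
    is_swap = (~is_mem) & (comp < true_p + true_swap_rate)
    centre = np.where(
        is_mem, targets, nontargets[np.arange(n_trials), lure_idx]
    )
    resp_deg = np.where(is_mem | is_swap, (centre + noise) % 360.0, uniform)
    offsets = circular_offset(resp_deg, targets)
    return [
        RecallTrial(
            participant_id=participant_id,
            condition=condition,
            trial_index=i + 1,
            target_deg=float(targets[i]),
            nontargets_deg=tuple(float(c) for c in nontargets[i]),
            response_deg=float(resp_deg[i]),
            offset_deg=float(offsets[i]),
            score=score_response(float(offsets[i]), condition),
        )
        for i in range(n_trials)
    ]


def _participant_truth(spec: CohortSpec, true_k: float, pid: str) -> GroundTruth:
    """Map capacity to per-condition ground truth under the regime."""
    g = max(0.0, spec.effective_alpha * (true_k - spec.k0))
    # split the true GT equally between the SD and P components
    sdt, pt = g / 2.0, g / 2.0
    p_low, sd_low = spec.baseline_p, spec.baseline_sd_deg
    p_high = p_low * (1.0 - pt)
    sd_high = sd_low * (1.0 - sdt)
    if sd_high <= 0 or p_high < 0:
        raise ConfigError(
            f"linkage produced inadmissible truth for {pid} (g = {g:.3f})"
        )
    return GroundTruth(
        participant_id=pid,
        true_k=float(true_k),
        true_p={"low_precision": p_low, "high_precision": p_high},
        true_sd_deg={"low_precision": sd_low, "high_precision": sd_high},
        true_swap_rate={c: spec.swap_rate for c in CONDITIONS},
        true_sdt=sdt,
        true_pt=pt,
        true_gt=g,
        u=spec.u,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(_MAX_REJECTION_ATTEMPTS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ConfigError("truncated-normal sampling failed; check capacity bounds")


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[ChangeDetectionTrial], list[RecallTrial], list[GroundTruth]]:
    """Generate a full two-session cohort plus its ground-truth sidecar.

    Deterministic given ``spec.seed``: participant i's trials come from
    an RNG stream seeded by (seed, i), so the cohort is reproducible
    even under parallel generation.
    """
    spec.validate()
    cd_trials: list[ChangeDetectionTrial] = []
    recall_trials: list[RecallTrial] = []
    truths: list[GroundTruth] = []
    width = max(2, len(str(spec.n_participants)))
    for i in range(spec.n_participants):
        pid = f"P{i + 1:0{width}d}"
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        true_k = _truncated_normal(
            rng, spec.capacity_mean, spec.capacity_sd, spec.capacity_min, spec.capacity_max
        )
        truth = _participant_truth(spec, true_k, pid)
        truths.append(truth)
        cd_trials.extend(
            simulate_change_detection(
                true_k, spec.set_size, spec.n_cd_trials, spec.u, rng, pid
            )
        )
        for condition in CONDITIONS:
            recall_trials.extend(
                simulate_recall(
                    truth.true_p[condition],
                    truth.true_sd_deg[condition],
                    truth.true_swap_rate[condition],
                    spec.n_recall_trials,
                    condition,
                    rng,
                    pid,
                    n_items=spec.recall_set_size,
                )
            )
    return cd_trials, recall_trials, truths


def nontarget_offsets(trials: list[RecallTrial]) -> np.ndarray:
    """Signed target-to-non-target distances, one row per trial."""
    return np.array(
        [[signed_error(nt, t.target_deg) for nt in t.nontargets_deg] for t in trials]
    )


def signed_errors(trials: list[RecallTrial]) -> np.ndarray:
    """Signed response-to-target errors for a list of recall trials."""
    return np.array([signed_error(t.response_deg, t.target_deg) for t in trials])
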