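"""End-to-end analysis: trials in, participant summaries and statistics out.

Per participant: Cowan's K from the change-detection session; per
precision condition, burn-in filtering, mixture-model MLE, and the
SDT/PT/GT indices. Across participants: a median split into capacity
groups, paired tests with Bayes factors within each group, mixed
ANOVAs (precision condition x capacity group) on SD and P, one-tailed
capacity-trade-off correlations, and the duration-per-item
critical-value block for the configured exposure.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from ._version import __version__ as _pkg_version
from .capacity import estimate_capacity, median_split
from .datamodel import (
    CONDITIONS,
    ChangeDetectionTrial,
    MixtureFit,
    ParticipantSummary,
    RecallTrial,
)
from .errors import EstimationError
from .mixture import FitConfig, MixtureModelFitter
from .simulate import nontarget_offsets, signed_errors
from .stats import mixed_anova, paired_t, pearson_one_tailed
from .critical_value import duration_per_item, predict_tradeoff
from .tradeoff import DEFAULT_BURN_IN, apply_burn_in, tradeoff_indices

__all__ = ["summarize_participant", "analyze_cohort", "fit_condition"]


def fit_condition(
    trials: list[RecallTrial],
    config: FitConfig | None = None,
    n_skip: int = DEFAULT_BURN_IN,
) -> MixtureFit:
    """Burn-in filter one condition block, then fit its mixture model."""
    kept = apply_burn_in(trials, n_skip)
    if not kept:
        raise EstimationError(
            f"no trials left after burn-in of {n_skip} (block of {len(trials)})"
        )
    config = config or FitConfig()
    fitter = MixtureModelFitter(config)
    errors = signed_errors(kept)
    if config.model == "swap":
        return fitter.fit(errors, nontarget_offsets(kept))
    return fitter.fit(errors)


def summarize_participant(
    cd_trials: list[ChangeDetectionTrial],
    recall_trials: list[RecallTrial],
    config: FitConfig | None = None,
    n_skip: int = DEFAULT_BURN_IN,
) -> tuple[ParticipantSummary, dict[str, MixtureFit]]:
    """Full single-participant analysis (group left 'unassigned').

    Returns the summary plus the raw per-condition fits.
    """
    if not cd_trials:
        raise EstimationError("change-detection session missing")
    pid = cd_trials[0].participant_id
    by_condition: dict[str, list[RecallTrial]] = defaultdict(list)
    for t in recall_trials:
        if t.participant_id != pid:
            raise EstimationError(
                f"recall trial for {t.participant_id!r} mixed into {pid!r}"
            )
        by_condition[t.condition].append(t)
    missing = [c for c in CONDITIONS if not by_condition[c]]
    if missing:
        raise EstimationError(f"participant {pid}: missing block(s) {missing}")
    cap = estimate_capacity(cd_trials)
    fits = {c: fit_condition(by_condition[c], config, n_skip) for c in CONDITIONS}
    sd_low = fits["low_precision"].sd_deg
    sd_high = fits["high_precision"].sd_deg
    p_low = fits["low_precision"].p_mem
    p_high = fits["high_precision"].p_mem
    sdt, pt, gt = tradeoff_indices(sd_low, sd_high, p_low, p_high)
    summary = ParticipantSummary(
        participant_id=pid,
        k=cap.k,
        group="unassigned",
        sd_low=sd_low,
        sd_high=sd_high,
        p_low=p_low,
        p_high=p_high,
        sdt=sdt,
        pt=pt,
        gt=gt,
    )
    return summary, fits


def analyze_cohort(
    cd_trials: list[ChangeDetectionTrial],
    recall_trials: list[RecallTrial],
    config: FitConfig | None = None,
    n_skip: int = DEFAULT_BURN_IN,
    exposure_ms: float = 500.0,
    recall_set_size: int = 4,
) -> dict:
    """Run the full two-session analysis and return the report dict."""
    cd_by_pid: dict[str, list[ChangeDetectionTrial]] = defaultdict(list)
    for t in cd_trials:
        cd_by_pid[t.participant_id].append(t)
    recall_by_pid: dict[str, list[RecallTrial]] = defaultdict(list)
    for t in recall_trials:
        recall_by_pid[t.participant_id].append(t)
    if set(recall_by_pid) - set(cd_by_pid):
        raise EstimationError(
            f"recall data without change-detection data for "
            f"{sorted(set(recall_by_pid) - set(cd_by_pid))}"
        )
    summaries: list[ParticipantSummary] = []
    for pid in sorted(cd_by_pid):
        summary, _ = summarize_participant(
            cd_by_pid[pid], recall_by_pid.get(pid, []), config, n_skip
        )
        summaries.append(summary)

    groups = median_split({s.participant_id: s.k for s in summaries})
    summaries = [
        ParticipantSummary(**{**s.to_dict(), "group": groups[s.participant_id]})
        for s in summaries
    ]
    df = pd.DataFrame([s.to_dict() for s in summaries])

    population = _population_level(df)
    individual = _individual_level(df)
    ratio = duration_per_item(exposure_ms, recall_set_size)
    report = {
        "package_version": _pkg_version,
        "n_participants": len(summaries),
        "participants": [s.to_dict() for s in summaries],
        "group_k_means": {
            g: float(df.loc[df.group == g, "k"].mean()) for g in ("low", "high")
        },
        "population_level": population,
        "individual_level": individual,
        "critical_value": {
            "exposure_ms": exposure_ms,
            "set_size": recall_set_size,
            "ms_per_item": ratio,
            "predicted_tradeoff": predict_tradeoff(ratio),
        },
    }
    return report


def _population_level(df: pd.DataFrame) -> dict:
    long = df.melt(
        id_vars=["participant_id", "group"],
        value_vars=["sd_low", "sd_high", "p_low", "p_high"],
        var_name="measure",
        value_name="value",
    )
    long["dv"] = long["measure"].str.split("_").str[0]
    long["condition"] = long["measure"].str.split("_").str[1].map(
        {"low": "low_precision", "high": "high_precision"}
    )
    out: dict = {"anova": {}, "paired": {}}
    for dv in ("sd", "p"):
        sub = long[long.dv == dv]
        effects = mixed_anova(
            sub, dv="value", within="condition", subject="participant_id", between="group"
        )
        out["anova"][dv] = [e.to_dict() for e in effects]
        out["paired"][dv] = {}
        for g in ("low", "high"):
            gdf = df[df.group == g]
            res = paired_t(gdf[f"{dv}_low"].to_numpy(), gdf[f"{dv}_high"].to_numpy())
            out["paired"][dv][g] = res.to_dict()
    return out


def _individual_level(df: pd.DataFrame) -> dict:
    out = {}
    for index in ("sdt", "pt", "gt"):
        res = pearson_one_tailed(
            df["k"].to_numpy(), df[index].to_numpy(), direction="positive"
        )
        out[f"k_vs_{index}"] = res.to_dict()
    return out
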