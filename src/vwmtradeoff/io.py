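"""CSV/JSON readers and writers for trial data, cohort specs and reports.

CSV is the canonical interchange (one row per trial); reports are JSON
with sorted keys and fixed float formatting so identical analyses give
byte-identical files.

Recall-trial columns:
    participant_id, condition, trial_index, target_deg,
    nontarget1_deg, nontarget2_deg, nontarget3_deg, response_deg
    (optional: offset_deg, score — recomputed if absent)

Change-detection columns:
    participant_id, set_size, changed, response_change
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .angles import circular_offset
from .datamodel import CONDITIONS, ChangeDetectionTrial, CohortSpec, RecallTrial
from .errors import ConfigError, SchemaError
from .tradeoff import score_response

RECALL_COLUMNS = [
    "participant_id",
    "condition",
    "trial_index",
    "target_deg",
    "nontarget1_deg",
    "nontarget2_deg",
    "nontarget3_deg",
    "response_deg",
]
CD_COLUMNS = ["participant_id", "set_size", "changed", "response_change"]

_DEG_COLUMNS = [
    "target_deg",
    "nontarget1_deg",
    "nontarget2_deg",
    "nontarget3_deg",
    "response_deg",
]


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def read_recall_trials(path) -> list[RecallTrial]:
    """Read continuous-report trials from CSV, validating every row."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, RECALL_COLUMNS, path)
    trials: list[RecallTrial] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        cond = str(row.condition)
        if cond not in CONDITIONS:
            raise SchemaError(
                f"{path}: row {i}, column 'condition': unknown label {cond!r}"
            )
        for col in _DEG_COLUMNS:
            v = float(getattr(row, col))
            if not 0.0 <= v < 360.0:
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: degree {v} outside [0, 360)"
                )
        offset = circular_offset(float(row.response_deg), float(row.target_deg))
        if hasattr(row, "score") and not pd.isna(row.score):
            score = int(row.score)
        else:
            score = score_response(offset, cond)
        trials.append(
            RecallTrial(
                participant_id=str(row.participant_id),
                condition=cond,
                trial_index=int(row.trial_index),
                target_deg=float(row.target_deg),
                nontargets_deg=(
                    float(row.nontarget1_deg),
                    float(row.nontarget2_deg),
                    float(row.nontarget3_deg),
                ),
                response_deg=float(row.response_deg),
                offset_deg=float(offset),
                score=score,
            )
        )
    return trials


def write_recall_trials(trials: list[RecallTrial], path) -> None:
    rows = [
        {
            "participant_id": t.participant_id,
            "condition": t.condition,
            "trial_index": t.trial_index,
            "target_deg": t.target_deg,
            "nontarget1_deg": t.nontargets_deg[0],
            "nontarget2_deg": t.nontargets_deg[1],
            "nontarget3_deg": t.nontargets_deg[2],
            "response_deg": t.response_deg,
            "offset_deg": t.offset_deg,
            "score": t.score,
        }
        for t in trials
    ]
    # 17 significant digits: write->read round-trips float64 losslessly
    pd.DataFrame(rows, columns=RECALL_COLUMNS + ["offset_deg", "score"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_change_detection_trials(path) -> list[ChangeDetectionTrial]:
    """Read single-probe change-detection trials from CSV."""
    df = pd.read_csv(path)
    _require_columns(df, CD_COLUMNS, path)
    trials: list[ChangeDetectionTrial] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        for col in ("changed", "response_change"):
            v = getattr(row, col)
            if not (isinstance(v, (bool,)) or v in (0, 1, "True", "False")):
                raise SchemaError(
                    f"{path}: row {i}, column {col!r}: not a boolean ({v!r})"
                )
        trials.append(
            ChangeDetectionTrial(
                participant_id=str(row.participant_id),
                set_size=int(row.set_size),
                changed=_as_bool(row.changed),
                response_change=_as_bool(row.response_change),
            )
        )
    return trials


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v == "True"
    return bool(v)


def write_change_detection_trials(trials: list[ChangeDetectionTrial], path) -> None:
    rows = [
        {
            "participant_id": t.participant_id,
            "set_size": t.set_size,
            "changed": t.changed,
            "response_change": t.response_change,
        }
        for t in trials
    ]
    pd.DataFrame(rows, columns=CD_COLUMNS).to_csv(path, index=False)


def read_cohort_spec(path) -> CohortSpec:
    """Load a cohort spec from YAML or JSON."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse spec ({exc})") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: cohort spec must be a mapping")
    return CohortSpec.from_dict(data)


def write_cohort_spec(spec: CohortSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))


def write_report(report: dict, path) -> None:
    """Write an analysis report as canonical JSON (sorted keys)."""
    Path(path).write_text(json.dumps(_round_floats(report), indent=2, sort_keys=True))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so report files are byte-reproducible."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj
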