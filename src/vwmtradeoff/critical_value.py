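"""Duration-per-item critical-value classifier for the trade-off literature.

Across published voluntary quality/quantity trade-off experiments, the
trade-off reliably appears once the exposure duration per memory item
reaches about 100 ms/item, and reliably fails to appear at 50 ms/item
or below. This module encodes that literature summary (25 experiments
from ten papers, packaged as ``data/table1.csv``) and a classifier:

    predict trade-off  iff  duration_ms / set_size >= 100 ms/item

For the open interval (50, 100) ms/item no published rule exists;
"no" is used, which matches the literature table's own predictability
judgements for its 60 and 50-100 ms/item rows (an interpretation, not a
reported fact). Rows listing several set sizes but a single observed
outcome are evaluated at their largest set size (smallest, most
demanding ratio); rows where the table splits the outcome by set size
are evaluated per sub-condition. The table's own "can predict" column
is kept for cross-validation but never consulted by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import SchemaError

__all__ = [
    "Table1Row",
    "ConsistencyReport",
    "duration_per_item",
    "predict_tradeoff",
    "tabulate_consistency",
    "load_table1",
]

CRITICAL_MS_PER_ITEM = 100.0


@dataclass(frozen=True)
class Table1Row:
    """One literature experiment: design parameters and observed outcome.

    ``observed_tradeoff`` has one entry per set size when the source
    splits the outcome by set-size sub-condition, else a single entry.
    """

    study: str
    experiment: str
    n: int
    task: str
    stimulus: str
    set_sizes: tuple[int, ...]
    duration_ms: float
    observed_tradeoff: tuple[bool, ...]
    can_predict: bool | None = None

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if not self.set_sizes:
            raise ValueError("set_sizes must be non-empty")
        if len(self.observed_tradeoff) not in (1, len(self.set_sizes)):
            raise ValueError(
                "observed_tradeoff must have one entry, or one per set size"
            )


@dataclass(frozen=True)
class ConsistencyReport:
    n_rows: int
    n_consistent: int
    rows: tuple[dict, ...]

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_consistent": self.n_consistent,
            "rows": list(self.rows),
        }


def duration_per_item(duration_ms: float, set_size: int) -> float:
    """Exposure duration per memory item, ms/item."""
    if duration_ms <= 0 or set_size <= 0:
        raise ValueError("duration_ms and set_size must be positive")
    return duration_ms / set_size


def predict_tradeoff(ms_per_item: float) -> str:
    """Predict whether a voluntary trade-off occurs at this ratio.

    "yes" iff the ratio reaches the 100 ms/item critical value.
    """
    if ms_per_item <= 0:
        raise ValueError("ms_per_item must be positive")
    return "yes" if ms_per_item >= CRITICAL_MS_PER_ITEM else "no"


def _row_evaluations(row: Table1Row) -> list[tuple[float, str, bool]]:
    """(ratio, prediction, observed) per evaluated sub-condition."""
    if len(row.observed_tradeoff) == len(row.set_sizes) and len(row.set_sizes) > 1:
        pairs = zip(row.set_sizes, row.observed_tradeoff)
    else:
        # single outcome: evaluate at the most demanding (largest) set size
        pairs = [(max(row.set_sizes), row.observed_tradeoff[0])]
    out = []
    for set_size, observed in pairs:
        ratio = duration_per_item(row.duration_ms, set_size)
        out.append((ratio, predict_tradeoff(ratio), bool(observed)))
    return out


def tabulate_consistency(rows: list[Table1Row]) -> ConsistencyReport:
    """Count experiments whose observed outcome matches the prediction.

    A row is consistent iff every evaluated sub-condition's prediction
    matches its observed outcome.
    """
    row_reports = []
    n_consistent = 0
    for row in rows:
        evals = _row_evaluations(row)
        consistent = all((pred == "yes") == obs for _, pred, obs in evals)
        n_consistent += consistent
        row_reports.append(
            {
                "study": row.study,
                "experiment": row.experiment,
                "ms_per_item": [e[0] for e in evals],
                "predicted": [e[1] for e in evals],
                "observed": ["yes" if e[2] else "no" for e in evals],
                "consistent": bool(consistent),
            }
        )
    return ConsistencyReport(
        n_rows=len(rows), n_consistent=n_consistent, rows=tuple(row_reports)
    )


def _parse_yes_no(value: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v not in ("yes", "no"):
        raise SchemaError(f"{where}: expected yes/no, got {value!r}")
    return v == "yes"


def load_table1(path=None) -> list[Table1Row]:
    """Load the packaged literature table (or a CSV in the same layout)."""
    if path is None:
        source = resources.files("vwmtradeoff").joinpath("data/table1.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = [
        "study",
        "experiment",
        "n",
        "task",
        "stimulus",
        "set_sizes",
        "duration_ms",
        "observed_tradeoff",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"literature table: missing column(s) {missing}")
    rows: list[Table1Row] = []
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        where = f"literature table row {i}"
        try:
            set_sizes = tuple(int(s) for s in str(rec.set_sizes).split(";"))
            observed = tuple(
                _parse_yes_no(o, where) for o in str(rec.observed_tradeoff).split(";")
            )
            can_predict = (
                _parse_yes_no(rec.can_predict, where)
                if hasattr(rec, "can_predict")
                else None
            )
            rows.append(
                Table1Row(
                    study=str(rec.study),
                    experiment=str(rec.experiment),
                    n=int(rec.n),
                    task=str(rec.task),
                    stimulus=str(rec.stimulus),
                    set_sizes=set_sizes,
                    duration_ms=float(rec.duration_ms),
                    observed_tradeoff=observed,
                    can_predict=can_predict,
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{where}: {exc}") from exc
    return rows
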