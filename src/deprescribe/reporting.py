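"""Result tables: base-case economics and per-100,000 event incidence.

Numbers in the tables are the raw ArmResult/CEAResult values; display
rounding (whole pounds, QALYs to 3 decimals) happens only at serialization
via :func:`format_base_case` / :func:`format_events`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import CEAResult
from .microsim import ArmResult, EVENT_CATEGORIES

__all__ = ["ReportTable", "build_event_table", "build_base_case_table",
           "format_base_case", "format_events"]

_CATEGORY_LABELS = {
    "hf": "Heart failure",
    "chd": "Coronary heart disease",
    "stroke_tia": "Stroke/Transient ischemic attack",
    "serious_ae": "Serious drug-related adverse event",
    "minor_ae": "Minor drug-related adverse event",
}


@dataclass
class ReportTable:
    """Event-incidence block, optionally with the base-case block attached."""

    events: pd.DataFrame
    base_case: pd.DataFrame | None = None


def build_event_table(arm_reduction: ArmResult, arm_usual: ArmResult) -> ReportTable:
    """Per-category event counts per 100,000 patients with the signed
    difference column (reduction minus usual care: positive means more
    events under medication reduction).  Both arms must come from the same
    run (same cohort and seed)."""
    if arm_reduction.run_key != arm_usual.run_key:
        raise ValueError(
            f"arms come from different runs: {arm_reduction.run_key} vs {arm_usual.run_key}"
        )
    rows = []
    for cat in EVENT_CATEGORIES:
        red = arm_reduction.events_per_100k[cat]
        usual = arm_usual.events_per_100k[cat]
        rows.append(
            {
                "event": _CATEGORY_LABELS[cat],
                "reduction": red,
                "usual_care": usual,
                "difference": red - usual,
            }
        )
    return ReportTable(events=pd.DataFrame(rows))


def build_base_case_table(
    usual: ArmResult, reduction: ArmResult, cea: CEAResult
) -> pd.DataFrame:
    """Two-strategy cost/QALY block with increments, ICER and label."""
    return pd.DataFrame(
        [
            {
                "strategy": "Reduced medication",
                "cost": reduction.mean_cost,
                "qalys": reduction.mean_qaly,
                "incremental_cost": None,
                "incremental_qalys": None,
                "icer": None,
                "label": None,
            },
            {
                "strategy": "Usual care",
                "cost": usual.mean_cost,
                "qalys": usual.mean_qaly,
                "incremental_cost": cea.delta_cost,
                "incremental_qalys": cea.delta_qaly,
                "icer": cea.icer,
                "label": cea.label,
            },
        ]
    )


def format_base_case(table: pd.DataFrame) -> pd.DataFrame:
    """Display formatting: whole pounds, QALYs to 3 decimals."""
    out = table.copy()
    for col in ("cost", "incremental_cost", "icer"):
        out[col] = out[col].map(lambda v: None if pd.isna(v) else f"{v:,.0f}")
    for col in ("qalys", "incremental_qalys"):
        out[col] = out[col].map(lambda v: None if pd.isna(v) else f"{v:.3f}")
    return out


def format_events(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in ("reduction", "usual_care", "difference"):
        out[col] = out[col].map(lambda v: f"{v:,.0f}")
    return out
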