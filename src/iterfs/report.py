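"""Report assembly: the classification-performance table and logs.

The main report mirrors the field's tabular convention: one row per
evaluated subset with a "median [low, high]" balanced-accuracy cell per
classifier, a 0/1 success flag, a phase label (``Phase_0_Full``,
``Phase_3_Final_Selected``, ``Phase_3_Final_Rejected``) and the
semicolon-joined feature list. Reporting is a pure function of the stored
framework result, so a report can be regenerated bit-identically.
"""

from __future__ import annotations

import json

import pandas as pd

from .evaluation import SubsetEvaluation
from .framework import FrameworkResult, PhaseRecord, SubsetEntry

__all__ = ["build_report", "result_to_json", "write_log"]

_CLASSIFIER_COLUMNS = {
    "random_forest": "RF_BA",
    "logistic": "LR_BA",
    "knn": "KNN_BA",
    "tree": "C50_BA",
    "svm_rbf": "SVM_BA",
}


def _row(entry: SubsetEntry, ev: SubsetEvaluation, phase_label: str) -> dict:
    label = entry.label.split("::", 1)[-1]
    row = {"Dataset": label, "Features": len(entry.features)}
    for classifier_id, est in ev.per_classifier.items():
        row[_CLASSIFIER_COLUMNS.get(classifier_id, f"{classifier_id}_BA")] = str(est)
    row["Classification_Success"] = int(ev.success)
    row["Phase"] = phase_label
    row["Features_Used"] = "; ".join(entry.features)
    return row


def build_report(result: FrameworkResult) -> pd.DataFrame:
    """Table-shaped summary: initial screen plus the final verification."""
    rows: list[dict] = []
    first_phase0 = next((r for r in result.trace if r.phase_id == "phase0"), None)
    if first_phase0 is not None:
        for entry, ev in first_phase0.evaluated:
            rows.append(_row(entry, ev, "Phase_0_Full"))
    last_phase3 = next((r for r in reversed(result.trace) if r.phase_id == "phase3"), None)
    if last_phase3 is not None:
        for entry, ev in last_phase3.evaluated:
            side = "Phase_3_Final_Selected" if entry.label.startswith("Selected::") else "Phase_3_Final_Rejected"
            rows.append(_row(entry, ev, side))
    return pd.DataFrame(rows)


def result_to_json(result: FrameworkResult) -> str:
    """Full-precision machine-readable result."""
    payload = {
        "selected": list(result.selected),
        "rejected": list(result.rejected),
        "warning": result.warning,
        "status": result.status,
        "n_outer_iterations": max((r.outer_iteration for r in result.trace), default=0),
        "evaluations": [
            {
                "phase": record.phase_id,
                "outer_iteration": record.outer_iteration,
                "subset": list(entry.features),
                "label": entry.label,
                "success": ev.success,
                "per_classifier": {
                    cid: {"median": est.median_ba, "ci_low": est.ci_low, "ci_high": est.ci_high}
                    for cid, est in ev.per_classifier.items()
                },
            }
            for record in result.trace
            for entry, ev in record.evaluated
        ],
    }
    return json.dumps(payload, indent=2)


def write_log(result: FrameworkResult, path: str) -> None:
    """Line-delimited evaluation log (one record per cache-miss evaluation)."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in result.evaluator.log_records:
            fh.write(json.dumps(record) + "\n")
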