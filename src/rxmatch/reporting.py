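"""Run-report assembly and rendering.

Conventions used in all printed tables: metrics at 5 decimals, percentages
at 2 decimals, alert budgets as integers. The JSON form carries the same
content for machine consumption; the text form is for humans.
"""

from __future__ import annotations

import json
from typing import Any, Sequence

from .ingest import CleaningReport
from .matcher import MatchStatus
from .metrics import (
    ErrorMatrix,
    alert_budget,
    build_error_matrix,
    compute_metrics,
    dedupe_pairs,
    frequency_report,
)
from .pipeline import CheckResult

__all__ = ["build_run_report", "render_text", "render_json"]

_CATEGORY_ORDER = [
    "DIFFERENT_INGREDIENT",
    "DIFFERENT_STRENGTH",
    "DIFFERENT_PACK_QUANTITY",
    "DIFFERENT_FORM",
    "OUTSIDE_RXNORM",
    "OTHER_QUALITATIVE",
]


def build_run_report(
    result: CheckResult,
    cleaning: CleaningReport | None = None,
    terminology: Any = None,
    top_k: int = 5,
) -> dict:
    """Aggregate a check result into a serializable report structure."""
    labeled = result.labeled
    unique = dedupe_pairs(labeled)
    matrix_total = build_error_matrix(labeled)
    matrix_unique = build_error_matrix(unique)
    metrics_total = compute_metrics(matrix_total, mode="total")
    metrics_unique = compute_metrics(matrix_unique, mode="unique")

    n_match = sum(1 for o in result.outcomes if o.status == MatchStatus.MATCH)
    report: dict = {
        "cleaning": None
        if cleaning is None
        else {
            "n_input": cleaning.n_input,
            "n_removed_signal_words": cleaning.n_removed_signal_words,
            "n_removed_missing_ndc": cleaning.n_removed_missing_ndc,
            "n_removed_invalid_ndc": cleaning.n_removed_invalid_ndc,
            "n_retained": cleaning.n_retained,
            "retained_percent": cleaning.retained_percent,
        },
        "n_pairs_checked": len(result.outcomes),
        "n_missing_rxcui": result.n_missing_rxcui,
        "n_match": n_match,
        "n_mismatch": sum(1 for o in result.outcomes if o.status == MatchStatus.MISMATCH),
        "category_counts": {
            c: result.category_counts().get(c, 0) for c in _CATEGORY_ORDER
        },
        "error_matrix": {
            "total": vars(matrix_total) | {"n": matrix_total.total},
            "unique": vars(matrix_unique) | {"n": matrix_unique.total},
        },
        "metrics": {
            "total": metrics_total.rounded() | {"n_pairs": metrics_total.n_pairs},
            "unique": metrics_unique.rounded() | {"n_pairs": metrics_unique.n_pairs},
        },
        "alert_budget": {
            "static": alert_budget(matrix_total),
            "learning": alert_budget(matrix_unique),
        },
    }
    if terminology is not None:
        report["top_matched_drugs"] = [
            {"rxcui": r, "name": name, "count": n, "percent": pct}
            for r, name, n, pct in frequency_report(
                result.outcomes, terminology, top=top_k, denominator=len(result.outcomes)
            )
        ]
    return report


def _fmt(value) -> str:
    if value is None:
        return "undefined"
    if isinstance(value, float):
        return f"{value:.5f}"
    return str(value)


def render_text(report: dict) -> str:
    lines: list[str] = ["# Medication selection double-check report", ""]
    if report.get("cleaning"):
        c = report["cleaning"]
        lines += [
            "## Cleaning funnel",
            f"input pairs:            {c['n_input']}",
            f"removed (signal words): {c['n_removed_signal_words']}",
            f"removed (missing NDC):  {c['n_removed_missing_ndc']}",
            f"removed (invalid NDC):  {c['n_removed_invalid_ndc']}",
            f"retained:               {c['n_retained']} ({c['retained_percent']:.2f}%)",
            "",
        ]
    lines += [
        "## Matching",
        f"pairs checked:     {report['n_pairs_checked']}",
        f"missing RxCUI:     {report['n_missing_rxcui']}",
        f"matching concepts: {report['n_match']}",
        f"mismatched:        {report['n_mismatch']}",
        "",
        "## Mismatch categories",
    ]
    for cat, n in report["category_counts"].items():
        lines.append(f"{cat:<26} {n}")
    lines.append("")
    for mode in ("total", "unique"):
        m = report["error_matrix"][mode]
        lines += [
            f"## Error matrix ({mode} pairs, n={m['n']})",
            f"TP={m['tp']}  FP={m['fp']}  FN={m['fn']}  TN={m['tn']}",
        ]
        met = report["metrics"][mode]
        for key in ("accuracy", "sensitivity", "false_positive_rate", "specificity", "precision", "f1"):
            lines.append(f"{key:<20} {_fmt(met[key])}")
        lines.append("")
    ab = report["alert_budget"]
    lines += [
        "## Alert budget (alerts per clinically significant alert)",
        f"static:   {_fmt(ab['static'])}",
        f"learning: {_fmt(ab['learning'])}",
        "",
    ]
    if report.get("top_matched_drugs"):
        lines.append("## Most frequently matched clinical drugs")
        for row in report["top_matched_drugs"]:
            lines.append(
                f"{row['rxcui']:<10} {row['name']:<60} {row['count']} ({row['percent']:.2f}%)"
            )
        lines.append("")
    return "\n".join(lines)


def render_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def outcome_rows(outcomes: Sequence) -> list[list[str]]:
    """Per-pair outcome table rows (header first) for delimited output."""
    rows = [["pair_id", "status", "category", "label", "rx_scds", "disp_scds", "note"]]
    for o in outcomes:
        rows.append(
            [
                o.pair_id,
                o.status.value,
                o.category.value if o.category else "",
                o.label.value if o.label else "",
                "|".join(sorted(o.rx_scds)),
                "|".join(sorted(o.disp_scds)),
                o.note,
            ]
        )
    return rows
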