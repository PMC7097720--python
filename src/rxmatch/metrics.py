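"""Error matrices, performance metrics and alert-burden summaries.

Two evaluation modes mirror two alerting policies:

- **total** ("static"): every occurrence of a mismatched NDC pair fires an
  alert, so metrics are computed over all labeled pairs;
- **unique** ("learning"): once a specific ordered (prescribed NDC,
  dispensed NDC) pair has been adjudicated, repeats are suppressed, so
  metrics are computed over distinct ordered NDC pairs.

The alert budget — alerts issued per clinically significant alert — is the
quantity pharmacists experience as alert burden.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .matcher import Label, MatchOutcome, MatchStatus

__all__ = [
    "ErrorMatrix",
    "MetricsReport",
    "dedupe_pairs",
    "build_error_matrix",
    "compute_metrics",
    "alert_budget",
    "frequency_report",
]


@dataclass(frozen=True)
class ErrorMatrix:
    """Confusion-matrix counts over labeled pair outcomes."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("error-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


@dataclass(frozen=True)
class MetricsReport:
    """The six performance metrics, full precision; ``None`` marks an
    undefined value (zero denominator). ``rounded()`` gives the 5-decimal
    presentation used in printed tables."""

    accuracy: float | None
    sensitivity: float | None
    false_positive_rate: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    n_pairs: int
    mode: str  # "total" | "unique"

    def rounded(self, ndigits: int = 5) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in {
                "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "false_positive_rate": self.false_positive_rate,
                "specificity": self.specificity,
                "precision": self.precision,
                "f1": self.f1,
            }.items()
        }


def dedupe_pairs(outcomes: Iterable[MatchOutcome]) -> list[MatchOutcome]:
    """Keep the first occurrence of each ordered (rx_ndc, disp_ndc) pair.

    The key is the ordered pair of normalized NDCs — (A, B) and (B, A) are
    distinct dispensing situations. Outcomes lacking a normalized NDC on
    either side (unresolvable codes) are keyed by their raw absence marker
    and deduplicated the same way.
    """
    seen: set[tuple[str | None, str | None]] = set()
    out: list[MatchOutcome] = []
    for o in outcomes:
        key = (o.rx_ndc, o.disp_ndc)
        if key in seen:
            continue
        seen.add(key)
        out.append(o)
    return out


def build_error_matrix(outcomes: Iterable[MatchOutcome]) -> ErrorMatrix:
    """Count labels; unlabeled (missing-RxCUI) outcomes are excluded."""
    counts = Counter(o.label for o in outcomes if o.label is not None)
    return ErrorMatrix(
        tp=counts.get(Label.TP, 0),
        fp=counts.get(Label.FP, 0),
        fn=counts.get(Label.FN, 0),
        tn=counts.get(Label.TN, 0),
    )


def compute_metrics(m: ErrorMatrix, mode: str = "total") -> MetricsReport:
    """Derive the six metrics from an error matrix.

    accuracy = (tp+tn)/n, sensitivity = tp/(tp+fn), fpr = fp/(fp+tn),
    specificity = tn/(fp+tn), precision = tp/(tp+fp),
    f1 = 2·precision·sensitivity/(precision+sensitivity); each is ``None``
    when its denominator is zero.
    """
    precision = _ratio(m.tp, m.tp + m.fp)
    sensitivity = _ratio(m.tp, m.tp + m.fn)
    f1 = None
    if precision is not None and sensitivity is not None and (precision + sensitivity) > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=_ratio(m.tp + m.tn, m.total),
        sensitivity=sensitivity,
        false_positive_rate=_ratio(m.fp, m.fp + m.tn),
        specificity=_ratio(m.tn, m.fp + m.tn),
        precision=precision,
        f1=f1,
        n_pairs=m.total,
        mode=mode,
    )


def alert_budget(m: ErrorMatrix) -> int | None:
    """Alerts fired per clinically significant alert: (tp+fp)/tp, half-up.

    ``None`` when no true positives exist (the ratio is undefined).
    Half-up rounding keeps x.5 budgets on the conservative (higher) side.
    """
    if m.tp == 0:
        return None
    return int(math.floor(Fraction(m.tp + m.fp, m.tp) + Fraction(1, 2)))


def frequency_report(
    outcomes: Sequence[MatchOutcome],
    terminology,
    top: int = 5,
    denominator: int | None = None,
) -> list[tuple[str, str, int, float]]:
    """Most frequently matched clinical drugs: (rxcui, name, count, percent).

    Counts the agreed clinical concept of each matched pair (smallest rxcui
    of the intersection when a pair resolves to several). Percent is of all
    analyzed pairs (``denominator``, defaulting to ``len(outcomes)``),
    rounded to 2 decimals. Descending by count, ties by rxcui ascending.
    """
    den = denominator if denominator is not None else len(outcomes)
    counts: Counter[str] = Counter()
    for o in outcomes:
        if o.status == MatchStatus.MATCH:
            common = o.rx_scds & o.disp_scds
            if common:
                counts[min(common)] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    out = []
    for rxcui, n in ranked:
        try:
            name = terminology.concept(rxcui).name
        except Exception:
            name = ""
        pct = round(100.0 * n / den, 2) if den else 0.0
        out.append((rxcui, name, n, pct))
    return out
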