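"""End-to-end check: clean → resolve → match → classify → label.

`run_check` is the library entry point the CLI wraps. Resolution failures
of any kind on a side (invalid NDC, NDC unknown to the terminology, a
concept with no clinical-drug relation) yield an empty clinical-concept
set for that side, which routes the pair to the missing-RxCUI stream —
those pairs are reported but excluded from the error matrix, the same way
unresolvable codes must be excluded from a deployed check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ResolutionError, ValidationError
from .ingest import RecordPair
from .matcher import (
    MatchOutcome,
    MatchStatus,
    classify_mismatch,
    label_outcome,
    match_pair,
)
from .ndc import normalize_ndc
from .terminology import ScdAttributes, TerminologyBackend

logger = logging.getLogger(__name__)

__all__ = ["resolve_ndc", "evaluate_pair", "run_check", "CheckResult"]


def resolve_ndc(
    raw_ndc: str, terminology: TerminologyBackend
) -> tuple[frozenset[str], str | None, str]:
    """Resolve a raw NDC to clinical-concept rxcuis.

    Returns ``(scd_set, normalized_ndc_or_None, note)``; an empty set with a
    reason note when the code cannot reach a clinical concept.
    """
    try:
        ndc = normalize_ndc(raw_ndc)
    except ValidationError as exc:
        return frozenset(), None, f"invalid_ndc:{exc.code}"
    concept = terminology.ndc_to_concept(ndc)
    if concept is None:
        return frozenset(), ndc.normalized, "no_rxcui"
    try:
        return terminology.resolve_to_scds(concept), ndc.normalized, ""
    except ResolutionError:
        logger.info("NDC %s: concept %s unresolvable to clinical level", ndc.normalized, concept.rxcui)
        return frozenset(), ndc.normalized, "unresolvable_concept"


def _attrs_for(scds: frozenset[str], terminology: TerminologyBackend) -> list[ScdAttributes]:
    return [terminology.get_scd_attributes(r) for r in sorted(scds)]


def evaluate_pair(
    pair: RecordPair,
    terminology: TerminologyBackend,
    truly_equivalent: bool | None = None,
) -> MatchOutcome:
    """Resolve, match, classify and label one record pair."""
    rx_scds, rx_ndc, rx_note = resolve_ndc(pair.rx_ndc_raw, terminology)
    disp_scds, disp_ndc, disp_note = resolve_ndc(pair.disp_ndc_raw, terminology)
    status = match_pair(rx_scds, disp_scds)
    outcome = MatchOutcome(
        pair_id=pair.pair_id,
        status=status,
        rx_scds=rx_scds,
        disp_scds=disp_scds,
        rx_ndc=rx_ndc,
        disp_ndc=disp_ndc,
        note=";".join(n for n in (rx_note, disp_note) if n),
    )
    if status == MatchStatus.MISMATCH:
        outcome.category = classify_mismatch(
            _attrs_for(rx_scds, terminology), _attrs_for(disp_scds, terminology)
        )
    if status != MatchStatus.MISSING_RXCUI:
        outcome.label = label_outcome(outcome, truly_equivalent)
    return outcome


@dataclass
class CheckResult:
    outcomes: list[MatchOutcome] = field(default_factory=list)

    @property
    def n_missing_rxcui(self) -> int:
        return sum(1 for o in self.outcomes if o.status == MatchStatus.MISSING_RXCUI)

    @property
    def labeled(self) -> list[MatchOutcome]:
        return [o for o in self.outcomes if o.label is not None]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for o in self.outcomes:
            if o.category is not None:
                counts[o.category.value] = counts.get(o.category.value, 0) + 1
        return counts


def run_check(
    pairs: Iterable[RecordPair],
    terminology: TerminologyBackend,
    equivalence_truth: Mapping[str, bool] | None = None,
) -> CheckResult:
    """Evaluate a cleaned stream of record pairs.

    ``equivalence_truth`` optionally maps pair_id → whether the two products
    are truly equivalent (synthetic ground truth; enables FN labeling).
    """
    result = CheckResult()
    for pair in pairs:
        truth = None if equivalence_truth is None else equivalence_truth.get(pair.pair_id)
        result.outcomes.append(evaluate_pair(pair, terminology, truth))
    return result
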