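"""Clinical-drug matching, mismatch taxonomy, and error-matrix labeling.

A pair matches when the clinical-level concept sets resolved for its two
NDCs intersect. Mismatches are classified by a severity-ordered cascade —
the most harmful difference names the category — and mapped to confusion-
matrix labels: ingredient or strength differences are the clinically
significant alerts (TP); quantity, form, qualitative and outside-scope
differences are nuisance alerts (FP); matches are TN unless synthetic
ground truth marks the pair as truly non-equivalent (FN — a terminology
mapping defect, the one error class the check cannot see on its own).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import AttributeUnavailable
from .terminology import ScdAttributes, canonical_unit

__all__ = [
    "MatchStatus",
    "MismatchCategory",
    "Label",
    "MatchOutcome",
    "match_pair",
    "classify_mismatch",
    "label_outcome",
]


class MatchStatus(str, Enum):
    MISSING_RXCUI = "MISSING_RXCUI"
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"


class MismatchCategory(str, Enum):
    DIFFERENT_INGREDIENT = "DIFFERENT_INGREDIENT"
    DIFFERENT_STRENGTH = "DIFFERENT_STRENGTH"
    DIFFERENT_PACK_QUANTITY = "DIFFERENT_PACK_QUANTITY"
    DIFFERENT_FORM = "DIFFERENT_FORM"
    OUTSIDE_RXNORM = "OUTSIDE_RXNORM"
    OTHER_QUALITATIVE = "OTHER_QUALITATIVE"


class Label(str, Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    TN = "TN"


#: Categories considered clinically significant (alert-worthy) mismatches.
SIGNIFICANT_CATEGORIES = frozenset(
    {MismatchCategory.DIFFERENT_INGREDIENT, MismatchCategory.DIFFERENT_STRENGTH}
)


@dataclass
class MatchOutcome:
    """Per-pair result of the automated double-check."""

    pair_id: str
    status: MatchStatus
    rx_scds: frozenset[str] = frozenset()
    disp_scds: frozenset[str] = frozenset()
    category: MismatchCategory | None = None
    label: Label | None = None
    rx_ndc: str | None = None  # normalized, for unique-pair deduplication
    disp_ndc: str | None = None
    note: str = ""


def match_pair(rx_scds: frozenset[str], disp_scds: frozenset[str]) -> MatchStatus:
    """Compare the two resolved clinical-concept sets.

    Empty set on either side means the NDC never reached a clinical concept
    (unknown NDC, unresolvable term type, or invalid code) — the pair cannot
    be checked. A non-empty intersection counts as a match: a brand NDC and
    its generic resolve to the same clinical drug.
    """
    if not rx_scds or not disp_scds:
        return MatchStatus.MISSING_RXCUI
    if rx_scds & disp_scds:
        return MatchStatus.MATCH
    return MatchStatus.MISMATCH


def _representative(attrs: Iterable[ScdAttributes]) -> ScdAttributes:
    """Deterministic pick when a side resolved to several clinical concepts:
    the attributes of the lexicographically smallest rxcui."""
    chosen = min(attrs, key=lambda a: a.scd_rxcui, default=None)
    if chosen is None:
        raise AttributeUnavailable("no attributes supplied for a mismatch side")
    return chosen


def classify_mismatch(
    attrs_rx: Sequence[ScdAttributes], attrs_disp: Sequence[ScdAttributes]
) -> MismatchCategory:
    """Name a mismatch by its most harmful difference (first hit wins).

    Cascade: outside curated scope → ingredient → strength → pack quantity
    → dose form → other qualitative distinction. Outside-scope screens
    first because uncurated concepts carry no attributes to compare;
    strength equality is exact (value, canonicalized unit) per ingredient —
    no unit conversion is attempted.
    """
    if any(not a.curated for a in list(attrs_rx) + list(attrs_disp)):
        return MismatchCategory.OUTSIDE_RXNORM
    rx = _representative(attrs_rx)
    disp = _representative(attrs_disp)
    if not rx.ingredients or not disp.ingredients:
        raise AttributeUnavailable(
            f"curated concept without ingredients: {rx.scd_rxcui} / {disp.scd_rxcui}"
        )
    if rx.ingredients != disp.ingredients:
        return MismatchCategory.DIFFERENT_INGREDIENT
    if rx.strength_key() != disp.strength_key():
        return MismatchCategory.DIFFERENT_STRENGTH
    if rx.pack_quantity != disp.pack_quantity:
        return MismatchCategory.DIFFERENT_PACK_QUANTITY
    if canonical_unit(rx.dose_form) != canonical_unit(disp.dose_form):
        return MismatchCategory.DIFFERENT_FORM
    return MismatchCategory.OTHER_QUALITATIVE


def label_outcome(outcome: MatchOutcome, truly_equivalent: bool | None = None) -> Label | None:
    """Assign the confusion-matrix label for a matched or mismatched pair.

    ``truly_equivalent`` is external ground truth (available only in
    synthetic runs): a MATCH over drugs known to be non-equivalent is a
    false negative. Missing-RxCUI pairs carry no label.
    """
    if outcome.status == MatchStatus.MISSING_RXCUI:
        return None
    if outcome.status == MatchStatus.MATCH:
        if truly_equivalent is False:
            return Label.FN
        return Label.TN
    if outcome.category is None:
        raise ValueError("MISMATCH outcome must carry a category before labeling")
    return Label.TP if outcome.category in SIGNIFICANT_CATEGORIES else Label.FP
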