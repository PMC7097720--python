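"""National Drug Code (NDC) validation and 11-digit normalization.

US NDCs are printed in three hyphenated segments — labeler, product,
package — in one of four dialects: 4-4-2, 5-3-2, 5-4-1 (the FDA 10-digit
forms) or the already-normalized 5-4-2. Billing and terminology systems use
the 11-digit form obtained by zero-padding the short segment of a 10-digit
code. An unhyphenated 10-digit string is ambiguous (the dropped zero's
segment is unknowable) and is rejected unless the caller states the dialect.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["NdcCode", "normalize_ndc", "TEN_DIGIT_DIALECTS"]

#: Segment lengths of the three 10-digit dialects, keyed by their usual name.
TEN_DIGIT_DIALECTS = {
    "4-4-2": (4, 4, 2),
    "5-3-2": (5, 3, 2),
    "5-4-1": (5, 4, 1),
}

_SEGMENT_TARGET = (5, 4, 2)


@dataclass(frozen=True)
class NdcCode:
    """A validated NDC in normalized 11-digit 5-4-2 form."""

    raw: str
    labeler: str
    product: str
    package: str

    @property
    def normalized(self) -> str:
        """11-digit concatenation ``labeler + product + package``."""
        return self.labeler + self.product + self.package

    @property
    def hyphenated(self) -> str:
        """``LLLLL-PPPP-KK`` presentation form."""
        return f"{self.labeler}-{self.product}-{self.package}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.normalized


def _pad_segments(raw: str, segments: list[str]) -> NdcCode:
    lengths = tuple(len(s) for s in segments)
    if lengths != _SEGMENT_TARGET and lengths not in TEN_DIGIT_DIALECTS.values():
        raise ValidationError(
            f"NDC {raw!r}: segment lengths {lengths} match no standard dialect "
            "(5-4-2, 4-4-2, 5-3-2, 5-4-1)",
            code="segment_lengths",
        )
    padded = [s.zfill(w) for s, w in zip(segments, _SEGMENT_TARGET)]
    return NdcCode(raw=raw, labeler=padded[0], product=padded[1], package=padded[2])


def normalize_ndc(raw: str, ten_digit_dialect: str | None = None) -> NdcCode:
    """Validate ``raw`` and normalize it to the 11-digit 5-4-2 form.

    Parameters
    ----------
    raw:
        The code as received: hyphenated in any standard dialect, or an
        unhyphenated 11-digit string. Leading/trailing whitespace is trimmed.
    ten_digit_dialect:
        Optional dialect name (``"4-4-2"``, ``"5-3-2"`` or ``"5-4-1"``) to
        assume for *unhyphenated* 10-digit inputs, which are otherwise
        rejected as ambiguous.

    Raises
    ------
    ValidationError
        For non-digit content, wrong segment counts or lengths, internal
        whitespace, or ambiguous/invalid overall length.
    """
    text = raw.strip()
    if not text:
        raise ValidationError("empty NDC", code="empty")
    if any(c.isspace() for c in text):
        raise ValidationError(f"NDC {raw!r}: internal whitespace", code="internal_space")

    if "-" in text:
        segments = text.split("-")
        if len(segments) != 3:
            raise ValidationError(
                f"NDC {raw!r}: expected 3 hyphenated segments, got {len(segments)}",
                code="segment_count",
            )
        if not all(s.isdigit() for s in segments):
            raise ValidationError(f"NDC {raw!r}: non-digit content", code="non_digit")
        return _pad_segments(raw, segments)

    if not text.isdigit():
        raise ValidationError(f"NDC {raw!r}: non-digit content", code="non_digit")
    if len(text) == 11:
        return NdcCode(raw=raw, labeler=text[:5], product=text[5:9], package=text[9:])
    if len(text) == 10:
        if ten_digit_dialect is None:
            raise ValidationError(
                f"NDC {raw!r}: unhyphenated 10-digit code is ambiguous; "
                "supply a dialect to disambiguate",
                code="ambiguous_10_digit",
            )
        try:
            lengths = TEN_DIGIT_DIALECTS[ten_digit_dialect]
        except KeyError:
            raise ValidationError(
                f"unknown 10-digit dialect {ten_digit_dialect!r}", code="segment_lengths"
            ) from None
        a, b, _ = lengths
        return _pad_segments(raw, [text[:a], text[a : a + b], text[a + b :]])
    raise ValidationError(
        f"NDC {raw!r}: length {len(text)} outside {{10 hyphenated, 11}}", code="length"
    )
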