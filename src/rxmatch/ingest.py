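"""Reading and cleaning paired e-prescription / dispensing records.

Cleaning removes pairs flagged by signal words ("duplicate", "cancel",
"wrong", "denied" — annotations pharmacy staff leave on invalid records),
pairs missing an NDC on either side, and — in strict mode only — pairs
whose NDC fails normalization. By default malformed NDCs flow through to
the matcher, where they land in the missing-RxCUI stream: real streams
contain vendor-invented codes (diabetic supplies, compounds) that are valid
records but will never resolve in the terminology.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import FormatError, ValidationError
from .ndc import normalize_ndc

logger = logging.getLogger(__name__)

__all__ = ["RecordPair", "CleaningReport", "load_pairs", "clean_pairs", "DEFAULT_SIGNAL_WORDS"]

DEFAULT_SIGNAL_WORDS = frozenset({"duplicate", "cancel", "wrong", "denied"})

REQUIRED_COLUMNS = ("rx_name", "rx_ndc", "disp_name", "disp_ndc")


@dataclass(frozen=True)
class RecordPair:
    """One e-prescription / dispensing event, both sides as received."""

    pair_id: str
    rx_name: str
    rx_ndc_raw: str
    disp_name: str
    disp_ndc_raw: str
    prescriber_id: str | None = None


@dataclass
class CleaningReport:
    """Funnel tallies; removals plus retained always sum to the input count."""

    n_input: int = 0
    n_removed_signal_words: int = 0
    n_removed_missing_ndc: int = 0
    n_removed_invalid_ndc: int = 0
    n_retained: int = 0

    @property
    def retained_percent(self) -> float:
        """Share of input pairs surviving the funnel, in percent (2 decimals)."""
        if self.n_input == 0:
            return 0.0
        return round(100.0 * self.n_retained / self.n_input, 2)

    def check(self) -> None:
        total = (
            self.n_removed_signal_words
            + self.n_removed_missing_ndc
            + self.n_removed_invalid_ndc
            + self.n_retained
        )
        assert total == self.n_input, "funnel counts must sum to the input count"


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_pairs(path: str | Path, delimiter: str | None = None) -> Iterator[RecordPair]:
    """Yield record pairs from a delimited text file, in file order.

    The header must contain ``rx_name, rx_ndc, disp_name, disp_ndc``;
    ``pair_id`` and ``prescriber_id`` are optional (missing pair ids fall
    back to the 1-based row number). Comma or tab delimiting is
    auto-detected from the header unless given. Malformed rows are skipped
    with a logged reason; a missing required column raises
    :class:`~rxmatch.errors.FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        fh.seek(0)
        delim = delimiter or _sniff_delimiter(first)
        reader = csv.DictReader(fh, delimiter=delim)
        missing = [c for c in REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        for i, row in enumerate(reader, start=1):
            if row.get(None):
                logger.warning("row %d: extra fields, skipped (reason=extra_fields)", i)
                continue
            values = {k: (v or "") for k, v in row.items() if k is not None}
            yield RecordPair(
                pair_id=values.get("pair_id") or str(i),
                rx_name=values.get("rx_name", ""),
                rx_ndc_raw=values.get("rx_ndc", ""),
                disp_name=values.get("disp_name", ""),
                disp_ndc_raw=values.get("disp_ndc", ""),
                prescriber_id=values.get("prescriber_id") or None,
            )


def _has_signal_word(pair: RecordPair, words: frozenset[str]) -> bool:
    text = f"{pair.rx_name}\n{pair.disp_name}".casefold()
    return any(w.casefold() in text for w in words)


def clean_pairs(
    pairs: Iterable[RecordPair],
    signal_words: Iterable[str] = DEFAULT_SIGNAL_WORDS,
    strict_ndc: bool = False,
) -> tuple[list[RecordPair], CleaningReport]:
    """Apply the cleaning funnel; returns retained pairs (input order) + tallies.

    Signal-word matching is a case-insensitive substring test over both
    free-text name fields, so inflections ("CANCELLED", "duplicated") are
    caught. With ``strict_ndc`` pairs whose NDC fails normalization are
    dropped here instead of flowing to the missing-RxCUI stream.
    """
    words = frozenset(signal_words)
    if not words:
        raise ValueError("signal_words must be non-empty")
    report = CleaningReport()
    kept: list[RecordPair] = []
    for pair in pairs:
        report.n_input += 1
        if _has_signal_word(pair, words):
            report.n_removed_signal_words += 1
            logger.debug("pair %s removed (reason=signal_word)", pair.pair_id)
            continue
        if not pair.rx_ndc_raw.strip() or not pair.disp_ndc_raw.strip():
            report.n_removed_missing_ndc += 1
            logger.debug("pair %s removed (reason=missing_ndc)", pair.pair_id)
            continue
        if strict_ndc:
            try:
                normalize_ndc(pair.rx_ndc_raw)
                normalize_ndc(pair.disp_ndc_raw)
            except ValidationError as exc:
                report.n_removed_invalid_ndc += 1
                logger.debug("pair %s removed (reason=invalid_ndc: %s)", pair.pair_id, exc.code)
                continue
        report.n_retained += 1
        kept.append(pair)
    report.check()
    return kept, report


def write_pairs(pairs: Sequence[RecordPair], path: str | Path, delimiter: str = ",") -> None:
    """Write pairs back out in the ingest format (used by the generator)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["pair_id", "rx_name", "rx_ndc", "disp_name", "disp_ndc", "prescriber_id"])
        for p in pairs:
            writer.writerow(
                [p.pair_id, p.rx_name, p.rx_ndc_raw, p.disp_name, p.disp_ndc_raw, p.prescriber_id or ""]
            )
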