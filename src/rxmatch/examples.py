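"""Bundled worked example: a small real-drug snapshot and record stream.

Encodes the canonical demonstration cases of the method using real RxNorm
identifiers: a diltiazem-prescribed / Protonix-dispensed selection error
(the prescribed NDC resolves directly to an SCD, the dispensed NDC resolves
via an SBD), plus one exemplar record pair for each row of the mismatch
taxonomy — same medication, different ingredient, different strength,
different pack quantity, different dose form, concept outside the curated
terminology, and a qualitative (osmotic release) distinction.

NDCs for the taxonomy exemplars are synthetic (reserved labeler ``99999``);
the two NDCs of the diltiazem/Protonix case are the real printed codes.
"""

from __future__ import annotations

import pandas as pd

from .ingest import RecordPair
from .matcher import MatchStatus, MismatchCategory
from .terminology import FixtureTerminology

__all__ = ["worked_example", "worked_example_frames"]

# rxcui, tty, name, status, remapped_to, curated
_CONCEPTS = [
    ("830845", "SCD", "24 HR diltiazem hydrochloride 180 mg extended release oral capsule", "active", "", "true"),
    ("314200", "SCD", "pantoprazole 40 mg delayed release oral tablet", "active", "", "true"),
    ("284400", "SBD", "Protonix 40 mg delayed release oral tablet", "active", "", "true"),
    ("751620", "SCD", "Bystolic 2.5 mg oral tablet", "active", "", "true"),
    ("313585", "SCD", "24 HR venlafaxine 75 mg extended release oral capsule", "active", "", "true"),
    ("966225", "SCD", "Levothyroxine sodium 0.15 mg oral tablet", "active", "", "true"),
    ("861700", "SCD", "Amylases 82000 UNT/endopeptidases 51000 UNT/lipase 15000 UNT delayed release oral capsule", "active", "", "true"),
    ("1595476", "SCD", "Amylases 84000 UNT/endopeptidases 63000 UNT/lipase 20000 UNT delayed release oral capsule", "active", "", "true"),
    ("905100", "GPCK", "12 (risedronate sodium 35 mg oral tablet) pack", "active", "", "true"),
    ("905092", "GPCK", "4 (risedronate sodium 35 mg oral tablet) pack", "active", "", "true"),
    ("198334", "SCD", "risedronate sodium 35 mg oral tablet", "active", "", "true"),
    ("835840", "SCD", "testosterone cypionate 200 mg/mL injectable solution", "active", "", "true"),
    ("2047882", "SCD", "1 mL testosterone cypionate 200 mg/mL injection", "active", "", "true"),
    ("1371671", "OTHER", "Proprietary compound A", "active", "", "false"),
    ("1371861", "OTHER", "Proprietary compound B", "active", "", "false"),
    ("198034", "SCD", "24 HR nifedipine 30 mg extended release oral tablet", "active", "", "true"),
    ("1812011", "SCD", "Osmotic 24 HR nifedipine 30 mg extended release oral tablet", "active", "", "true"),
]

# ndc11, rxcui, ndc_status
_NDC_MAP = [
    ("00093511798", "830845", "active"),   # 00093-5117-98
    ("00008084181", "284400", "active"),   # 00008-0841-81
    ("99999000101", "751620", "active"),   # one-to-many: two NDCs, one concept
    ("99999000102", "751620", "active"),
    ("99999000201", "313585", "active"),
    ("99999000301", "966225", "active"),
    ("99999000401", "861700", "active"),
    ("99999000501", "1595476", "active"),
    ("99999000601", "905100", "active"),
    ("99999000701", "905092", "active"),
    ("99999000801", "835840", "active"),
    ("99999000901", "2047882", "active"),
    ("99999001001", "1371671", "active"),
    ("99999001101", "1371861", "active"),
    ("99999001201", "198034", "active"),
    ("99999001301", "1812011", "active"),
]

# rxcui, ingredient, strength_value, strength_unit, dose_form, pack_quantity, qualifiers
_ATTRS = [
    ("830845", "diltiazem hydrochloride", "180", "mg", "extended release oral capsule", "", "24 hr"),
    ("314200", "pantoprazole", "40", "mg", "delayed release oral tablet", "", ""),
    ("751620", "nebivolol", "2.5", "mg", "oral tablet", "", ""),
    ("313585", "venlafaxine", "75", "mg", "extended release oral capsule", "", "24 hr"),
    ("966225", "levothyroxine sodium", "0.15", "mg", "oral tablet", "", ""),
    ("861700", "amylases", "82000", "UNT", "delayed release oral capsule", "", ""),
    ("861700", "endopeptidases", "51000", "UNT", "delayed release oral capsule", "", ""),
    ("861700", "lipase", "15000", "UNT", "delayed release oral capsule", "", ""),
    ("1595476", "amylases", "84000", "UNT", "delayed release oral capsule", "", ""),
    ("1595476", "endopeptidases", "63000", "UNT", "delayed release oral capsule", "", ""),
    ("1595476", "lipase", "20000", "UNT", "delayed release oral capsule", "", ""),
    ("905100", "risedronate sodium", "35", "mg", "oral tablet", "12", ""),
    ("905092", "risedronate sodium", "35", "mg", "oral tablet", "4", ""),
    ("198334", "risedronate sodium", "35", "mg", "oral tablet", "", ""),
    ("835840", "testosterone cypionate", "200", "mg/mL", "injectable solution", "", ""),
    ("2047882", "testosterone cypionate", "200", "mg/mL", "injection", "", ""),
    ("198034", "nifedipine", "30", "mg", "extended release oral tablet", "", "24 hr"),
    ("1812011", "nifedipine", "30", "mg", "extended release oral tablet", "", "24 hr|osmotic"),
]

# rxcui, related_rxcui, relation
_RELATED = [
    ("284400", "314200", "tradename_of"),
    ("905100", "198334", "contains"),
    ("905092", "198334", "contains"),
]

_PAIRS = [
    RecordPair("fig-selection-error", "Diltiazem HCl ER coated beads 180 mg", "00093-5117-98",
               "Protonix 40 mg oral tablet", "00008-0841-81"),
    RecordPair("same-medication", "Bystolic 2.5 mg oral tablet", "99999-0001-01",
               "Bystolic 2.5 mg oral tablet", "99999-0001-02"),
    RecordPair("different-ingredient", "24 HR venlafaxine 75 mg extended release oral capsule",
               "99999-0002-01", "Levothyroxine sodium 0.15 mg oral tablet", "99999-0003-01"),
    RecordPair("different-strength",
               "Amylases 82000 UNT/endopeptidases 51000 UNT/lipase 15000 UNT delayed release oral capsule",
               "99999-0004-01",
               "Amylases 84000 UNT/endopeptidases 63000 UNT/lipase 20000 UNT delayed release oral capsule",
               "99999-0005-01"),
    RecordPair("different-pack-quantity", "12 (risedronate sodium 35 mg oral tablet) pack",
               "99999-0006-01", "4 (risedronate sodium 35 mg oral tablet) pack", "99999-0007-01"),
    RecordPair("different-form", "testosterone cypionate 200 mg/mL injectable solution",
               "99999-0008-01", "1 mL testosterone cypionate 200 mg/mL injection", "99999-0009-01"),
    RecordPair("outside-terminology", "Proprietary compound A", "99999-0010-01",
               "Proprietary compound B", "99999-0011-01"),
    RecordPair("other-qualitative", "24 HR nifedipine 30 mg extended release oral tablet",
               "99999-0012-01", "Osmotic 24 HR nifedipine 30 mg extended release oral tablet",
               "99999-0013-01"),
]

#: pair_id -> (expected status, expected category or None)
EXPECTED = {
    "fig-selection-error": (MatchStatus.MISMATCH, MismatchCategory.DIFFERENT_INGREDIENT),
    "same-medication": (MatchStatus.MATCH, None),
    "different-ingredient": (MatchStatus.MISMATCH, MismatchCategory.DIFFERENT_INGREDIENT),
    "different-strength": (MatchStatus.MISMATCH, MismatchCategory.DIFFERENT_STRENGTH),
    "different-pack-quantity": (MatchStatus.MISMATCH, MismatchCategory.DIFFERENT_PACK_QUANTITY),
    "different-form": (MatchStatus.MISMATCH, MismatchCategory.DIFFERENT_FORM),
    "outside-terminology": (MatchStatus.MISMATCH, MismatchCategory.OUTSIDE_RXNORM),
    "other-qualitative": (MatchStatus.MISMATCH, MismatchCategory.OTHER_QUALITATIVE),
}


def worked_example_frames() -> dict[str, pd.DataFrame]:
    """The snapshot as the four standard tables (writable via write_tables)."""
    return {
        "concepts": pd.DataFrame(
            _CONCEPTS, columns=["rxcui", "tty", "name", "status", "remapped_to", "curated"]
        ),
        "ndc_map": pd.DataFrame(_NDC_MAP, columns=["ndc11", "rxcui", "ndc_status"]),
        "scd_attributes": pd.DataFrame(
            _ATTRS,
            columns=[
                "rxcui", "ingredient", "strength_value", "strength_unit",
                "dose_form", "pack_quantity", "qualifiers",
            ],
        ),
        "related": pd.DataFrame(_RELATED, columns=["rxcui", "related_rxcui", "relation"]),
    }


def worked_example() -> tuple[FixtureTerminology, list[RecordPair], dict]:
    """Return (terminology snapshot, record pairs, expected outcome per pair)."""
    frames = worked_example_frames()
    store = FixtureTerminology.from_frames(
        frames["concepts"], frames["ndc_map"], frames["scd_attributes"], frames["related"]
    )
    return store, list(_PAIRS), dict(EXPECTED)
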