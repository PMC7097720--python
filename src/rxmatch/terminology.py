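"""Drug terminology layer: concepts, clinical-drug attributes, NDC mappings.

The comparison unit of the whole pipeline is the *clinical-level* concept:
a semantic clinical drug (SCD — ingredient + strength + dose form) or a
generic pack (GPCK — a counted bundle of clinical drugs). Branded concepts
(SBD, BPCK) are resolved to their generic counterparts before comparison.
Packs deliberately compare at pack level rather than being expanded to
their component tablets: two pack sizes of the same tablet are different
dispensed products, and collapsing them to the shared component would make
pack-quantity selection errors invisible.

Two backends satisfy the same contract: :class:`FixtureTerminology`, a pure
in-memory snapshot loaded from four TSV tables, and the REST client in
:mod:`rxmatch.rxnorm_api`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol

import pandas as pd

from .errors import AttributeUnavailable, ResolutionError, UnknownConcept
from .ndc import NdcCode

__all__ = [
    "RxConcept",
    "ScdAttributes",
    "NdcMapping",
    "TerminologyBackend",
    "FixtureTerminology",
    "CLINICAL_TTYS",
    "canonical_unit",
    "write_tables",
    "TABLE_FILES",
]

#: Term types that are already at clinical comparison level.
CLINICAL_TTYS = frozenset({"SCD", "GPCK"})


def canonical_unit(unit: str) -> str:
    """Canonicalize a strength unit string: trim and case-fold (no conversion)."""
    return unit.strip().casefold()


@dataclass(frozen=True)
class RxConcept:
    """A terminology node identified by its rxcui."""

    rxcui: str
    tty: str  # SCD | SBD | GPCK | BPCK | OTHER
    name: str
    status: str = "active"  # active | remapped | retired
    remapped_to: str | None = None
    curated: bool = True


@dataclass(frozen=True)
class ScdAttributes:
    """Structured attributes of a clinical drug or pack concept.

    ``strengths`` maps each ingredient to its (value, unit) pair;
    ``pack_quantity`` is present only for pack concepts. Uncurated concepts
    carry a stub with ``curated=False`` and empty attributes.
    """

    scd_rxcui: str
    ingredients: frozenset[str] = frozenset()
    strengths: Mapping[str, tuple[float, str]] = field(default_factory=dict)
    dose_form: str = ""
    pack_quantity: int | None = None
    qualifiers: frozenset[str] = frozenset()
    curated: bool = True

    def strength_key(self) -> frozenset[tuple[str, float, str]]:
        """Order-free strength fingerprint with canonicalized units."""
        return frozenset(
            (ing, float(v), canonical_unit(u)) for ing, (v, u) in self.strengths.items()
        )


@dataclass(frozen=True)
class NdcMapping:
    ndc: str  # normalized 11-digit
    rxcui: str | None
    ndc_status: str = "active"  # active | obsolete | unknown


class TerminologyBackend(Protocol):
    """Contract shared by the fixture store and the live REST client."""

    def ndc_to_concept(self, ndc: NdcCode | str) -> RxConcept | None: ...

    def resolve_to_scds(self, concept: RxConcept) -> frozenset[str]: ...

    def get_scd_attributes(self, scd_rxcui: str) -> ScdAttributes: ...


# --- fixture store ---------------------------------------------------------

_CONCEPT_COLS = ["rxcui", "tty", "name", "status", "remapped_to", "curated"]
_NDC_COLS = ["ndc11", "rxcui", "ndc_status"]
_ATTR_COLS = [
    "rxcui",
    "ingredient",
    "strength_value",
    "strength_unit",
    "dose_form",
    "pack_quantity",
    "qualifiers",
]
_RELATED_COLS = ["rxcui", "related_rxcui", "relation"]

TABLE_FILES = {
    "concepts": "concepts.tsv",
    "ndc_map": "ndc_map.tsv",
    "scd_attributes": "scd_attributes.tsv",
    "related": "related.tsv",
}


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_tables(frames: Mapping[str, pd.DataFrame], path: str | Path) -> None:
    """Write the four snapshot tables (keys of :data:`TABLE_FILES`) as TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for key, filename in TABLE_FILES.items():
        frames[key].to_csv(path / filename, sep="\t", index=False)


class FixtureTerminology:
    """In-memory terminology snapshot, a pure function of its four tables.

    Tables (tab-separated, UTF-8, header row, fixed column order):

    - ``concepts.tsv``: rxcui, tty, name, status, remapped_to, curated
    - ``ndc_map.tsv``: ndc11, rxcui, ndc_status (blank rxcui = unmappable NDC)
    - ``scd_attributes.tsv``: rxcui, ingredient, strength_value,
      strength_unit, dose_form, pack_quantity, qualifiers — one row per
      (concept, ingredient); qualifiers are ``|``-joined and repeated per row
    - ``related.tsv``: rxcui, related_rxcui, relation
    """

    def __init__(
        self,
        concepts: Iterable[RxConcept],
        ndc_map: Iterable[NdcMapping],
        attributes: Iterable[ScdAttributes],
        related: Iterable[tuple[str, str, str]],
    ):
        self._concepts: dict[str, RxConcept] = {c.rxcui: c for c in concepts}
        self._ndc: dict[str, NdcMapping] = {m.ndc: m for m in ndc_map}
        self._attrs: dict[str, ScdAttributes] = {a.scd_rxcui: a for a in attributes}
        self._related: dict[str, list[tuple[str, str]]] = {}
        for rxcui, rel, relation in related:
            self._related.setdefault(rxcui, []).append((rel, relation))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        concepts: pd.DataFrame,
        ndc_map: pd.DataFrame,
        scd_attributes: pd.DataFrame,
        related: pd.DataFrame,
    ) -> "FixtureTerminology":
        concept_objs = [
            RxConcept(
                rxcui=str(r.rxcui),
                tty=str(r.tty),
                name=str(r.name),
                status=str(r.status) or "active",
                remapped_to=str(r.remapped_to) or None,
                curated=str(r.curated).strip().lower() not in {"false", "0", "no"},
            )
            for r in concepts.itertuples(index=False)
        ]
        mappings = [
            NdcMapping(
                ndc=str(r.ndc11),
                rxcui=str(r.rxcui) or None,
                ndc_status=str(r.ndc_status) or "active",
            )
            for r in ndc_map.itertuples(index=False)
        ]
        attrs: list[ScdAttributes] = []
        for rxcui, grp in scd_attributes.groupby("rxcui", sort=False):
            strengths = {}
            for r in grp.itertuples(index=False):
                if str(r.ingredient):
                    strengths[str(r.ingredient)] = (
                        float(r.strength_value),
                        str(r.strength_unit),
                    )
            first = grp.iloc[0]
            pq = str(first["pack_quantity"])
            quals = frozenset(q for q in str(first["qualifiers"]).split("|") if q)
            attrs.append(
                ScdAttributes(
                    scd_rxcui=str(rxcui),
                    ingredients=frozenset(strengths),
                    strengths=strengths,
                    dose_form=str(first["dose_form"]),
                    pack_quantity=int(pq) if pq else None,
                    qualifiers=quals,
                )
            )
        rel = [
            (str(r.rxcui), str(r.related_rxcui), str(r.relation))
            for r in related.itertuples(index=False)
        ]
        return cls(concept_objs, mappings, attrs, rel)

    @classmethod
    def from_dir(cls, path: str | Path) -> "FixtureTerminology":
        path = Path(path)
        return cls.from_frames(
            _read_tsv(path / TABLE_FILES["concepts"]),
            _read_tsv(path / TABLE_FILES["ndc_map"]),
            _read_tsv(path / TABLE_FILES["scd_attributes"]),
            _read_tsv(path / TABLE_FILES["related"]),
        )

    # -- introspection (used by reports and the recorded transport) ---------

    def concept(self, rxcui: str) -> RxConcept:
        try:
            return self._concepts[rxcui]
        except KeyError:
            raise UnknownConcept(f"rxcui {rxcui} not in snapshot") from None

    def concepts(self) -> list[RxConcept]:
        return list(self._concepts.values())

    def ndc_mappings(self) -> list[NdcMapping]:
        return list(self._ndc.values())

    def related_of(self, rxcui: str) -> list[tuple[str, str]]:
        return list(self._related.get(rxcui, []))

    def has_attributes(self, rxcui: str) -> bool:
        return rxcui in self._attrs

    # -- backend contract ----------------------------------------------------

    def _follow_remap(self, concept: RxConcept) -> RxConcept:
        seen = {concept.rxcui}
        while concept.status == "remapped" and concept.remapped_to:
            concept = self.concept(concept.remapped_to)
            if concept.rxcui in seen:  # defensive: corrupt snapshot
                raise ResolutionError(f"remap cycle at rxcui {concept.rxcui}")
            seen.add(concept.rxcui)
        return concept

    def ndc_to_concept(self, ndc: NdcCode | str) -> RxConcept | None:
        key = ndc.normalized if isinstance(ndc, NdcCode) else str(ndc)
        mapping = self._ndc.get(key)
        if mapping is None or not mapping.rxcui:
            return None
        return self._follow_remap(self.concept(mapping.rxcui))

    def resolve_to_scds(self, concept: RxConcept) -> frozenset[str]:
        concept = self._follow_remap(concept)
        if concept.tty in CLINICAL_TTYS:
            return frozenset({concept.rxcui})
        if not concept.curated:
            # outside the curated scope: no structured links, compare as-is
            return frozenset({concept.rxcui})
        wanted = {"BPCK": {"GPCK", "SCD"}}.get(concept.tty, {"SCD"})
        out = frozenset(
            rel
            for rel, _relation in self._related.get(concept.rxcui, [])
            if self._concepts.get(rel) is not None and self._concepts[rel].tty in wanted
        )
        if not out:
            raise ResolutionError(
                f"{concept.tty} {concept.rxcui} has no related clinical drug concept"
            )
        return out

    def get_scd_attributes(self, scd_rxcui: str) -> ScdAttributes:
        concept = self.concept(scd_rxcui)
        if not concept.curated:
            return ScdAttributes(scd_rxcui=scd_rxcui, curated=False)
        try:
            return self._attrs[scd_rxcui]
        except KeyError:
            raise AttributeUnavailable(
                f"curated concept {scd_rxcui} has no structured attributes"
            ) from None
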