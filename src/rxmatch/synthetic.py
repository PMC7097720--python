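"""Synthetic drug terminology and record-pair generator with ground truth.

Emulates the structure a real dispensing stream presents to the check:

- a mini formulary of clinical drugs laid out on an ingredient × strength ×
  dose-form grid, each with a qualitative (osmotic-release) twin;
- branded counterparts (SBD) for a subset of clinical drugs and generic
  pack families (GPCK) in two pack sizes, exercising both resolution paths;
- the one-to-many concept→NDC relation (several NDCs per concept), an
  obsolete NDC remapped to an active concept, unmappable NDCs, and a pair
  of uncurated ("outside") concepts;
- optional mapping corruptions: NDCs of a truly different drug that the
  terminology (wrongly) maps to the target concept — the only mechanism
  that can produce false negatives, recorded in the ground truth.

Record pairs are drawn per-pair from a categorical distribution over the
configured error rates; each error mutates exactly one attribute so the
classifier cascade is exercised category by category. Synthetic NDCs use
the reserved labeler prefix ``99999`` so fixture provenance is self-evident.

Default rates encode the observed study conditions: per-category mismatch
rates equal to the published frequencies over 527,009 checked pairs
(3 ingredient, 1 strength, 285 pack-quantity, 67 form, 40 outside, 159
qualitative), cleaning removals of ~1.83% split evenly between signal words
and missing NDCs, and no mapping corruption.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigError, GenerationError
from .ingest import RecordPair
from .terminology import FixtureTerminology, write_tables

__all__ = [
    "GeneratorConfig",
    "SyntheticTerminology",
    "GroundTruth",
    "build_fixture_terminology",
    "generate_record_pairs",
    "write_ground_truth",
    "read_ground_truth",
    "equivalence_map",
]

_CHECKED_PAIRS = 527_009  # denominator of the published mismatch frequencies

_STRENGTH_LADDER = [5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0]
_FORMS = ["oral tablet", "oral capsule", "oral solution", "topical cream"]
_SIGNAL_WORDS = ["duplicate", "cancel", "wrong", "denied"]
_PACK_SIZES = (12, 4)


@dataclass
class GeneratorConfig:
    """Study-condition knobs for the synthetic terminology and pair stream."""

    n_ingredients: int = 12
    n_strength_levels: int = 3
    n_forms: int = 2
    n_brands: int = 6
    n_packs: int = 3
    ndcs_per_concept: int = 2
    rate_missing_ndc: float = 9_829 / 537_710 / 2
    rate_signal_word: float = 9_829 / 537_710 / 2
    rate_ingredient: float = 3 / _CHECKED_PAIRS
    rate_strength: float = 1 / _CHECKED_PAIRS
    rate_pack_quantity: float = 285 / _CHECKED_PAIRS
    rate_form: float = 67 / _CHECKED_PAIRS
    rate_outside: float = 40 / _CHECKED_PAIRS
    rate_other: float = 159 / _CHECKED_PAIRS
    rate_mapping_corruption: float = 0.0
    n_pairs: int = 10_000
    seed: int = 0

    def rates(self) -> dict[str, float]:
        return {
            "signal": self.rate_signal_word,
            "missing": self.rate_missing_ndc,
            "ingredient": self.rate_ingredient,
            "strength": self.rate_strength,
            "pack_quantity": self.rate_pack_quantity,
            "form": self.rate_form,
            "outside": self.rate_outside,
            "other": self.rate_other,
            "corruption": self.rate_mapping_corruption,
        }

    def validate(self) -> None:
        for f in fields(self):
            if f.name.startswith(("n_", "ndcs_")) and getattr(self, f.name) < 0:
                raise ConfigError(f"{f.name} must be non-negative")
        for name, rate in self.rates().items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate_{name} must lie in [0, 1]")
        if sum(self.rates().values()) > 1.0 + 1e-12:
            raise ConfigError("error rates must sum to at most 1 (remainder = true matches)")
        if self.n_ingredients < 2 or self.n_strength_levels < 2 or self.n_forms < 2:
            raise ConfigError("grid needs >= 2 ingredients, strengths and forms")
        if self.ndcs_per_concept < 1:
            raise ConfigError("ndcs_per_concept must be >= 1")
        if self.n_strength_levels > len(_STRENGTH_LADDER) or self.n_forms > len(_FORMS):
            raise ConfigError("requested strength/form levels exceed the built-in ladders")


@dataclass
class GroundTruth:
    """Intended outcome of one generated pair, for parameter recovery."""

    pair_id: str
    intended_status: str  # MATCH | MISMATCH | REMOVED_SIGNAL | REMOVED_MISSING
    intended_category: str = ""  # mismatch category name, or blank
    intended_label: str = ""  # TP | FP | TN | FN | blank (removed pairs)


@dataclass
class SyntheticTerminology:
    """A built snapshot plus the catalog the generator draws from."""

    frames: dict[str, pd.DataFrame]
    store: FixtureTerminology
    grid: dict[tuple[int, int, int], str]
    scd_info: dict[str, tuple[int, int, int]]
    names: dict[str, str]
    ndcs: dict[str, list[str]]
    twins: dict[str, str]
    brands: dict[str, list[str]]
    pack_families: list[tuple[str, str]]
    outside: tuple[str, str]
    corrupt_ndc: dict[str, tuple[str, str]]  # scd -> (ndc, true other scd)
    obsolete_ndc: str = ""
    unmappable_ndcs: list[str] = field(default_factory=list)

    def write_dir(self, path: str | Path) -> None:
        write_tables(self.frames, path)


def _ndc11(product: int, package: int) -> str:
    return f"99999{product:04d}{package:02d}"


def build_fixture_terminology(config: GeneratorConfig) -> SyntheticTerminology:
    """Deterministically build the snapshot implied by ``config``.

    The layout is a pure function of the counts in the config (no random
    draws), so identical configs give byte-identical tables.
    """
    config.validate()
    concepts: list[tuple] = []
    ndc_rows: list[tuple] = []
    attr_rows: list[tuple] = []
    related: list[tuple] = []

    grid: dict[tuple[int, int, int], str] = {}
    scd_info: dict[str, tuple[int, int, int]] = {}
    names: dict[str, str] = {}
    ndcs: dict[str, list[str]] = {}
    twins: dict[str, str] = {}
    brands: dict[str, list[str]] = {}
    pack_families: list[tuple[str, str]] = []
    corrupt_ndc: dict[str, tuple[str, str]] = {}

    product_counter = 0

    def assign_ndcs(rxcui: str, rxcui_status: str = "active") -> None:
        nonlocal product_counter
        product_counter += 1
        ndcs[rxcui] = []
        for j in range(config.ndcs_per_concept):
            code = _ndc11(product_counter, j + 1)
            ndc_rows.append((code, rxcui, rxcui_status))
            ndcs[rxcui].append(code)

    ingredients = [f"drug{i:02d}" for i in range(config.n_ingredients)]
    strengths = _STRENGTH_LADDER[: config.n_strength_levels]
    forms = _FORMS[: config.n_forms]

    # clinical-drug grid + qualitative twins
    idx = 0
    for i, ing in enumerate(ingredients):
        for s, value in enumerate(strengths):
            for f_, form in enumerate(forms):
                idx += 1
                scd = str(1_000_000 + idx)
                name = f"{ing} {value:g} mg {form}"
                concepts.append((scd, "SCD", name, "active", "", "true"))
                attr_rows.append((scd, ing, f"{value:g}", "mg", form, "", ""))
                grid[(i, s, f_)] = scd
                scd_info[scd] = (i, s, f_)
                names[scd] = name
                assign_ndcs(scd)

                twin = str(2_000_000 + idx)
                twin_name = f"Osmotic {name}"
                concepts.append((twin, "SCD", twin_name, "active", "", "true"))
                attr_rows.append((twin, ing, f"{value:g}", "mg", form, "", "osmotic"))
                names[twin] = twin_name
                twins[scd] = twin
                assign_ndcs(twin)

    grid_list = sorted(grid.values())
    n_grid = len(grid_list)

    # branded counterparts
    for b in range(config.n_brands):
        scd = grid_list[(b * max(1, n_grid // max(1, config.n_brands))) % n_grid]
        i, s, f_ = scd_info[scd]
        sbd = str(3_000_000 + b)
        name = f"Brandname{b:02d} {strengths[s]:g} mg {forms[f_]}"
        concepts.append((sbd, "SBD", name, "active", "", "true"))
        related.append((sbd, scd, "tradename_of"))
        names[sbd] = name
        brands.setdefault(scd, []).append(sbd)
        assign_ndcs(sbd)

    # generic pack families, two sizes each
    for p in range(config.n_packs):
        scd = grid_list[(p * max(1, n_grid // max(1, config.n_packs)) + 1) % n_grid]
        family = []
        for k, size in enumerate(_PACK_SIZES):
            gpck = str(4_000_000 + 2 * p + k)
            name = f"{size} ({names[scd]}) pack"
            i, s, f_ = scd_info[scd]
            concepts.append((gpck, "GPCK", name, "active", "", "true"))
            attr_rows.append(
                (gpck, ingredients[i], f"{strengths[s]:g}", "mg", forms[f_], str(size), "")
            )
            related.append((gpck, scd, "contains"))
            names[gpck] = name
            family.append(gpck)
            assign_ndcs(gpck)
        pack_families.append((family[0], family[1]))

    # uncurated ("outside") concept pair
    outside = ("8000001", "8000002")
    for rxcui, suffix in zip(outside, "AB"):
        concepts.append((rxcui, "OTHER", f"Proprietary formulation {suffix}", "active", "", "false"))
        names[rxcui] = f"Proprietary formulation {suffix}"
        assign_ndcs(rxcui)

    # obsolete NDC -> retired concept remapped to an active clinical drug
    retired = "8100001"
    concepts.append((retired, "SCD", f"retired {names[grid_list[0]]}", "remapped", grid_list[0], "true"))
    product_counter += 1
    obsolete_ndc = _ndc11(product_counter, 1)
    ndc_rows.append((obsolete_ndc, retired, "obsolete"))

    # NDCs the terminology has never curated at all
    unmappable: list[str] = []
    for _ in range(3):
        product_counter += 1
        code = _ndc11(product_counter, 1)
        ndc_rows.append((code, "", "unknown"))
        unmappable.append(code)

    # corrupt mappings: the NDC of a truly different drug points at the grid
    # concept — undetectable by matching, the ground-truth FN channel
    for scd in grid_list:
        i, s, f_ = scd_info[scd]
        true_other = grid[((i + 1) % config.n_ingredients, s, f_)]
        product_counter += 1
        code = _ndc11(product_counter, 1)
        ndc_rows.append((code, scd, "active"))
        corrupt_ndc[scd] = (code, true_other)

    frames = {
        "concepts": pd.DataFrame(
            concepts, columns=["rxcui", "tty", "name", "status", "remapped_to", "curated"]
        ),
        "ndc_map": pd.DataFrame(ndc_rows, columns=["ndc11", "rxcui", "ndc_status"]),
        "scd_attributes": pd.DataFrame(
            attr_rows,
            columns=[
                "rxcui", "ingredient", "strength_value", "strength_unit",
                "dose_form", "pack_quantity", "qualifiers",
            ],
        ),
        "related": pd.DataFrame(related, columns=["rxcui", "related_rxcui", "relation"]),
    }
    store = FixtureTerminology.from_frames(
        frames["concepts"], frames["ndc_map"], frames["scd_attributes"], frames["related"]
    )
    return SyntheticTerminology(
        frames=frames,
        store=store,
        grid=grid,
        scd_info=scd_info,
        names=names,
        ndcs=ndcs,
        twins=twins,
        brands=brands,
        pack_families=pack_families,
        outside=outside,
        corrupt_ndc=corrupt_ndc,
        obsolete_ndc=obsolete_ndc,
        unmappable_ndcs=unmappable,
    )


_CATEGORY_OF_KIND = {
    "ingredient": "DIFFERENT_INGREDIENT",
    "strength": "DIFFERENT_STRENGTH",
    "pack_quantity": "DIFFERENT_PACK_QUANTITY",
    "form": "DIFFERENT_FORM",
    "outside": "OUTSIDE_RXNORM",
    "other": "OTHER_QUALITATIVE",
}
_TP_KINDS = {"ingredient", "strength"}


def generate_record_pairs(
    synth: SyntheticTerminology, config: GeneratorConfig
) -> tuple[list[RecordPair], list[GroundTruth]]:
    """Draw ``config.n_pairs`` record pairs plus their intended outcomes.

    Each pair independently draws one kind from the configured rates
    (remainder = clean match). Error kinds mutate exactly one attribute of
    the dispensed product relative to the prescribed one; signal-word and
    missing-NDC pairs are otherwise clean matches destined for removal in
    the cleaning funnel.
    """
    config.validate()
    rng = random.Random(config.seed)
    rates = config.rates()
    kinds = list(rates)
    cumulative: list[tuple[float, str]] = []
    acc = 0.0
    for kind in kinds:
        acc += rates[kind]
        cumulative.append((acc, kind))

    grid_list = sorted(synth.grid.values())
    if not grid_list:
        raise GenerationError("terminology has no clinical-drug grid")

    def pick_kind() -> str:
        u = rng.random()
        for bound, kind in cumulative:
            if u < bound:
                return kind
        return "match"

    def side_for(scd: str, allow_brand: bool = True) -> tuple[str, str]:
        """(name, ndc) for a concept, occasionally via its brand."""
        sbds = synth.brands.get(scd, [])
        if allow_brand and sbds and rng.random() < 0.3:
            sbd = rng.choice(sbds)
            return synth.names[sbd], rng.choice(synth.ndcs[sbd])
        return synth.names[scd], rng.choice(synth.ndcs[scd])

    pairs: list[RecordPair] = []
    truths: list[GroundTruth] = []

    for n in range(config.n_pairs):
        pair_id = f"p{n:06d}"
        kind = pick_kind()
        prescriber = f"pr{rng.randrange(50):03d}"

        if kind == "pack_quantity":
            if not synth.pack_families:
                raise GenerationError("pack-quantity errors requested but no pack concepts exist")
            big, small = rng.choice(synth.pack_families)
            rx, disp = (big, small) if rng.random() < 0.5 else (small, big)
            rx_name, rx_ndc = synth.names[rx], rng.choice(synth.ndcs[rx])
            disp_name, disp_ndc = synth.names[disp], rng.choice(synth.ndcs[disp])
        elif kind == "outside":
            a, b = synth.outside
            rx_name, rx_ndc = synth.names[a], rng.choice(synth.ndcs[a])
            disp_name, disp_ndc = synth.names[b], rng.choice(synth.ndcs[b])
        else:
            scd = rng.choice(grid_list)
            i, s, f_ = synth.scd_info[scd]
            rx_name, rx_ndc = side_for(scd)
            if kind == "ingredient":
                delta = rng.randrange(1, config.n_ingredients)
                other = synth.grid[((i + delta) % config.n_ingredients, s, f_)]
                disp_name, disp_ndc = side_for(other)
            elif kind == "strength":
                delta = rng.randrange(1, config.n_strength_levels)
                other = synth.grid[(i, (s + delta) % config.n_strength_levels, f_)]
                disp_name, disp_ndc = side_for(other)
            elif kind == "form":
                delta = rng.randrange(1, config.n_forms)
                other = synth.grid[(i, s, (f_ + delta) % config.n_forms)]
                disp_name, disp_ndc = side_for(other)
            elif kind == "other":
                twin = synth.twins[scd]
                disp_name, disp_ndc = synth.names[twin], rng.choice(synth.ndcs[twin])
            elif kind == "corruption":
                code, true_other = synth.corrupt_ndc[scd]
                disp_name, disp_ndc = synth.names[true_other], code
            else:  # match / signal / missing start from a clean match
                disp_name, disp_ndc = side_for(scd)

        if kind == "signal":
            word = rng.choice(_SIGNAL_WORDS).upper()
            if rng.random() < 0.5:
                rx_name = f"{rx_name} {word}"
            else:
                disp_name = f"{disp_name} — {word}ED" if word != "DENIED" else f"{disp_name} — {word}"
        elif kind == "missing":
            if rng.random() < 0.5:
                rx_ndc = ""
            else:
                disp_ndc = ""

        pairs.append(
            RecordPair(pair_id, rx_name, rx_ndc, disp_name, disp_ndc, prescriber)
        )

        if kind == "signal":
            truths.append(GroundTruth(pair_id, "REMOVED_SIGNAL"))
        elif kind == "missing":
            truths.append(GroundTruth(pair_id, "REMOVED_MISSING"))
        elif kind == "corruption":
            truths.append(GroundTruth(pair_id, "MATCH", "", "FN"))
        elif kind == "match":
            truths.append(GroundTruth(pair_id, "MATCH", "", "TN"))
        else:
            truths.append(
                GroundTruth(
                    pair_id,
                    "MISMATCH",
                    _CATEGORY_OF_KIND[kind],
                    "TP" if kind in _TP_KINDS else "FP",
                )
            )
    return pairs, truths


def write_ground_truth(truths: Iterable[GroundTruth], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["pair_id", "intended_status", "intended_category", "intended_label"])
        for t in truths:
            w.writerow([t.pair_id, t.intended_status, t.intended_category, t.intended_label])


def read_ground_truth(path: str | Path) -> list[GroundTruth]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return [
            GroundTruth(
                r["pair_id"], r["intended_status"], r["intended_category"], r["intended_label"]
            )
            for r in csv.DictReader(fh, delimiter="\t")
        ]


def equivalence_map(truths: Iterable[GroundTruth]) -> dict[str, bool]:
    """pair_id -> whether the two products are truly equivalent (FN = False)."""
    return {t.pair_id: t.intended_label != "FN" for t in truths}
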