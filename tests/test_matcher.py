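"""Matching semantics, the mismatch cascade, and error-matrix labels."""

import random

import pytest

from rxmatch.matcher import (
    Label,
    MatchOutcome,
    MatchStatus,
    MismatchCategory,
    classify_mismatch,
    label_outcome,
    match_pair,
)
from rxmatch.pipeline import run_check
from rxmatch.terminology import ScdAttributes

F = frozenset


@pytest.mark.parametrize(
    "rx,disp,expected",
    [
        (F({"830845"}), F({"314200"}), MatchStatus.MISMATCH),
        (F({"751620"}), F({"751620"}), MatchStatus.MATCH),
        (F(), F({"314200"}), MatchStatus.MISSING_RXCUI),
        (F({"314200"}), F(), MatchStatus.MISSING_RXCUI),
        (F({"A", "B"}), F({"B", "C"}), MatchStatus.MATCH),  # pack overlap
    ],
)
def test_match_pair(rx, disp, expected):
    assert match_pair(rx, disp) == expected


def test_worked_example_categories(example):
    store, pairs, expected = example
    result = run_check(pairs, store)
    for outcome in result.outcomes:
        status, category = expected[outcome.pair_id]
        assert outcome.status == status, outcome.pair_id
        assert outcome.category == category, outcome.pair_id


def test_worked_example_labels(example):
    store, pairs, _ = example
    result = run_check(pairs, store)
    labels = {o.pair_id: o.label for o in result.outcomes}
    assert labels["fig-selection-error"] == Label.TP
    assert labels["different-ingredient"] == Label.TP
    assert labels["different-strength"] == Label.TP
    assert labels["different-pack-quantity"] == Label.FP
    assert labels["different-form"] == Label.FP
    assert labels["outside-terminology"] == Label.FP
    assert labels["other-qualitative"] == Label.FP
    assert labels["same-medication"] == Label.TN


def test_match_with_ground_truth_nonequivalence_is_fn():
    outcome = MatchOutcome(pair_id="x", status=MatchStatus.MATCH)
    assert label_outcome(outcome, truly_equivalent=False) == Label.FN
    assert label_outcome(outcome, truly_equivalent=True) == Label.TN
    assert label_outcome(outcome, truly_equivalent=None) == Label.TN


def test_missing_rxcui_carries_no_label():
    outcome = MatchOutcome(pair_id="x", status=MatchStatus.MISSING_RXCUI)
    assert label_outcome(outcome) is None


# --- cascade vs brute-force comparator -------------------------------------

_PRECEDENCE = [
    ("outside", MismatchCategory.OUTSIDE_RXNORM),
    ("ingredient", MismatchCategory.DIFFERENT_INGREDIENT),
    ("strength", MismatchCategory.DIFFERENT_STRENGTH),
    ("pack", MismatchCategory.DIFFERENT_PACK_QUANTITY),
    ("form", MismatchCategory.DIFFERENT_FORM),
]


def oracle_classify(attrs_rx, attrs_disp):
    """Enumerate every attribute difference, then apply severity precedence."""
    diffs = set()
    if any(not a.curated for a in list(attrs_rx) + list(attrs_disp)):
        diffs.add("outside")
    else:
        rx = min(attrs_rx, key=lambda a: a.scd_rxcui)
        disp = min(attrs_disp, key=lambda a: a.scd_rxcui)
        if set(rx.ingredients) != set(disp.ingredients):
            diffs.add("ingredient")
        rx_s = {(i, float(v), u.strip().casefold()) for i, (v, u) in rx.strengths.items()}
        disp_s = {(i, float(v), u.strip().casefold()) for i, (v, u) in disp.strengths.items()}
        if rx_s != disp_s:
            diffs.add("strength")
        if rx.pack_quantity != disp.pack_quantity:
            diffs.add("pack")
        if rx.dose_form.strip().casefold() != disp.dose_form.strip().casefold():
            diffs.add("form")
    for key, category in _PRECEDENCE:
        if key in diffs:
            return category
    return MismatchCategory.OTHER_QUALITATIVE


def _random_attrs(rng, rxcui):
    ings = rng.sample(["a", "b", "c", "d"], k=rng.randint(1, 3))
    return ScdAttributes(
        scd_rxcui=rxcui,
        ingredients=frozenset(ings),
        strengths={i: (rng.choice([5.0, 10.0, 25.0]), rng.choice(["mg", "MG ", "unt"])) for i in ings},
        dose_form=rng.choice(["oral tablet", "oral capsule", "Oral Tablet"]),
        pack_quantity=rng.choice([None, 4, 12]),
        qualifiers=frozenset(rng.sample(["osmotic", "24 hr"], k=rng.randint(0, 2))),
        curated=rng.random() > 0.1,
    )


def test_cascade_equals_brute_force_oracle():
    """On random small attribute sets the cascade agrees with an independent
    enumerate-all-differences comparator applying the same precedence."""
    rng = random.Random(20240311)
    for trial in range(500):
        n_rx, n_disp = rng.randint(1, 3), rng.randint(1, 3)
        attrs_rx = [_random_attrs(rng, f"{100 + i}") for i in range(n_rx)]
        attrs_disp = [_random_attrs(rng, f"{200 + i}") for i in range(n_disp)]
        assert classify_mismatch(attrs_rx, attrs_disp) == oracle_classify(attrs_rx, attrs_disp)


def test_cascade_exhaustive_and_exclusive(small_synth):
    """Every pair of distinct clinical concepts in a <=50-concept snapshot gets
    exactly one category, matching the brute-force comparator."""
    store = small_synth.store
    clinical = [
        c.rxcui
        for c in store.concepts()
        if store.has_attributes(c.rxcui) or not c.curated
    ]
    assert len(clinical) <= 50
    for a in clinical:
        for b in clinical:
            if a == b:
                continue
            attrs_a = [store.get_scd_attributes(a)]
            attrs_b = [store.get_scd_attributes(b)]
            got = classify_mismatch(attrs_a, attrs_b)
            assert got == oracle_classify(attrs_a, attrs_b)
            assert isinstance(got, MismatchCategory)


def test_strength_units_canonicalized_not_converted():
    base = ScdAttributes(
        scd_rxcui="1", ingredients=F({"a"}), strengths={"a": (5.0, "MG ")}, dose_form="oral tablet"
    )
    same_unit = ScdAttributes(
        scd_rxcui="2", ingredients=F({"a"}), strengths={"a": (5.0, "mg")}, dose_form="oral tablet"
    )
    other_unit = ScdAttributes(
        scd_rxcui="3", ingredients=F({"a"}), strengths={"a": (5.0, "g")}, dose_form="oral tablet"
    )
    assert classify_mismatch([base], [same_unit]) == MismatchCategory.OTHER_QUALITATIVE
    assert classify_mismatch([base], [other_unit]) == MismatchCategory.DIFFERENT_STRENGTH
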