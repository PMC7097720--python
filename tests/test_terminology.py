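"""Fixture terminology store, REST client, and backend equivalence."""

import json
import urllib.error

import pytest

from rxmatch.errors import BackendUnavailable, ResolutionError, UnknownConcept
from rxmatch.ndc import normalize_ndc
from rxmatch.rxnorm_api import RxNormClient, make_recorded_transport
from rxmatch.terminology import FixtureTerminology, write_tables


def test_ndc_to_concept_via_brand(example):
    store, _, _ = example
    concept = store.ndc_to_concept(normalize_ndc("00008-0841-81"))
    assert concept is not None and concept.rxcui == "284400" and concept.tty == "SBD"
    assert store.resolve_to_scds(concept) == frozenset({"314200"})


def test_scd_resolves_to_itself(example):
    store, _, _ = example
    concept = store.ndc_to_concept("00093511798")
    assert concept.rxcui == "830845" and concept.tty == "SCD"
    assert store.resolve_to_scds(concept) == frozenset({"830845"})


def test_unknown_ndc_is_absent_not_an_error(example):
    store, _, _ = example
    assert store.ndc_to_concept("99999999999") is None


def test_pack_concepts_compare_at_pack_level(example):
    store, _, _ = example
    pack = store.concept("905100")
    assert pack.tty == "GPCK"
    assert store.resolve_to_scds(pack) == frozenset({"905100"})
    attrs = store.get_scd_attributes("905100")
    assert attrs.pack_quantity == 12
    assert attrs.ingredients == frozenset({"risedronate sodium"})


def test_obsolete_ndc_remaps_to_active_concept(small_synth):
    # 3-node chain: obsolete NDC -> retired rxcui -> remapped_to active rxcui
    concept = small_synth.store.ndc_to_concept(small_synth.obsolete_ndc)
    assert concept is not None
    assert concept.status == "active"
    assert concept.rxcui == sorted(small_synth.grid.values())[0]


def test_unmappable_and_uncurated(small_synth):
    store = small_synth.store
    for ndc in small_synth.unmappable_ndcs:
        assert store.ndc_to_concept(ndc) is None
    outside = store.concept(small_synth.outside[0])
    assert not outside.curated
    assert store.resolve_to_scds(outside) == frozenset({outside.rxcui})
    stub = store.get_scd_attributes(outside.rxcui)
    assert not stub.curated and not stub.ingredients


def test_resolution_closure(small_synth):
    """Resolution output only contains clinical-level or uncurated concepts."""
    store = small_synth.store
    for concept in store.concepts():
        try:
            scds = store.resolve_to_scds(concept)
        except ResolutionError:
            continue
        for rxcui in scds:
            c = store.concept(rxcui)
            assert c.tty in {"SCD", "GPCK"} or not c.curated


def test_unresolvable_concept_raises(example):
    store, _, _ = example
    from rxmatch.terminology import RxConcept

    lonely = RxConcept(rxcui="314200", tty="SBD", name="orphan brand")
    with pytest.raises(ResolutionError):
        store.resolve_to_scds(lonely)
    with pytest.raises(UnknownConcept):
        store.concept("42")


def test_tsv_round_trip(tmp_path, small_synth):
    """from_dir(write_dir(x)) reproduces the same backend behavior."""
    small_synth.write_dir(tmp_path)
    reloaded = FixtureTerminology.from_dir(tmp_path)
    for m in small_synth.store.ndc_mappings():
        assert reloaded.ndc_to_concept(m.ndc) == small_synth.store.ndc_to_concept(m.ndc)
    for c in small_synth.store.concepts():
        if small_synth.store.has_attributes(c.rxcui):
            assert reloaded.get_scd_attributes(c.rxcui) == small_synth.store.get_scd_attributes(c.rxcui)


def _assert_equivalent(store, client):
    for m in store.ndc_mappings():
        assert client.ndc_to_concept(m.ndc) == store.ndc_to_concept(m.ndc)
    for concept in store.concepts():
        try:
            expected = store.resolve_to_scds(concept)
        except ResolutionError:
            with pytest.raises(ResolutionError):
                client.resolve_to_scds(concept)
            continue
        assert client.resolve_to_scds(concept) == expected
        for rxcui in expected:
            if store.has_attributes(rxcui) or not store.concept(rxcui).curated:
                assert client.get_scd_attributes(rxcui) == store.get_scd_attributes(rxcui)


def test_backend_equivalence_worked_example(example):
    """Recorded REST endpoint and fixture store answer identically."""
    store, _, _ = example
    client = RxNormClient(transport=make_recorded_transport(store), min_interval=0)
    _assert_equivalent(store, client)


def test_backend_equivalence_synthetic(small_synth):
    client = RxNormClient(transport=make_recorded_transport(small_synth.store), min_interval=0)
    _assert_equivalent(small_synth.store, client)


def test_client_cache_persists_and_replays(tmp_path, example):
    store, _, _ = example
    calls = []
    recorded = make_recorded_transport(store)

    def counting(url):
        calls.append(url)
        return recorded(url)

    cache = tmp_path / "cache.json"
    with RxNormClient(transport=counting, cache_path=cache, min_interval=0) as client:
        first = client.ndc_to_concept("00008084181")
    n_live = len(calls)
    assert n_live > 0 and cache.exists()

    def dead(url):
        raise urllib.error.URLError("offline")

    with RxNormClient(transport=dead, cache_path=cache, min_interval=0, backoff=0) as client:
        assert client.ndc_to_concept("00008084181") == first
    assert len(calls) == n_live  # byte-identical cache hits, no new requests
    assert json.loads(cache.read_text())  # persistent across runs


def test_backend_unavailable_after_retries():
    attempts = []

    def dead(url):
        attempts.append(url)
        raise urllib.error.URLError("down")

    client = RxNormClient(transport=dead, min_interval=0, max_retries=3, backoff=0)
    with pytest.raises(BackendUnavailable):
        client.ndc_to_concept("00008084181")
    assert len(attempts) == 3


def test_write_tables_layout(tmp_path, small_synth):
    write_tables(small_synth.frames, tmp_path)
    names = {p.name for p in tmp_path.iterdir()}
    assert names == {"concepts.tsv", "ndc_map.tsv", "scd_attributes.tsv", "related.tsv"}
    header = (tmp_path / "concepts.tsv").read_text().splitlines()[0]
    assert header.split("\t") == ["rxcui", "tty", "name", "status", "remapped_to", "curated"]
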