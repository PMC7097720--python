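import pytest

from rxmatch.examples import worked_example
from rxmatch.synthetic import GeneratorConfig, build_fixture_terminology


@pytest.fixture(scope="session")
def example():
    """(terminology, pairs, expected) for the bundled worked example."""
    return worked_example()


@pytest.fixture(scope="session")
def small_synth():
    """A small deterministic synthetic terminology (< 50 clinical concepts)."""
    cfg = GeneratorConfig(
        n_ingredients=3, n_strength_levels=2, n_forms=2, n_brands=2, n_packs=1,
        ndcs_per_concept=2,
    )
    return build_fixture_terminology(cfg)
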