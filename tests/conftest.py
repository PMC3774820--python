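import pytest

from r2ribozyme import build_target_ref, default_element, default_target_ref
from r2ribozyme.simulate import PlantConfig, generate_ribozyme


@pytest.fixture(scope="session")
def ref28s():
    return default_target_ref()


@pytest.fixture(scope="session")
def element():
    return default_element()


@pytest.fixture(scope="session")
def planted():
    """One planted ribozyme shared across tests (seed 1, offset -28)."""
    return generate_ribozyme(PlantConfig(seed=1))


@pytest.fixture(scope="session")
def planted_set():
    """A small panel of planted ribozymes at varied cleavage offsets."""
    offsets = (-28, -13, -29, -36, -9, 0)
    return [generate_ribozyme(PlantConfig(seed=s, cleavage_offset=offsets[s % 6]))
            for s in range(12)]


@pytest.fixture(scope="session")
def flower_ref():
    """Tiny 28S reference engineered with two microhomology sites.

    The upstream flank places elem-prefix matches 'GGTA' (run 4) at
    position 10 and 'GGT' (run 3) at position 16 for the default element,
    giving exactly two priming sites with weights 4:3.
    """
    return build_target_ref("ACCTTACCTTGGTACAGGTC" + "AGGTCAGGTTCGAATCCAAC",
                            20, id="tiny")
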