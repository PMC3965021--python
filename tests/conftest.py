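import pytest
from hypothesis import settings

from funclink import (DataNetwork, GeneSetCollection, GoldStandard,
                      gold_from_annotations)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def toy_net() -> DataNetwork:
    """Small weighted network: a triangle plus a pendant edge."""
    return DataNetwork(tag="toy", edges={
        ("A", "B"): 3.0,
        ("A", "C"): 2.0,
        ("B", "C"): 1.5,
        ("C", "D"): 0.5,
    })


@pytest.fixture
def toy_pathways() -> GeneSetCollection:
    return GeneSetCollection(sets={
        "S1": frozenset({"A", "B", "C"}),
        "S2": frozenset({"C", "D"}),
    })


@pytest.fixture
def toy_gold(toy_pathways) -> GoldStandard:
    return gold_from_annotations(toy_pathways)
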