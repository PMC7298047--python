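import pandas as pd
import pytest

from repurpose import GeneSet, Interaction, InteractionTable


@pytest.fixture
def small_universe_table() -> InteractionTable:
    """Ten-gene universe pinned by a broad drug, plus a focused drug.

    Drug X targets g1-g3 (all inside the query half of the universe);
    drug U targets every gene so that the auto universe is g1..g10.
    """
    edges = [Interaction("X", "drug x", f"g{i}", "T") for i in (1, 2, 3)]
    edges += [Interaction("U", "drug u", f"g{i}", "T") for i in range(1, 11)]
    return InteractionTable(edges)


@pytest.fixture
def query_half() -> GeneSet:
    return GeneSet.from_symbols([f"g{i}" for i in range(1, 6)], label="q")


@pytest.fixture
def emr_three_patients() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3"],
            "age": [35, 50, 70],
            "drug": ["D", "D", "D"],
            "glaucoma": [0, 1, 0],
        }
    )
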