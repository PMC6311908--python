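import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nipkit.data_io import InteractionSet, Protein, ProteinSet
from nipkit.features import PropertyTable
from nipkit.synthetic import SyntheticConfig, generate_world

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def property_table() -> PropertyTable:
    return PropertyTable.default()


@pytest.fixture(scope="session")
def small_world() -> dict:
    """A compact coupled world reused by strategy and pipeline tests."""
    return generate_world(
        SyntheticConfig(n_proteins=60, length_range=(60, 150),
                        n_positive_edges=150, seed=5)
    )


@pytest.fixture(scope="session")
def matched_fixture() -> dict:
    """The degree-control study conditions: 200 proteins, 600 positives."""
    world = generate_world(
        SyntheticConfig(n_proteins=200, n_positive_edges=600, seed=11)
    )
    return {
        "positives": world["planted"],
        "similarity": world["similarity"],
        "universe": world["planted"].protein_ids(),
    }


@pytest.fixture
def toy_proteins() -> ProteinSet:
    rng = np.random.default_rng(42)
    return ProteinSet(
        Protein(pid, random_sequence(rng, 60)) for pid in ("A", "B", "C", "D")
    )


@pytest.fixture
def path_graph() -> InteractionSet:
    """The path a - b - c - d."""
    return InteractionSet([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def triangle_graph() -> InteractionSet:
    return InteractionSet([("a", "b"), ("b", "c"), ("a", "c")])
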