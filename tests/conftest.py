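import pandas as pd
import pytest

from hscnet.core_sets import GeneSet, Universe
from hscnet.phenotype_assoc import AnnotationMatrix


@pytest.fixture
def small_universe() -> Universe:
    return Universe(name="U", symbols=frozenset(f"G{i}" for i in range(20)))


@pytest.fixture
def overlap_sets(small_universe):
    """Fixed size 5, comparator size 4, overlap 3 over N=20 -> (3,2,1,14)."""
    fixed = GeneSet(name="fixed", symbols=frozenset(["G0", "G1", "G2", "G3", "G4"]),
                    universe_name="U")
    comparator = GeneSet(name="comp",
                         symbols=frozenset(["G0", "G1", "G2", "G10"]),
                         universe_name="U")
    return fixed, comparator


@pytest.fixture
def tiny_annotations() -> AnnotationMatrix:
    """g1 -> {P1, P2}, g2 -> {P1}."""
    df = pd.DataFrame([[1, 1], [1, 0]], index=["g1", "g2"],
                      columns=["P1", "P2"])
    return AnnotationMatrix(incidence=df)
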