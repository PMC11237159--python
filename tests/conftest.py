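import numpy as np
import pytest

from glueevo import synthetic as syn
from glueevo.formats import ExpressionTable


@pytest.fixture
def tiny_table() -> ExpressionTable:
    """3 reference genes + 1 focal gene over 1 glue + 3 non-glue species."""
    return ExpressionTable(
        genes=["g1", "g2", "g3", "prit"],
        species=["glue", "n1", "n2", "n3"],
        values=np.array(
            [
                [10.0, 5.0, 2.0, 0.5],
                [4.0, 1.0, 8.0, 2.0],
                [6.0, 6.0, 3.0, 1.0],
                [50.0, 5.0, 2.0, 0.5],
            ]
        ),
        species_role={"glue": "glue", "n1": "nonglue", "n2": "nonglue", "n3": "nonglue"},
        gene_class={"g1": "reference", "g2": "reference", "g3": "reference", "prit": "focal"},
    )


@pytest.fixture
def synthetic_protein():
    """Noise-free modular protein with its true architecture."""
    seq, annotation, truth = syn.gen_modular_protein(substitution_rate=0.0, seed=42)
    return seq, annotation, truth
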