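import numpy as np
import pytest

from csdpop.genotypes import GenotypeMatrix
from csdpop.synth import SyntheticSpec, gen_structured_genotypes


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """4 individuals in 2 fields (2 regions), 3 biallelic loci, no missing."""
    calls = np.array(
        [
            [[1, 1], [1, 2], [1, 1]],
            [[1, 2], [1, 2], [1, 1]],
            [[2, 2], [1, 1], [1, 2]],
            [[2, 2], [2, 2], [2, 2]],
        ],
        dtype=np.int16,
    )
    ids = ["a1", "a2", "b1", "b2"]
    return GenotypeMatrix(
        calls=calls,
        individual_ids=ids,
        locus_ids=["L1", "L2", "L3"],
        field_of={"a1": "fA", "a2": "fA", "b1": "fB", "b2": "fB"},
        region_of={"fA": "r1", "fB": "r2"},
    )


@pytest.fixture
def study_matrix() -> GenotypeMatrix:
    """Study-shaped synthetic dataset (8 fields, 4 regions, 81 loci)."""
    return gen_structured_genotypes(SyntheticSpec(seed=42))
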