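import numpy as np
import pandas as pd
import pytest

from plasmapipe.io_formats import GroupManifest, IntensityMatrix
from plasmapipe.synthetic import (
    CohortDesign,
    EffectSpec,
    MissingnessSpec,
    ToyComplexSpec,
    apply_missingness,
    generate_cohort,
    generate_toy_complex,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort with one injected doubling, complete data."""
    design = CohortDesign(group_sizes={"A": 12, "B": 12}, n_proteins=40,
                          seed=11)
    return generate_cohort(design, [EffectSpec("P0001", "B", 2.0)])


@pytest.fixture(scope="session")
def study_cohort():
    """Three-group study-sized cohort with realistic missingness."""
    design = CohortDesign.default_study(seed=5, n_proteins=200)
    matrix, manifest = generate_cohort(design, [])
    res = apply_missingness(matrix, MissingnessSpec(), seed=6)
    return res.matrix, manifest


@pytest.fixture(scope="session")
def toy_free():
    """Toy complex with the partner beyond contact range."""
    return generate_toy_complex(ToyComplexSpec(peptide_length=10,
                                               burial_fraction=0.0, seed=3))


@pytest.fixture(scope="session")
def toy_half():
    """Toy complex calibrated to ~50% peptide burial."""
    return generate_toy_complex(ToyComplexSpec(peptide_length=10,
                                               burial_fraction=0.5, seed=3))


@pytest.fixture
def tiny_matrix():
    values = pd.DataFrame(
        [[1.0, 2.0, np.nan], [4.0, 5.0, 6.0]],
        index=["P1", "P2"], columns=["s1", "s2", "s3"],
    )
    return IntensityMatrix(values)


@pytest.fixture
def two_group_manifest():
    return GroupManifest(pd.Series(
        {"s1": "A", "s2": "A", "s3": "B"}, name="group"))
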