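import numpy as np
import pandas as pd
import pytest

from microstab.io import (CultureTable, FeatureTable, SampleMetadata,
                          read_tree)
from microstab.simulate import generate_cohort, study_like_config


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        {
            "s1": [10, 0, 5],
            "s2": [2, 8, 0],
            "s3": [0, 3, 7],
            "s4": [6, 6, 6],
        },
        index=["A", "B", "C"],
    )
    tax = pd.Series(
        ["d__Bacteria;g__Lactobacillus", "d__Bacteria;g__Gardnerella",
         "unclassified"],
        index=["A", "B", "C"],
    )
    return FeatureTable(counts, tax)


@pytest.fixture
def tiny_metadata():
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "volunteer_id": ["A", "A", "B", "B"],
        "visit": ["1", "2", "1", "2"],
        "sample_type": ["CU", "CU", "fecal", "fecal"],
        "dna_conc": [1.0, 2.0, 5.0, 4.0],
    }))


@pytest.fixture
def simple_tree():
    return read_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def cohort():
    """One study-design synthetic cohort shared across tests."""
    return generate_cohort(study_like_config(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (8 volunteers) for faster end-to-end tests."""
    cfg = study_like_config(seed=5, n_volunteers=8, visit5_volunteers=5,
                            dropouts=())
    return generate_cohort(cfg)
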