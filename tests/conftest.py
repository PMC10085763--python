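import numpy as np
import pandas as pd
import pytest

from rcgs import config as rcgs_config
from rcgs import filter_markers, genomic_matrix
from rcgs.genotypes import MarkerMatrix


@pytest.fixture(scope="session")
def mini2_bundle():
    """Two bi-parental families of 20 lines each, 120 markers."""
    return rcgs_config.fixture("mini2", seed=1)


@pytest.fixture(scope="session")
def mini14_bundle():
    """Fourteen families of 4 lines each, 200 markers."""
    return rcgs_config.fixture("mini14", seed=2)


@pytest.fixture(scope="session")
def small_g(mini2_bundle):
    """QC-filtered marker matrix and its genomic relationship matrix."""
    mm, *_ = mini2_bundle
    mm_qc, _ = filter_markers(mm)
    return mm_qc, genomic_matrix(mm_qc)


@pytest.fixture()
def toy_marker_matrix():
    """4 individuals x 5 markers, hand-written dosages, one missing call."""
    dosages = np.array(
        [
            [0, 1, 2, 0, 2],
            [1, 1, 0, 0, 2],
            [2, 0, 1, 0, 2],
            [0, 2, np.nan, 0, 2],
        ],
        dtype=float,
    )
    return MarkerMatrix(
        ["L1", "L2", "L3", "L4"],
        ["m1", "m2", "m3", "m4", "m5"],
        dosages,
    )
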