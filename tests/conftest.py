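import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from seedshadow.genotypes import ErrorRates, GenotypeTable
from seedshadow.parentage import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def square_100m():
    """1-ha square plot in local meters."""
    return Polygon([(0, 0), (100, 0), (100, 100), (0, 100)])


def make_table(calls, ids=None, loci=None, motif=2):
    """GenotypeTable from a nested list [(a, b) per locus] per individual."""
    calls = np.asarray(calls, dtype=np.int64)
    n, L = calls.shape[:2]
    return GenotypeTable(
        ids if ids is not None else [f"i{j}" for j in range(n)],
        loci if loci is not None else [f"L{l + 1}" for l in range(L)],
        calls,
        np.full(L, motif),
    )


@pytest.fixture
def toy_dataset(square_100m):
    """Four mapped adults and two seedlings on one 3-allele locus.

    Small enough for exhaustive enumeration of every parent-pair
    combination; genotypes chosen so both compatible and excluded pairs
    occur at e = 0.
    """
    adults = pd.DataFrame(
        {
            "id": ["A0", "A1", "A2", "A3"],
            "x": [20.0, 80.0, 30.0, 70.0],
            "y": [30.0, 30.0, 75.0, 70.0],
            "species": ["Q"] * 4,
            "dbh_cm": [40.0, 25.0, 55.0, 33.0],
            "fecundity_mean": [500.0, 800.0, 300.0, 650.0],
            "fecundity_sd": [0.0, 0.0, 0.0, 0.0],
        }
    )
    seedlings = pd.DataFrame(
        {"id": ["S0", "S1"], "x": [35.0, 60.0], "y": [40.0, 60.0]}
    )
    # one locus, alleles 100/102/104
    calls = np.array(
        [
            [[100, 102]],  # A0
            [[102, 104]],  # A1
            [[100, 100]],  # A2
            [[104, 104]],  # A3
            [[100, 104]],  # S0: compatible with e.g. A0 x A1, A2 x A3
            [[102, 102]],  # S1: needs a 102 from each parent
        ]
    )
    gt = GenotypeTable(["A0", "A1", "A2", "A3", "S0", "S1"], ["L1"], calls, np.array([2]))
    err = ErrorRates(np.array([0.05]), np.array([0.05]))
    return Dataset(adults, seedlings, gt, square_100m, err)
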