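import numpy as np
import pytest

from sexnest.records import SpecimenRecord


def rec(visitor="V1", sex="female", plant="P1", site="S", year=2000):
    return SpecimenRecord(
        visitor_taxon=visitor, sex=sex, plant_taxon=plant, site=site, year=year
    )


@pytest.fixture
def four_records():
    """2 female V1-on-P1, 1 male V2-on-P2, 1 male V2-on-P1."""
    return [
        rec("V1", "female", "P1"),
        rec("V1", "female", "P1"),
        rec("V2", "male", "P2"),
        rec("V2", "male", "P1"),
    ]


@pytest.fixture
def nested_matrix():
    """Strictly nested 3x3 count matrix (perfect weighted nestedness)."""
    return np.array([[3, 2, 1], [2, 1, 0], [1, 0, 0]])


def random_count_matrix(rng, m=None, n=None, high=5):
    """Random count matrix with every row and column sum >= 1."""
    m = m or rng.integers(2, 6)
    n = n or rng.integers(2, 6)
    while True:
        X = rng.integers(0, high, size=(m, n))
        if (X.sum(0) > 0).all() and (X.sum(1) > 0).all():
            return X
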