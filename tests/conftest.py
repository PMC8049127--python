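import numpy as np
import pytest

from stadnet import DistanceMatrix, PatientProfile, table1_fixture


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    """Random symmetric matrix in [0,1] with zero diagonal."""
    v = rng.random((n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(f"n{i}" for i in range(n)), v)


def random_profile(rng: np.random.Generator, alphabet: list[str],
                   max_len: int = 8, stay: str = "s") -> PatientProfile:
    """Random ordered list of distinct codes from the alphabet."""
    length = int(rng.integers(1, max_len + 1))
    length = min(length, len(alphabet))
    codes = rng.choice(alphabet, size=length, replace=False)
    return PatientProfile(stay_id=stay, codes=tuple(codes))


@pytest.fixture
def sepsis_pair():
    """The bundled two-patient worked example (raw ICD-9 level)."""
    return table1_fixture(level="raw")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
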