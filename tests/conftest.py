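import numpy as np
import pytest

from tcrl import (
    Repertoire,
    RepertoireSet,
    SimulationConfig,
    SubstitutionScheme,
    simulate_covariates,
    simulate_repertoire_set,
)


@pytest.fixture(scope="session")
def scheme_b62():
    return SubstitutionScheme(matrix_name="BLOSUM62")


@pytest.fixture(scope="session")
def scheme_p250():
    return SubstitutionScheme(matrix_name="PAM250")


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated subjects with the generator's default repertoire law."""
    rng = np.random.default_rng(42)
    return simulate_repertoire_set(6, rng, SimulationConfig())


@pytest.fixture
def toy_repertoire():
    """Table-1-like single subject: three unique sequences, abundances 1,1,9."""
    return Repertoire(
        subject_id="1",
        sequences=["CASSLGRGKAFF", "CASSWLIGYTF", "CASSLGRAEAFF"],
        abundances=np.array([1, 1, 9]),
    )


@pytest.fixture
def two_subject_set():
    return RepertoireSet([
        Repertoire("a", ["CASSLGRGKAFF", "CASSWLIGYTF"], np.array([2, 3])),
        Repertoire("b", ["CASSLGRAEAFF", "CSARERGEQYF", "CASRDRQETQYF"], np.array([1, 4, 1])),
    ])


@pytest.fixture(scope="session")
def medium_design():
    """n=120 covariates plus a seeded generator for trait draws."""
    rng = np.random.default_rng(7)
    cov = simulate_covariates(120, rng)
    return cov, rng
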