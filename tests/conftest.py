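import numpy as np
import pytest

from cct.kinetics import KineticParams
from cct.synthetic import SynthConfig, default_params, generate_cct_counts


@pytest.fixture(scope="session")
def baseline_params() -> KineticParams:
    return default_params()


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic dataset for fast pipeline unit tests."""
    return generate_cct_counts(SynthConfig(n_cells=400, n_genes=300, genes_per_program=40, seed=11))


@pytest.fixture(scope="session")
def full_synth():
    """The default-size synthetic dataset (study conditions)."""
    return generate_cct_counts(SynthConfig(seed=0))


def random_kinetic_params(rng: np.random.Generator) -> KineticParams:
    """A random valid kinetic parameter set (log-uniform around plausible scales)."""
    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return KineticParams(
        kt_s=lu(1, 30), kt_m=lu(1, 30),
        kd_s=lu(0.5, 3), kd_m=lu(0.5, 3),
        kd_s2=lu(0.1, 1), kd_m2=lu(0.1, 1),
        p=lu(1.2, 4),
        s_f=lu(1.3, 2), m_f=lu(1.3, 2),
        t1=lu(0.3, 2), t1s=lu(0.3, 2), t2s=lu(0.3, 2), tm=lu(0.05, 0.3),
    )
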