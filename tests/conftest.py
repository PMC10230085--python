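import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from refstab.io import load_table1_fixture
from refstab.stability import CtMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """Packaged candidate table from the transcriptome CV screen."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_insilico(table1):
    return table1[table1["group"] != "Published"]


def random_ct_matrix(n_genes, n_samples, seed, spread=2.0):
    """Unstructured random Ct matrix for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    values = 20.0 + spread * rng.standard_normal((n_genes, n_samples))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return CtMatrix(pd.DataFrame(values, index=genes, columns=samples))


@pytest.fixture
def ct_4x5():
    return random_ct_matrix(4, 5, seed=42)


@pytest.fixture
def ct_4x6():
    return random_ct_matrix(4, 6, seed=7)
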