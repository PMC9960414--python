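import numpy as np
import pandas as pd
import pytest

from metabosub.data_io import ClinicalTable, ExpressionMatrix, GeneSet
from metabosub.synthetic_data import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Fast cohort used by several modules (n=150, strong signal)."""
    return generate_cohort(SyntheticCohortConfig(n_samples=150, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort matching the default configuration (n=480)."""
    return generate_cohort(SyntheticCohortConfig(seed=1))


@pytest.fixture
def tiny_expr():
    rng = np.random.default_rng(5)
    genes = [f"G{i}" for i in range(6)]
    samples = [f"S{i}" for i in range(8)]
    return ExpressionMatrix(genes, samples, rng.uniform(0, 100, (6, 8)), "tpm")


@pytest.fixture
def clinical_factory():
    def build(sample_ids, os_months=None, os_event=None, purity=None):
        n = len(sample_ids)
        return ClinicalTable(pd.DataFrame({
            "sample_id": sample_ids,
            "os_months": os_months if os_months is not None else [12.0] * n,
            "os_event": os_event if os_event is not None else [1] * n,
            "purity": purity if purity is not None else [0.8] * n,
        }))
    return build


@pytest.fixture
def two_gene_sets():
    gly = GeneSet("GLY", tuple(f"GLY{i:03d}" for i in range(1, 30)))
    chol = GeneSet("CHOL", tuple(f"CHOL{i:03d}" for i in range(1, 25)))
    return gly, chol
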