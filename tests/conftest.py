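import numpy as np
import pytest

from mrorient import SummaryDataset


@pytest.fixture
def toy_dataset() -> SummaryDataset:
    """Small fixed dataset with unequal weights and allele labels."""
    return SummaryDataset(
        snp_id=np.array(["rs1", "rs2", "rs3", "rs4"], dtype=object),
        beta_exposure=np.array([0.12, -0.21, 0.33, 0.08]),
        se_exposure=np.array([0.01, 0.015, 0.02, 0.012]),
        beta_outcome=np.array([0.05, -0.02, 0.09, 0.01]),
        se_outcome=np.array([0.1, 0.2, 0.1, 0.15]),
        effect_allele=np.array(["A", "C", "G", "T"], dtype=object),
        other_allele=np.array(["G", "T", "A", "C"], dtype=object),
    )


def random_dataset(rng: np.random.Generator, m: int = 6) -> SummaryDataset:
    """Generic dataset with mixed-sign exposure betas and unequal SEs."""
    return SummaryDataset(
        snp_id=np.array([f"rs{i}" for i in range(m)], dtype=object),
        beta_exposure=rng.normal(0.0, 0.2, m),
        se_exposure=rng.uniform(0.005, 0.02, m),
        beta_outcome=rng.normal(0.0, 0.1, m),
        se_outcome=rng.uniform(0.05, 0.3, m),
    )
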