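import numpy as np
import pytest

from progsat import CohortData, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> CohortData:
    """60 samples x 40 genes with common mutations and ~50% events."""
    cfg = SimulationConfig(
        n_samples=60,
        n_genes=40,
        freq_min=0.1,
        freq_max=0.5,
        freq_shape=1.0,
        n_prognostic=2,
        hazard_ratio=2.0,
        prognostic_freq=0.3,
        median_survival_months=30.0,
        accrual_months=24.0,
        followup_months=18.0,
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_cohort() -> CohortData:
    """Hand-built 6-sample, 3-gene cohort with known times and statuses."""
    return CohortData(
        sample_ids=[f"S{i}" for i in range(1, 7)],
        gene_ids=["TP53", "NOTCH1", "ZNF750"],
        mutation_matrix=np.array(
            [
                [1, 0, 0],
                [1, 1, 0],
                [0, 1, 0],
                [0, 0, 1],
                [1, 0, 1],
                [0, 1, 1],
            ]
        ),
        time_months=np.array([3.0, 7.5, 12.0, 12.0, 20.0, 28.0]),
        status=np.array([1, 1, 0, 1, 1, 0]),
        stage_label="II",
    )
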