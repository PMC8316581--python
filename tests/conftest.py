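import numpy as np
import pytest

from comosub import (
    ExpressionDataset,
    SimulationDesign,
    generate_disease_dataset,
    generate_paired_study,
)
from comosub.preprocess import log2_fold_change


@pytest.fixture(scope="session")
def small_design():
    """A compact planted cohort: quick to factorize, still well separated."""
    return SimulationDesign(
        n_genes=300,
        k_true=3,
        patients_per_cluster=[20, 20, 20],
        n_controls=20,
        effect_size=2.0,
        noise_sd=0.5,
        module_size=20,
        shared_candidate_size=10,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return generate_disease_dataset(small_design, "A")


@pytest.fixture(scope="session")
def small_fold_change(small_cohort):
    ds, _ = small_cohort
    return log2_fold_change(ds)


@pytest.fixture(scope="session")
def paired_study():
    """Default-scale paired study with a planted shared candidate set."""
    return generate_paired_study(SimulationDesign(seed=1), SimulationDesign(seed=2))


@pytest.fixture()
def tiny_dataset():
    rng = np.random.default_rng(0)
    return ExpressionDataset(
        gene_ids=[f"g{i}" for i in range(1, 6)],
        sample_ids=["p1", "p2", "p3", "c1", "c2"],
        values=rng.uniform(4, 10, size=(5, 5)),
        group=["patient"] * 3 + ["control"] * 2,
    )
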