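import numpy as np
import pytest

from famnet.synthetic import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def demo_config():
    return CohortConfig(
        seed=11,
        n_family_genes=20,
        n_background_genes=200,
        n_cancer=60,
        n_normal=40,
        planted_pairs=[("FAM001", "FAM002", 0.9, 0.0),
                       ("FAM003", "FAM004", -0.5, 0.5)],
        de_genes=[("FAM005", 3.0), ("FAM006", -2.5)],
        methylation_de_genes=[("FAM007", 1.5), ("FAM008", -1.5)],
        survival_gene="FAM009",
        survival_log_hr=float(np.log(2)),
        drug_couplings=[("FAM010", "drugA", 0.8, 0.5),
                        ("FAM011", "drugB", -0.6, 0.5)],
        noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def demo_cohort(demo_config):
    return generate_cohort(demo_config)
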