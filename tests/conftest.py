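import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pmenet.synthetic import SyntheticConfig, generate_study
from pmenet.tables import FeatureTable

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def toy_table() -> FeatureTable:
    """4 features x 6 samples, annotated, with simple integer counts."""
    values = pd.DataFrame(
        [
            [5, 0, 3, 2, 0, 1],
            [1, 1, 1, 1, 1, 1],
            [0, 4, 0, 0, 4, 0],
            [2, 2, 2, 2, 2, 2],
        ],
        index=["f1", "f2", "f3", "f4"],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    annotation = {
        "f1": "Bacteria;Acidobacteria;Acidobacteriia",
        "f2": "Bacteria;Proteobacteria;Betaproteobacteria",
        "f3": "Bacteria;Proteobacteria;Deltaproteobacteria",
        "f4": "Bacteria;Acidobacteria;Holophagae",
    }
    return FeatureTable(values, feature_annotation=annotation)


@pytest.fixture(scope="session")
def default_study() -> dict:
    """One synthetic 48-sample study with planted modules and couplings."""
    cfg = SyntheticConfig(
        n_taxa=20, n_gene_categories=10, n_modules=4, coupling_strength=0.9,
        sequencing_depth=10000, seed=11,
    )
    return generate_study(cfg) | {"config": cfg}


def two_block_config(seed: int, n_samples: int = 500) -> SyntheticConfig:
    """The planted 2-block recovery scenario: two guilds of 20 taxa at
    within-module correlation 0.9 in a 120-taxon community."""
    return SyntheticConfig(
        n_soil_types=1, n_layers=1, n_stages=1, n_replicates=n_samples,
        n_taxa=120, n_background_taxa=80, n_modules=2,
        within_module_rho=0.9, means_sd=0.5, sequencing_depth=10000, seed=seed,
    )


def rand_index(labels_a, labels_b) -> float:
    """Unadjusted Rand index between two labelings (pair-counting)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    agree = 0
    for i in range(n):
        same_a = a[i + 1 :] == a[i]
        same_b = b[i + 1 :] == b[i]
        agree += int((same_a == same_b).sum())
    total = n * (n - 1) // 2
    return agree / total if total else 1.0
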