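import numpy as np
import pandas as pd
import pytest

from gutmwas.simulate import CohortDesign, simulate_gene_catalog, simulate_taxon_table


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(
        n_per_group=40,
        n_genes=400,
        n_clusters=4,
        cluster_size_range=(55, 65),
        noise_sd=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def species_table(small_design):
    table, truth = simulate_taxon_table(small_design, "species")
    return table, truth


@pytest.fixture(scope="session")
def gene_catalog(small_design):
    return simulate_gene_catalog(small_design)


def basis_pair_fractions(seed, rho=0.8, n_features=50, n_samples=200):
    """Compositional data from a log-normal basis with one correlated pair."""
    rng = np.random.default_rng(seed)
    logw = rng.normal(0.0, 1.0, size=(n_features, n_samples))
    logw[1] = rho * logw[0] + np.sqrt(1 - rho**2) * rng.normal(size=n_samples)
    w = np.exp(logw)
    return w / w.sum(axis=0)
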