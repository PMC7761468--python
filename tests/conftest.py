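import numpy as np
import pytest

from bsaseq import synthetic as syn


@pytest.fixture(scope="session")
def parents():
    """Small two-chromosome parental pair shared across tests."""
    return syn.generate_parents(
        n_chrom=2, chrom_length=30_000, n_sites=80, n_genes=8, seed=7
    )


@pytest.fixture(scope="session")
def population(parents):
    """285-line BC2F9 population on the shared parents."""
    return syn.simulate_population(
        parents, n_individuals=285, n_backcrosses=2,
        n_selfing_generations=9, recomb_rate=1.0, seed=11,
    )


@pytest.fixture(scope="session")
def phenotyped(parents, population):
    archs = syn.default_architectures(parents, seed=13)
    syn.assign_phenotypes(population, archs, seed=17)
    return population, archs


def cluster_se(values_2d: np.ndarray) -> tuple[float, float]:
    """(mean, SE) of a per-genotype indicator, clustering on individuals:
    linked sites within a line are correlated, so the individual is the
    sampling unit."""
    per_ind = values_2d.mean(axis=1)
    return float(per_ind.mean()), float(per_ind.std(ddof=1) / np.sqrt(len(per_ind)))
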