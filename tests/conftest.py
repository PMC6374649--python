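import numpy as np
import pytest

from nestkin.genotypes import AlleleFrequencies, MultilocusGenotype
from nestkin.simulate import (
    SimulationConfig,
    apply_genotyping_error,
    simulate_population,
    simulate_workers,
)


@pytest.fixture(scope="session")
def uniform_freqs() -> AlleleFrequencies:
    """Five loci, 4-6 equifrequent alleles each."""
    tables = {}
    for i, k in enumerate((4, 5, 6, 4, 5)):
        tables[f"L{i + 1}"] = {100 + 2 * j: 1.0 / k for j in range(k)}
    return AlleleFrequencies(tables)


@pytest.fixture(scope="session")
def standard_scenario():
    """30 colonies x 5 workers, 14 informative loci, 2% mistyping.

    Returns (population, worker observations, observed genotypes, truth map).
    """
    cfg = SimulationConfig(
        n_colonies=(30, 1),
        n_loci=14,
        min_alleles=5,
        max_alleles=10,
        workers_per_colony_mean=5,
        workers_per_colony_dist="constant",
        mistyping_rate=0.02,
        missing_rate=0.0,
        square_cap=10**6,
        kernel_mean_m=100.0,
    )
    pop = simulate_population(cfg, seed=11)
    workers = [w for w in simulate_workers(pop, cfg, seed=12) if w.year == 2014]
    observed = apply_genotyping_error(
        [w.genotype for w in workers], pop.freqs, 0.02, 0.0, seed=13
    )
    truth = {w.worker_id: w.true_colony for w in workers}
    return pop, workers, observed, truth


def diploid(ind_id: str, **calls) -> MultilocusGenotype:
    return MultilocusGenotype(ind_id, calls)
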