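import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from ailqtl import (DietSchedule, GenotypeMatrix, MarkerMap, PhenotypeSeries,
                    QtlSpec, SimConfig, simulate_dataset)


@pytest.fixture
def tiny_geno() -> GenotypeMatrix:
    """Three markers x six animals, all classes present at each marker."""
    mm = MarkerMap.from_records([
        ("m1", "chr1", 100), ("m2", "chr1", 200), ("m3", "chr2", 150)])
    calls = np.array([[0, 0, 1, 1, 2, 2],
                      [2, 2, 1, 1, 0, 0],
                      [0, 1, 2, 0, 1, 2]], dtype=np.int8)
    return GenotypeMatrix(mm, [f"a{i}" for i in range(1, 7)], calls)


@pytest.fixture
def small_sim():
    """Small but realistic AIL dataset with one QTL, shared across tests."""
    cfg = SimConfig(seed=11, n_animals=200, n_generations=10, pop_size=60,
                    chromosomes=[("chr1", 100_000_000, 60),
                                 ("chr2", 100_000_000, 60)],
                    qtls=[QtlSpec("chr1", 50_000_000, 2.7)],
                    selective_n=120)
    geno, pheno, truth = simulate_dataset(cfg)
    return cfg, geno, pheno, truth


@pytest.fixture
def weekly_pheno() -> PhenotypeSeries:
    rng = np.random.default_rng(5)
    weights = rng.uniform(20, 40, size=(8, 3))
    return PhenotypeSeries([f"a{i}" for i in range(8)], [3, 4, 5], weights)
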