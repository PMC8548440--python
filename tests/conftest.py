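"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from isodist.simulate import (PlantedRegion, ScenarioParams, simulate_scenario,
                              worked_fixture)


def null_params(seed, n_sites=2000, n_per_pop=20):
    """Two exchangeable populations: no bottleneck, no inbreeding."""
    return ScenarioParams(
        n_sites=n_sites, chrom_lengths=tuple([25_000_000] * 4),
        n_ref=n_per_pop, n_iso=n_per_pop, bottleneck_generations=0,
        inbreeding_f=0.0, planted=None, unknown_ancestral_frac=0.0,
        seed=seed)


@pytest.fixture(scope="session")
def null_scenario():
    return simulate_scenario(null_params(seed=11, n_sites=4000))


@pytest.fixture(scope="session")
def contrast_scenario():
    """Reduced-size isolate-vs-reference contrast for unit tests."""
    return simulate_scenario(ScenarioParams(
        n_sites=8000, chrom_lengths=tuple([25_000_000] * 4), seed=5))


@pytest.fixture(scope="session")
def fixture_data():
    return worked_fixture()


def random_matrix(rng, n_samples, n_sites, missing_frac=0.0, polarized=True):
    """Random dosage matrix for oracle comparisons."""
    from isodist.store import MISSING, GenotypeMatrix

    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    d = rng.binomial(2, freqs, size=(n_samples, n_sites)).astype(np.int8)
    if missing_frac > 0:
        mask = rng.random(d.shape) < missing_frac
        d[mask] = MISSING
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_samples)], dosage=d,
        polarized=polarized)
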