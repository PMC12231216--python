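import numpy as np
import pandas as pd
import pytest

import envenomap as em
from envenomap import synthetic as syn


@pytest.fixture(scope="session")
def small_grid():
    """60x60 geographic grid at ~1 km resolution."""
    return em.GridSpec(60, 60, 48.0, 32.0, 1.0 / 120.0, "EPSG:4326")


@pytest.fixture(scope="session")
def landscape(small_grid):
    return syn.simulate_landscape(small_grid, n_layers=4, n_regions=3, n_cities=5, seed=7)


@pytest.fixture(scope="session")
def species_truth(landscape):
    return syn.define_virtual_species(landscape.env, syn.DEFAULT_SPECIES_COEFFICIENTS)


@pytest.fixture(scope="session")
def species_table(landscape, species_truth):
    """Weighted training table for a strong virtual species (desk scale)."""
    pts = syn.sample_occurrences(species_truth, n=120, seed=21)
    occ = em.thin_occurrences(em.OccurrenceSet("virtual", pts), 1.0, seed=22)
    labels = em.occupied_ecoregions(occ, landscape.ecoregions)
    bg = em.generate_pseudo_absences(landscape.ecoregions, labels, occ, n=800, seed=23)
    return em.assemble_training_table(occ, bg, landscape.env)


@pytest.fixture(scope="session")
def separable_table():
    """Toy table linearly separable in the first layer."""
    rng = np.random.default_rng(5)
    n = 40
    x1 = np.concatenate([rng.uniform(2, 3, n // 2), rng.uniform(-3, -2, n // 2)])
    x2 = rng.normal(size=n)
    y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
    df = pd.DataFrame(
        {
            "response": y,
            "weight": 1.0,
            "lon": rng.uniform(0, 1, n),
            "lat": rng.uniform(0, 1, n),
            "L1": x1,
            "L2": x2,
        }
    )
    return em.TrainingTable(df, "toy", ["L1", "L2"])
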