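"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from farmbayes import simdata

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from farmbayes.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def small_genotypes() -> GenotypeMatrix:
    """300 animals x 400 markers, admixed, fixed seed."""
    return simdata.simulate_genotypes(300, 400, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """One full synthetic dataset at smoke scale (h2=0.5, farm size 5)."""
    return simdata.simulate_dataset(300, 400, 60, h2=0.5, mean_farm_size=5.0, seed=21)


def make_td_records(
    n_cows=120,
    n_cdc=4,
    n_farms=30,
    n_seasons=3,
    records_per_cow=6,
    cdc_effects=None,
    season_effects=None,
    parity_effects=None,
    curve=None,
    noise_sd=0.5,
    seed=0,
):
    """Synthetic test-day records with known fixed effects and lactation curve.

    ``curve`` maps parity -> Legendre coefficients (P1..P3) on x in [-1, 1];
    the generating model is yield = 10 + cdc + season + parity + curve(dim).
    """
    rng = np.random.default_rng(seed)
    cdc_effects = cdc_effects if cdc_effects is not None else np.zeros(n_cdc)
    season_effects = season_effects if season_effects is not None else np.zeros(n_seasons)
    parity_effects = parity_effects if parity_effects is not None else np.zeros(3)
    rows = []
    for cow in range(n_cows):
        cdc = cow % n_cdc
        farm = cow % n_farms
        parity = 1 + (cow % 3)
        for _ in range(records_per_cow):
            dim = rng.uniform(5.0, 305.0)
            x = 2 * (dim - 5.0) / 300.0 - 1.0
            base = 10.0 + cdc_effects[cdc] + parity_effects[parity - 1]
            season = int(rng.integers(n_seasons))
            base += season_effects[season]
            if curve is not None:
                c = curve[parity]
                base += c[0] * x + c[1] * (1.5 * x**2 - 0.5) + c[2] * (2.5 * x**3 - 1.5 * x)
            rows.append(
                dict(cow_id=f"cow{cow:03d}", farm_id=f"farm{farm:02d}",
                     cdc_id=f"cdc{cdc}", season=f"s{season}", parity=parity,
                     dim=dim, **{"yield": base + rng.normal(0, noise_sd)})
            )
    return pd.DataFrame(rows)
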