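import numpy as np
import pytest

from pedavoid import (
    DemographyConfig,
    FounderConfig,
    MateChoiceModel,
    build_pedigree,
    simulate_population,
)


def random_pedigree(rng, n=30, p_parents=0.7):
    """A random valid pedigree: individuals arrive in birth order and pick
    parents among earlier arrivals of the right sex."""
    records = []
    males, females = [], []
    for i in range(n):
        iid = f"I{i:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        sire = dam = None
        if males and females and rng.random() < p_parents:
            sire = males[int(rng.integers(len(males)))]
            dam = females[int(rng.integers(len(females)))]
        records.append(dict(id=iid, sire=sire, dam=dam, sex=sex))
        (males if sex == "M" else females).append(iid)
    return build_pedigree(records)


SMALL_FOUNDERS = FounderConfig(n_founders=80, n_adult_females=30,
                               n_adult_males=12, n_groups=3, n_loci=12)
SMALL_DEMOGRAPHY = DemographyConfig(n_years=12, birth_probability=0.5)


@pytest.fixture(scope="session")
def sim_population():
    """One random-mating synthetic population shared across tests."""
    return simulate_population(SMALL_FOUNDERS, SMALL_DEMOGRAPHY,
                               MateChoiceModel(theta=0.0), seed=20240901)


@pytest.fixture(scope="session")
def sim_population_genotyped():
    """A population large enough for estimator-vs-F correlation checks,
    with enough generations to accumulate inbred lineages."""
    founders = FounderConfig(n_founders=60, n_adult_females=24,
                             n_adult_males=8, n_groups=2, n_loci=30)
    demog = DemographyConfig(n_years=18, birth_probability=0.5)
    return simulate_population(founders, demog, MateChoiceModel(theta=0.0),
                               seed=20240902)
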