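import numpy as np
import pandas as pd
import pytest

from phyletica import OrganismRecord, TraitMatrix
from phyletica.simulate import ScenarioParams, simulate_repertoires


@pytest.fixture
def toy_records():
    """Two organisms per superkingdom, all free-living, full coverage."""
    return [
        OrganismRecord("arc1", "A", "free_living", 1.0),
        OrganismRecord("arc2", "A", "free_living", 1.0),
        OrganismRecord("bac1", "B", "free_living", 1.0),
        OrganismRecord("bac2", "B", "free_living", 1.0),
        OrganismRecord("euk1", "E", "free_living", 1.0),
        OrganismRecord("euk2", "E", "free_living", 1.0),
    ]


@pytest.fixture
def toy_matrix(toy_records):
    """Five traits covering ABE, BE, A, E and AB groups."""
    orgs = [r.organism_id for r in toy_records]
    data = pd.DataFrame(
        [
            [2, 1, 5, 3, 4, 1],  # everywhere -> ABE
            [0, 0, 1, 0, 9, 8],  # one bacterium + eukarya -> BE
            [3, 0, 0, 0, 0, 0],  # single archaeon -> A
            [0, 0, 0, 0, 2, 2],  # eukarya only -> E
            [1, 1, 1, 1, 0, 0],  # akaryotes -> AB
        ],
        index=["t1", "t2", "t3", "t4", "t5"],
        columns=orgs,
    )
    return TraitMatrix(data)


def small_params(**overrides) -> ScenarioParams:
    """Scaled-down scenario used throughout the suite (seconds, not minutes)."""
    defaults = dict(
        n_organisms=(12, 40, 20),
        n_core=60,
        n_specific=(4, 15, 20),
        n_hgt=8,
        seed=7,
    )
    defaults.update(overrides)
    return ScenarioParams(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulation at default noise levels."""
    params = small_params()
    return (params,) + simulate_repertoires(params)


def random_matrix(rng: np.random.Generator, n_traits: int, n_orgs: int):
    """Random sparse matrix + metadata with organisms spread over A/B/E."""
    sks = rng.choice(list("ABE"), size=n_orgs)
    # guarantee every superkingdom is populated
    sks[:3] = ["A", "B", "E"]
    orgs = [f"{sk}{i:03d}" for i, sk in enumerate(sks)]
    records = [OrganismRecord(o, sk, "free_living", 1.0) for o, sk in zip(orgs, sks)]
    counts = rng.integers(0, 4, size=(n_traits, n_orgs)) * (
        rng.random((n_traits, n_orgs)) < 0.4
    )
    # every trait occurs somewhere
    for i in range(n_traits):
        if not counts[i].any():
            counts[i, rng.integers(n_orgs)] = 1
    df = pd.DataFrame(
        counts.astype(int),
        index=[f"tr{i:04d}" for i in range(n_traits)],
        columns=orgs,
    )
    return TraitMatrix(df), records
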