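import numpy as np
import pandas as pd
import pytest

from fdassembly.core_data import (
    CommunityMatrix,
    EnvironmentTable,
    TraitTable,
    default_codebook,
)


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture
def toy_traits(codebook):
    df = pd.DataFrame(
        {
            "size_class": ["<200", "200-600", ">600", "200-600"],
            "feeding_type": ["microphagous", "D_filtration", "tactile_raptorial",
                             "B_filtration"],
            "trophic_group": ["herbivorous", "herbivorous", "omnivorous",
                              "detritivorous"],
            "habitat": ["littoral", "pelagic", "pelagic", "littoral"],
        },
        index=["sp1", "sp2", "sp3", "sp4"],
    )
    return TraitTable(df, codebook)


@pytest.fixture
def toy_incidence():
    df = pd.DataFrame(
        [[1, 1, 0, 1], [1, 0, 1, 1], [0, 1, 1, 1]],
        index=["s1", "s2", "s3"],
        columns=["sp1", "sp2", "sp3", "sp4"],
        dtype=float,
    )
    return CommunityMatrix(df, mode="incidence")


@pytest.fixture
def toy_biomass():
    df = pd.DataFrame(
        [[10.0, 30.0, 0.0, 60.0], [5.0, 0.0, 20.0, 25.0], [0.0, 8.0, 4.0, 8.0]],
        index=["s1", "s2", "s3"],
        columns=["sp1", "sp2", "sp3", "sp4"],
    )
    return CommunityMatrix(df, mode="biomass")


@pytest.fixture
def toy_env():
    df = pd.DataFrame(
        {"TP": [80.0, 150.0, 420.0], "pond": ["a", "b", "c"], "month": [7, 7, 7]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return EnvironmentTable(df)


@pytest.fixture
def toy_csvs(tmp_path, toy_incidence, toy_biomass, toy_traits, toy_env):
    paths = {
        "incidence": tmp_path / "incidence.csv",
        "biomass": tmp_path / "biomass.csv",
        "traits": tmp_path / "traits.csv",
        "env": tmp_path / "env.csv",
    }
    toy_incidence.data.to_csv(paths["incidence"])
    toy_biomass.data.to_csv(paths["biomass"])
    toy_traits.data.to_csv(paths["traits"])
    toy_env.data.to_csv(paths["env"])
    return paths


def random_trait_frame(rng: np.random.Generator, n: int, codebook) -> pd.DataFrame:
    data = {
        t.name: rng.choice(t.categories, size=n) for t in codebook.traits
    }
    return pd.DataFrame(data, index=[f"sp{i}" for i in range(n)])
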