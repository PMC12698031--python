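"""Generator of fishpond-like survey datasets with a known assembly regime.

The default design mirrors a small pond survey: 9 ponds sampled monthly
March-September (incidence; 63 samples), with biomass quantified
July-September only (27 samples), a 59-species pool over the 17-category
trait codebook, and a total-phosphorus (TP) gradient spanning eutrophic to
highly hypereutrophic ponds.

Three assembly regimes:

* ``neutral`` - occupancy independent of traits and TP;
* ``filtering`` - occupancy and biomass weighted by a Gaussian tolerance
  kernel around each species' TP optimum (log10 scale, breadth ``sigma``);
* ``limiting_similarity`` - colonizers are rejected while their Gower
  distance to every resident is below ``theta``.

TP optima are a deterministic function of the trait syndrome: tactile
raptorial feeders and omnivores sit high on the gradient, stationary
suspension feeders, D-filtration feeders and herbivores sit low.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    CommunityMatrix,
    EnvironmentTable,
    TraitCodebook,
    TraitTable,
    ValidationError,
    default_codebook,
    write_community,
    write_environment,
    write_traits,
)
from .trait_space import gower_dissimilarity

logger = logging.getLogger(__name__)

REGIMES = ("neutral", "filtering", "limiting_similarity")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic survey design."""

    n_ponds: int = 9
    months: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)
    quantitative_months: tuple[int, ...] = (7, 8, 9)
    pool_size: int = 59
    regime: str = "neutral"
    filter_sigma: float = 0.3  # tolerance breadth on log10(TP)
    similarity_theta: float = 0.25  # min nearest-neighbour Gower distance
    tp_range: tuple[float, float] = (50.0, 600.0)
    occupancy: float = 0.45  # baseline per-species occurrence probability
    biomass_meanlog: float = 1.0  # natural-log lognormal parameters
    biomass_sdlog: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size < 5:
            raise ValidationError("pool_size must be >= 5")
        if not self.tp_range[0] < self.tp_range[1]:
            raise ValidationError("tp_range must be increasing")
        if self.tp_range[0] <= 0:
            raise ValidationError("tp_range must be positive")
        if self.filter_sigma <= 0:
            raise ValidationError("filter_sigma must be > 0")
        if not 0 <= self.similarity_theta < 1:
            raise ValidationError("similarity_theta must be in [0, 1)")
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}")
        if not set(self.quantitative_months) <= set(self.months):
            raise ValidationError("quantitative months must be a subset of months")
        if not 0 < self.occupancy <= 1:
            raise ValidationError("occupancy must be in (0, 1]")


def default_study_design(**overrides) -> SyntheticConfig:
    """The default 9-pond March-September design (63 + 27 samples)."""
    return dataclasses.replace(SyntheticConfig(), **overrides)


@dataclass(frozen=True)
class SpeciesPool:
    """Trait table plus per-species TP optimum (log10 ug/L)."""

    traits: TraitTable
    tp_optimum: pd.Series  # log10 scale, indexed by species id


# Archetype -> (probability, per-trait category weight tables).  Rotifer-like
# small microphagous species dominate the pool, as in typical pond surveys.
_ARCHETYPES: list[tuple[str, float, dict[str, dict[str, float]]]] = [
    ("rotifer", 0.50, {
        "size_class": {"<200": 0.8, "200-600": 0.2},
        "feeding_type": {"microphagous": 0.7, "raptorial_rotifer": 0.3},
        "trophic_group": {"herbivorous": 0.55, "detritivorous": 0.2, "omnivorous": 0.25},
        "habitat": {"littoral": 0.5, "pelagic": 0.5},
    }),
    ("cladoceran", 0.32, {
        "size_class": {"<200": 0.1, "200-600": 0.55, ">600": 0.35},
        "feeding_type": {"D_filtration": 0.35, "B_filtration": 0.25,
                         "C_filtration": 0.25, "S_filtration": 0.15},
        "trophic_group": {"herbivorous": 0.85, "detritivorous": 0.15},
        "habitat": {"littoral": 0.45, "pelagic": 0.55},
    }),
    ("calanoid", 0.05, {
        "size_class": {">600": 1.0},
        "feeding_type": {"stationary_suspension": 1.0},
        "trophic_group": {"herbivorous": 0.9, "omnivorous": 0.1},
        "habitat": {"pelagic": 1.0},
    }),
    ("cyclopoid", 0.13, {
        "size_class": {"200-600": 0.35, ">600": 0.65},
        "feeding_type": {"tactile_raptorial": 1.0},
        "trophic_group": {"omnivorous": 0.6, "carnivorous": 0.4},
        "habitat": {"littoral": 0.3, "pelagic": 0.7},
    }),
]

# Trait syndrome -> TP-optimum percentile adjustments (log10 gradient).
# Tactile-raptorial feeders and omnivores sit high on the gradient;
# stationary suspension feeders, D-filtration feeders and herbivores low.
_OPT_BASE = 0.5
_OPT_RULES: list[tuple[str, str, float]] = [
    ("feeding_type", "tactile_raptorial", +0.42),
    ("trophic_group", "omnivorous", +0.25),
    ("trophic_group", "carnivorous", +0.12),
    ("feeding_type", "stationary_suspension", -0.42),
    ("feeding_type", "D_filtration", -0.35),
    ("feeding_type", "microphagous", -0.15),
    ("feeding_type", "raptorial_rotifer", -0.15),
    ("trophic_group", "herbivorous", -0.18),
]

#: optima may extend this far (log10 units) beyond the TP range ends
_OPT_MARGIN = 0.3


def _draw(rng: np.random.Generator, table: dict[str, float]) -> str:
    cats = list(table)
    probs = np.array([table[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def optimum_percentile(trait_row: pd.Series) -> float:
    """Deterministic syndrome -> TP-optimum percentile map (before jitter)."""
    pct = _OPT_BASE
    for trait, cat, delta in _OPT_RULES:
        if trait_row[trait] == cat:
            pct += delta
    return float(np.clip(pct, 0.05, 0.95))


def generate_species_pool(
    config: SyntheticConfig, codebook: TraitCodebook | None = None
) -> SpeciesPool:
    """Sample a trait table over the codebook and assign TP optima."""
    codebook = codebook or default_codebook()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    width = max(2, len(str(config.pool_size)))
    species = [f"sp{i + 1:0{width}d}" for i in range(config.pool_size)]
    arch_probs = np.array([p for _, p, _ in _ARCHETYPES])
    rows = {}
    for sid in species:
        _, _, tables = _ARCHETYPES[rng.choice(len(_ARCHETYPES), p=arch_probs)]
        rows[sid] = {t: _draw(rng, tables[t]) for t in codebook.trait_names}
    traits = TraitTable(pd.DataFrame.from_dict(rows, orient="index"), codebook)

    lo, hi = np.log10(config.tp_range[0]), np.log10(config.tp_range[1])
    span_lo, span_hi = lo - _OPT_MARGIN, hi + _OPT_MARGIN
    opts = {}
    for sid in species:
        pct = optimum_percentile(traits.data.loc[sid])
        opt = span_lo + pct * (span_hi - span_lo) + rng.normal(0.0, 0.04)
        opts[sid] = float(np.clip(opt, span_lo, span_hi))
    return SpeciesPool(traits, pd.Series(opts, name="tp_optimum_log10"))


def tp_gradient(config: SyntheticConfig) -> EnvironmentTable:
    """Pond x month environment table with a log-spread TP gradient.

    Pond baselines are evenly log-spaced across ``tp_range`` (small seeded
    jitter), with a mild seasonal rise March-August that plateaus in
    September; pond ordering is preserved across months.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    lo, hi = np.log10(config.tp_range[0]), np.log10(config.tp_range[1])
    base = np.linspace(lo, hi, config.n_ponds) if config.n_ponds > 1 else np.array([(lo + hi) / 2])
    base = base + rng.normal(0.0, 0.02, size=config.n_ponds)
    records = []
    for p in range(config.n_ponds):
        pond = f"pond{p + 1:02d}"
        for month in config.months:
            season = 0.03 * (min(month, 8) - min(config.months))
            log_tp = base[p] + season + rng.normal(0.0, 0.01)
            sid = f"{pond}_m{month:02d}"
            records.append((sid, 10.0 ** log_tp, pond, month))
    df = pd.DataFrame(records, columns=["sample_id", "TP", "pond", "month"])
    return EnvironmentTable(df.set_index("sample_id"))


def _assemble_presence(
    rng: np.random.Generator,
    log_tp: float,
    pool: SpeciesPool,
    gower: np.ndarray,
    config: SyntheticConfig,
) -> np.ndarray:
    n = len(pool.traits.species_ids)
    opts = pool.tp_optimum.to_numpy()
    for _ in range(10):
        if config.regime == "limiting_similarity":
            present = np.zeros(n, dtype=bool)
            for i in rng.permutation(n):
                if rng.random() >= config.occupancy:
                    continue
                resident = np.flatnonzero(present)
                if resident.size and gower[i, resident].min() < config.similarity_theta:
                    continue
                present[i] = True
        else:
            probs = np.full(n, config.occupancy)
            if config.regime == "filtering":
                probs = probs * np.exp(-((log_tp - opts) ** 2)
                                       / (2.0 * config.filter_sigma**2))
            present = rng.random(n) < probs
        if present.any():
            return present
    raise ValidationError("community remained empty after 10 assembly attempts")


def assemble_communities(
    pool: SpeciesPool,
    env: EnvironmentTable,
    config: SyntheticConfig,
) -> tuple[CommunityMatrix, CommunityMatrix]:
    """Draw incidence (all months) and biomass (quantitative months) matrices."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    species = pool.traits.species_ids
    gower = gower_dissimilarity(pool.traits).values
    opts = pool.tp_optimum.to_numpy()
    inc_rows, bio_rows, bio_ids = [], [], []
    for sid, row in env.data.iterrows():
        log_tp = np.log10(float(row["TP"]))
        present = _assemble_presence(rng, log_tp, pool, gower, config)
        inc_rows.append(present.astype(float))
        if int(row["month"]) in config.quantitative_months:
            biomass = np.zeros(len(species))
            idx = np.flatnonzero(present)
            b = rng.lognormal(config.biomass_meanlog, config.biomass_sdlog, size=idx.size)
            if config.regime == "filtering":
                b = b * np.exp(-((log_tp - opts[idx]) ** 2)
                               / (2.0 * config.filter_sigma**2))
            biomass[idx] = b
            bio_rows.append(biomass)
            bio_ids.append(sid)
    inc = CommunityMatrix(
        pd.DataFrame(inc_rows, index=env.data.index, columns=species), mode="incidence")
    bio = CommunityMatrix(
        pd.DataFrame(bio_rows, index=pd.Index(bio_ids, name="sample_id"),
                     columns=species), mode="biomass")
    return inc, bio


@dataclass(frozen=True)
class SyntheticDataset:
    config: SyntheticConfig
    pool: SpeciesPool
    env: EnvironmentTable
    incidence: CommunityMatrix
    biomass: CommunityMatrix

    def truth(self) -> dict:
        return {
            "regime": self.config.regime,
            "parameters": dataclasses.asdict(self.config),
            "seed": self.config.seed,
        }


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full draw: species pool, TP gradient, and both community matrices."""
    pool = generate_species_pool(config)
    env = tp_gradient(config)
    inc, bio = assemble_communities(pool, env, config)
    return SyntheticDataset(config, pool, env, inc, bio)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three loader CSVs plus a truth.json manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "incidence": out / "community_incidence.csv",
        "biomass": out / "community_biomass.csv",
        "traits": out / "traits.csv",
        "env": out / "environment.csv",
        "truth": out / "truth.json",
    }
    write_community(ds.incidence, paths["incidence"])
    write_community(ds.biomass, paths["biomass"])
    write_traits(ds.pool.traits, paths["traits"])
    write_environment(ds.env, paths["env"])
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth(), fh, indent=2)
    return paths
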