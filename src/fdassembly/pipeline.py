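"""End-to-end orchestration: load/simulate -> trait space -> metrics -> nulls
-> SES -> group tests -> assembly labels -> gradient trends."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_data import (
    CommunityMatrix,
    EnvironmentTable,
    TraitTable,
    ValidationError,
    default_codebook,
    filter_empty_samples,
    load_tables,
)
from .diversity_metrics import (
    FD_METRICS,
    MetricEngine,
    community_weighted_means,
    fd_profile,
    fd_profile_long,
)
from .null_models import assembly_calls, compute_ses, ses_trends
from .synthetic_community import SyntheticConfig, generate_dataset, write_dataset
from .trait_space import choose_m, gower_dissimilarity, min_richness_for_hulls, pcoa_embed

logger = logging.getLogger(__name__)

MIN_N_ITER = 100


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration; either file inputs or a synthetic design."""

    out_dir: str | Path = "fdassembly_out"
    community_path: str | Path | None = None  # incidence CSV
    biomass_path: str | Path | None = None
    trait_path: str | Path | None = None
    env_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    bases: tuple[str, ...] = ("incidence", "biomass")
    fd_metrics: tuple[str, ...] = FD_METRICS
    include_cwm_ses: bool = True
    n_iter: int = 999
    seed: int | None = None
    m_max: int = 4
    correction: str = "sqrt"
    grouping: tuple[str, ...] = ("entire", "trophic_state")
    rao_convention: str = "raw"

    def __post_init__(self) -> None:
        if self.n_iter < MIN_N_ITER:
            raise ValidationError(f"n_iter must be >= {MIN_N_ITER}")
        if self.seed is None:
            raise ValidationError("a seed is required for reproducible runs")
        have_files = self.trait_path is not None and self.env_path is not None and (
            self.community_path is not None or self.biomass_path is not None
        )
        if self.synthetic is None and not have_files:
            raise ValidationError("provide input CSV paths or a synthetic config")


def _load_inputs(config: PipelineConfig, out: Path):
    matrices: dict[str, CommunityMatrix] = {}
    if config.synthetic is not None:
        ds = generate_dataset(config.synthetic)
        write_dataset(ds, out / "inputs")
        traits, env = ds.pool.traits, ds.env
        matrices["incidence"] = ds.incidence
        matrices["biomass"] = ds.biomass
    else:
        traits = env = None
        if config.community_path is not None:
            inc, traits, env = load_tables(config.community_path, config.trait_path,
                                           config.env_path, mode="incidence")
            matrices["incidence"] = inc
        if config.biomass_path is not None:
            bio, traits_b, env_b = load_tables(config.biomass_path, config.trait_path,
                                               config.env_path, mode="biomass")
            matrices["biomass"] = bio
            traits, env = traits_b, env_b
    matrices = {b: m for b, m in matrices.items() if b in config.bases}
    if not matrices:
        raise ValidationError(f"no community matrix available for bases {config.bases}")
    for basis in list(matrices):
        filtered, dropped = filter_empty_samples(matrices[basis])
        if dropped:
            logger.warning("stage load: dropped empty %s samples: %s", basis, dropped)
        matrices[basis] = filtered
    return matrices, traits, env


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and write the output tables plus a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "package_version": __version__,
        "stages": {},
        "warnings": [],
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "wall_time_s": round(time.perf_counter() - t0, 3), **counts}

        return done

    done = stage("load")
    matrices, traits, env = _load_inputs(config, out)
    done(**{f"n_samples_{b}": len(m.sample_ids) for b, m in matrices.items()},
         n_species=len(traits.species_ids))

    done = stage("trait_space")
    pool_species = sorted(
        {s for m in matrices.values()
         for s, tot in zip(m.species_ids, m.values().sum(axis=0)) if tot > 0}
    )
    pool_traits = TraitTable(traits.data.loc[pool_species], traits.codebook)
    dmat = gower_dissimilarity(pool_traits)
    space = pcoa_embed(dmat, correction=config.correction, m_max=config.m_max)
    richness = [
        int(np.count_nonzero(row)) for m in matrices.values()
        for row in m.values() if np.count_nonzero(row) > 0
    ]
    m_axes = choose_m(space, min_richness_for_hulls(richness), config.m_max)
    engine = MetricEngine(dmat, space, m_axes, traits=pool_traits,
                          rao_convention=config.rao_convention)
    dmat.write_csv(out / "gower.csv")
    space.write_csv(out / "trait_space.csv")
    done(n_species=len(pool_species), m=m_axes, quality=space.quality)

    done = stage("metrics")
    profiles, cwm_frames = [], []
    for basis, m in matrices.items():
        profiles.append(fd_profile(m, engine, config.fd_metrics))
        cwm_frames.append(community_weighted_means(m, pool_traits).assign(basis=basis))
    fd_long = pd.concat([fd_profile_long(p) for p in profiles], ignore_index=True)
    cwm = pd.concat(cwm_frames, ignore_index=True)
    fd_long.to_csv(out / "fd_metrics.csv", index=False, float_format="%.10g")
    cwm.to_csv(out / "cwm.csv", index=False, float_format="%.10g")
    done(fd_rows=len(fd_long), cwm_rows=len(cwm))

    done = stage("null_models")
    ses_frames = []
    for basis, m in matrices.items():
        metrics = tuple(config.fd_metrics)
        if config.include_cwm_ses and basis == "biomass":
            metrics = metrics + engine.cwm_metrics
        ses_frames.append(
            compute_ses(m, engine, metrics, n_iter=config.n_iter, seed=config.seed)
        )
    ses = pd.concat(ses_frames, ignore_index=True)
    ses.to_csv(out / "ses.csv", index=False, float_format="%.10g")
    done(ses_rows=len(ses), n_iter=config.n_iter)

    done = stage("classification")
    calls = assembly_calls(ses, env, groupings=config.grouping)
    calls.to_csv(out / "assembly_calls.csv", index=False, float_format="%.10g")
    done(call_rows=len(calls))

    done = stage("trends")
    trends = ses_trends(ses, env)
    trends.to_csv(out / "trends.csv", index=False, float_format="%.10g")
    done(trend_rows=len(trends))

    manifest["row_counts"] = {
        "fd_metrics.csv": len(fd_long), "cwm.csv": len(cwm), "ses.csv": len(ses),
        "assembly_calls.csv": len(calls), "trends.csv": len(trends),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", out)
    return out
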