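"""Domain types, CSV I/O, validation, and basic transformations.

The three tables every analysis starts from:

* a sample x species community matrix (0/1 incidence or biomass),
* a species x trait table whose values are drawn from a closed codebook,
* a sample x environment table carrying the total-phosphorus gradient.

All loaders cross-validate the bundle (referential integrity between
community, traits and environment) before anything downstream runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TROPHIC_STATES = ("eutrophic", "hypereutrophic", "highly_hypereutrophic")

#: TP breakpoints (ug/L), half-open lower-inclusive intervals.
TP_BREAKS = (40.0, 100.0, 300.0)


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


# ---------------------------------------------------------------------------
# Trait codebook
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodebookTrait:
    """One trait: its name, kind (ordinal/categorical) and ordered categories."""

    name: str
    kind: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("ordinal", "categorical"):
            raise ValidationError(f"unknown trait kind {self.kind!r}")
        if len(set(self.categories)) != len(self.categories):
            raise ValidationError(f"duplicate categories in trait {self.name!r}")


@dataclass(frozen=True)
class TraitCodebook:
    """Closed vocabulary of trait categories.

    The default codebook covers four traits (one ordinal size class plus
    three categorical traits) with 17 categories in total.
    """

    traits: tuple[CodebookTrait, ...]

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    @property
    def n_categories(self) -> int:
        return sum(len(t.categories) for t in self.traits)

    def __getitem__(self, name: str) -> CodebookTrait:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def categories(self, name: str) -> tuple[str, ...]:
        return self[name].categories

    def pairs(self) -> list[tuple[str, str]]:
        """All (trait, category) pairs in codebook order."""
        return [(t.name, c) for t in self.traits for c in t.categories]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitCodebook":
        traits = []
        for name in df["trait"].unique():
            sub = df[df["trait"] == name]
            kinds = sub["kind"].unique()
            if len(kinds) != 1:
                raise ValidationError(f"trait {name!r} has mixed kinds {list(kinds)}")
            traits.append(CodebookTrait(name, kinds[0], tuple(sub["category"])))
        return cls(tuple(traits))

    @classmethod
    def default(cls) -> "TraitCodebook":
        ref = resources.files("fdassembly") / "data" / "trait_codebook.csv"
        with resources.as_file(ref) as path:
            return cls.from_frame(pd.read_csv(path))


_DEFAULT_CODEBOOK: TraitCodebook | None = None


def default_codebook() -> TraitCodebook:
    global _DEFAULT_CODEBOOK
    if _DEFAULT_CODEBOOK is None:
        _DEFAULT_CODEBOOK = TraitCodebook.default()
    return _DEFAULT_CODEBOOK


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitTable:
    """Species x trait assignments; every value must be a codebook category."""

    data: pd.DataFrame
    codebook: TraitCodebook = field(default_factory=default_codebook)

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species ids in trait table: {dup}")
        missing_cols = set(self.codebook.trait_names) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"trait table missing columns: {sorted(missing_cols)}")
        for name in self.codebook.trait_names:
            col = df[name]
            if col.isna().any():
                bad = df.index[col.isna()].tolist()
                raise ValidationError(f"missing {name!r} for species {bad}")
            allowed = set(self.codebook.categories(name))
            outside = col[~col.isin(allowed)]
            if len(outside):
                sp, val = outside.index[0], outside.iloc[0]
                raise ValidationError(
                    f"trait value {val!r} for species {sp!r} is not a "
                    f"{name!r} category (allowed: {sorted(allowed)})"
                )

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, species: list[str]) -> "TraitTable":
        return TraitTable(self.data.loc[species], self.codebook)


@dataclass(frozen=True)
class CommunityMatrix:
    """Sample x species matrix, either 0/1 incidence or non-negative biomass."""

    data: pd.DataFrame
    mode: str  # "incidence" | "biomass"
    transformed: str = "none"  # "none" | "hellinger"

    def __post_init__(self) -> None:
        if self.mode not in ("incidence", "biomass"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.transformed not in ("none", "hellinger"):
            raise ValidationError(f"unknown transform {self.transformed!r}")
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in community matrix")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate species ids in community matrix")
        vals = df.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError("community matrix contains missing values")
        if (vals < 0).any():
            raise ValidationError("community matrix contains negative values")
        if self.mode == "incidence" and not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("incidence matrix contains values other than 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row(self, sample_id: str) -> np.ndarray:
        return self.data.loc[sample_id].to_numpy(dtype=float)


@dataclass(frozen=True)
class EnvironmentTable:
    """Sample-level environment: TP (ug/L), pond, month, derived trophic state."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample ids in environment table")
        for col in ("TP", "pond", "month"):
            if col not in df.columns:
                raise ValidationError(f"environment table missing column {col!r}")
        tp = pd.to_numeric(df["TP"], errors="raise")
        if (tp <= 0).any():
            bad = df.index[tp <= 0].tolist()
            raise ValidationError(f"non-positive TP for samples {bad}")
        if "trophic_state" not in df.columns:
            object.__setattr__(
                self, "data", df.assign(trophic_state=[classify_trophic_state(v) for v in tp])
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def tp(self) -> pd.Series:
        return self.data["TP"].astype(float)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def classify_trophic_state(tp: float) -> str:
    """Map a TP concentration (ug/L) onto the three-level trophic scale.

    Intervals are half-open lower-inclusive: [40, 100) eutrophic,
    [100, 300) hypereutrophic, [300, inf) highly hypereutrophic.  Values
    below 40 are labelled eutrophic with a warning (below the gradient's
    lower end); non-positive TP is an error.
    """
    tp = float(tp)
    if tp <= 0 or not np.isfinite(tp):
        raise ValidationError(f"TP must be positive and finite, got {tp}")
    if tp < TP_BREAKS[0]:
        logger.warning("TP=%.3g ug/L is below the eutrophic range; labelling eutrophic", tp)
        return "eutrophic"
    if tp < TP_BREAKS[1]:
        return "eutrophic"
    if tp < TP_BREAKS[2]:
        return "hypereutrophic"
    return "highly_hypereutrophic"


def hellinger_transform(m: CommunityMatrix) -> CommunityMatrix:
    """Row-wise Hellinger transform: y'_ij = sqrt(y_ij / sum_j y_ij).

    Each output row has unit sum of squares; zeros are preserved.  Rows
    with zero total are an error (drop them first via
    :func:`filter_empty_samples`).
    """
    if m.mode != "biomass":
        raise ValidationError("Hellinger transform requires a biomass matrix")
    if m.transformed != "none":
        raise ValidationError("matrix already transformed")
    vals = m.values()
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValidationError(f"all-zero sample rows: {bad}; remove them explicitly first")
    out = np.sqrt(vals / totals[:, None])
    df = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return CommunityMatrix(df, mode="biomass", transformed="hellinger")


def relative_abundance(m: CommunityMatrix, sample_id: str) -> np.ndarray:
    """Per-sample weight vector summing to 1.

    Biomass rows are normalized by their total; incidence rows give each
    present species weight 1/S.
    """
    row = m.row(sample_id)
    total = row.sum()
    if total <= 0:
        raise ValidationError(f"sample {sample_id!r} is empty")
    return row / total


def filter_empty_samples(m: CommunityMatrix) -> tuple[CommunityMatrix, list[str]]:
    """Drop samples with zero row total, logging which were removed."""
    totals = m.values().sum(axis=1)
    keep = totals > 0
    dropped = [sid for sid, k in zip(m.sample_ids, keep) if not k]
    if dropped:
        logger.warning("dropping %d empty samples: %s", len(dropped), dropped)
    return CommunityMatrix(m.data.loc[keep], m.mode, m.transformed), dropped


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def load_community(path: str | Path, mode: str, transpose: bool = False) -> CommunityMatrix:
    df = _read_csv(path)
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityMatrix(df.astype(float), mode=mode)


def load_traits(path: str | Path, codebook: TraitCodebook | None = None) -> TraitTable:
    df = _read_csv(path)
    df.index = df.index.astype(str)
    return TraitTable(df, codebook or default_codebook())


def load_environment(path: str | Path) -> EnvironmentTable:
    df = _read_csv(path)
    df.index = df.index.astype(str)
    return EnvironmentTable(df)


def load_tables(
    community_path: str | Path,
    trait_path: str | Path,
    env_path: str | Path,
    mode: str,
    codebook: TraitCodebook | None = None,
    transpose_community: bool = False,
) -> tuple[CommunityMatrix, TraitTable, EnvironmentTable]:
    """Load and cross-validate the community/trait/environment bundle.

    Every species with a nonzero column total must appear in the trait
    table, and every community sample must have an environment row.
    """
    community = load_community(community_path, mode, transpose=transpose_community)
    traits = load_traits(trait_path, codebook)
    env = load_environment(env_path)

    present = community.values().sum(axis=0) > 0
    needed = {s for s, p in zip(community.species_ids, present) if p}
    missing = sorted(needed - set(traits.species_ids))
    if missing:
        raise ValidationError(
            f"species present in community but absent from trait table: {missing}"
        )
    extra_traits = sorted(set(traits.species_ids) - set(community.species_ids))
    if extra_traits:
        logger.info("trait table has %d species not in the community matrix: %s",
                    len(extra_traits), extra_traits)

    no_env = sorted(set(community.sample_ids) - set(env.sample_ids))
    if no_env:
        raise ValidationError(f"samples missing from environment table: {no_env}")
    extra_env = sorted(set(env.sample_ids) - set(community.sample_ids))
    if extra_env:
        logger.info("environment table has %d samples not in the community matrix",
                    len(extra_env))
    return community, traits, env


def write_community(m: CommunityMatrix, path: str | Path) -> None:
    m.data.to_csv(path, float_format="%.10g")


def write_traits(t: TraitTable, path: str | Path) -> None:
    t.data.to_csv(path)


def write_environment(e: EnvironmentTable, path: str | Path) -> None:
    e.data.to_csv(path, float_format="%.10g")
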