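"""Mixed-trait Gower dissimilarity and its principal-coordinates embedding.

Categorical traits contribute 0/1 per pair; ordinal traits use Podani's
tie-corrected rank method.  The resulting dissimilarities are embedded by
classical scaling (with an element-wise square-root correction by default)
to give the coordinate "trait space" that hull- and MST-based metrics
operate on.  The trait space is built once over the full species pool and
held fixed for observed and null communities alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import TraitCodebook, TraitTable, ValidationError, default_codebook

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric species x species dissimilarities in [0, 1]."""

    species_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = self.values
        n = len(self.species_ids)
        if d.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if np.abs(np.diag(d)).max(initial=0.0) > 1e-12:
            raise ValidationError("dissimilarity matrix has nonzero diagonal")
        if d.min(initial=0.0) < -1e-12 or d.max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("dissimilarities outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.species_ids),
                            columns=list(self.species_ids))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")


@dataclass(frozen=True)
class TraitSpace:
    """PCoA embedding of a dissimilarity matrix.

    ``coordinates`` holds all positive-eigenvalue axes (descending
    eigenvalue order); ``m`` is the default number of axes used by hull
    metrics.  ``quality`` is the fraction of positive-axis squared
    distance captured by the first ``m`` axes.
    """

    species_ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    m: int
    correction: str
    quality: float
    negative_share: float  # |sum of negative eigenvalues| / sum |eigenvalues|

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axes(self, m: int | None = None) -> np.ndarray:
        m = self.m if m is None else m
        if m > self.n_axes:
            raise ValidationError(f"requested {m} axes but only {self.n_axes} available")
        return self.coordinates[:, :m]

    def write_csv(self, path: str | Path) -> None:
        cols = [f"axis{i + 1}" for i in range(self.n_axes)]
        df = pd.DataFrame(self.coordinates, index=list(self.species_ids), columns=cols)
        with open(path, "w") as fh:
            fh.write("# eigenvalues," + ",".join(f"{v:.10g}" for v in self.eigenvalues) + "\n")
            fh.write(f"# correction,{self.correction}\n# m,{self.m}\n")
            df.to_csv(fh, float_format="%.10g")


def _ordinal_contribution(codes: np.ndarray) -> np.ndarray:
    """Podani (1999) tie-corrected rank dissimilarity for one ordinal column.

    d_ij = (|r_i - r_j| - (T_i - 1)/2 - (T_j - 1)/2)
           / (r_max - r_min - (T_max - 1)/2 - (T_min - 1)/2)

    where r are mid-ranks over the species set and T the tie counts.  With
    no ties this reduces to |rank_i - rank_j| / (rank_max - rank_min).
    Pairs sharing a category contribute 0.
    """
    n = codes.size
    uniq, counts = np.unique(codes, return_counts=True)
    if uniq.size == 1:
        return np.zeros((n, n))
    below = np.concatenate(([0], np.cumsum(counts)[:-1]))
    midrank_of = {u: b + (c + 1) / 2.0 for u, b, c in zip(uniq, below, counts)}
    tie_of = {u: c for u, c in zip(uniq, counts)}
    r = np.array([midrank_of[c] for c in codes])
    t = np.array([tie_of[c] for c in codes], dtype=float)
    t_min, t_max = counts[0], counts[-1]
    denom = (midrank_of[uniq[-1]] - midrank_of[uniq[0]]
             - (t_max - 1) / 2.0 - (t_min - 1) / 2.0)
    num = np.abs(r[:, None] - r[None, :]) - (t[:, None] - 1) / 2.0 - (t[None, :] - 1) / 2.0
    d = num / denom
    d[codes[:, None] == codes[None, :]] = 0.0
    return d


def gower_dissimilarity(
    traits: TraitTable, codebook: TraitCodebook | None = None
) -> DissimilarityMatrix:
    """Gower dissimilarity over the trait table's species.

    The pairwise dissimilarity is the unweighted mean of per-trait
    contributions: 0/1 for categorical traits, Podani tie-corrected rank
    differences for ordinal ones.  A trait with a single category across
    all species contributes 0 everywhere (logged, not an error).
    """
    codebook = codebook or traits.codebook
    species = traits.species_ids
    n = len(species)
    if n < 2:
        raise ValidationError("Gower dissimilarity needs at least two species")
    total = np.zeros((n, n))
    for cb_trait in codebook.traits:
        col = traits.data[cb_trait.name]
        if col.nunique() == 1:
            logger.info("trait %r has a single category; contributes 0 to all pairs",
                        cb_trait.name)
            continue
        if cb_trait.kind == "ordinal":
            codes = pd.Categorical(col, categories=cb_trait.categories, ordered=True).codes
            total += _ordinal_contribution(np.asarray(codes))
        else:
            vals = col.to_numpy()
            total += (vals[:, None] != vals[None, :]).astype(float)
    d = total / len(codebook.traits)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(tuple(species), d)


def pcoa_embed(
    d: DissimilarityMatrix,
    correction: str = "sqrt",
    m_max: int = 4,
) -> TraitSpace:
    """Classical scaling (PCoA) of (optionally corrected) dissimilarities.

    ``correction="sqrt"`` takes the element-wise square root before
    scaling (Gower dissimilarities become Euclidean-embeddable);
    ``"none"`` scales the raw values.  All positive-eigenvalue axes are
    kept in the coordinates; ``m = min(m_max, #positive axes)`` is the
    default axis count for hull metrics.
    """
    if correction not in ("sqrt", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    if m_max < 1:
        raise ValidationError("m_max must be >= 1")
    delta = np.sqrt(d.values) if correction == "sqrt" else d.values.copy()
    if not delta.any():
        raise ValidationError(
            "all-zero dissimilarity matrix (single functional point); "
            "deduplicate trait syndromes upstream"
        )
    n = delta.shape[0]
    a = -0.5 * delta**2
    b = a - a.mean(axis=0, keepdims=True) - a.mean(axis=1, keepdims=True) + a.mean()
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValidationError("no positive eigenvalues in PCoA")
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_sum = float(-eigval[eigval < -tol].sum())
    abs_sum = float(np.abs(eigval).sum())
    if neg_sum > tol:
        logger.info("PCoA: negative eigenvalues carry %.3g of total squared distance",
                    neg_sum / abs_sum)
    m = min(m_max, n_pos)
    quality = float(eigval[pos][:m].sum() / eigval[pos].sum())
    return TraitSpace(
        species_ids=d.species_ids,
        coordinates=coords,
        eigenvalues=eigval[pos],
        m=m,
        correction=correction,
        quality=quality,
        negative_share=neg_sum / abs_sum if abs_sum > 0 else 0.0,
    )


def choose_m(space: TraitSpace, min_richness: int, m_max: int = 4) -> int:
    """Axis count for hull metrics: min(m_max, s_min - 1, #positive axes).

    ``min_richness`` is the smallest species richness across the samples
    that will enter FRic, so every such sample's hull is computable in
    principle.  Samples below the hull-metric minimum (S < 3) never enter
    FRic and should be excluded from ``min_richness`` by the caller (see
    :func:`min_richness_for_hulls`).
    """
    return max(1, min(m_max, min_richness - 1, space.n_axes))


def min_richness_for_hulls(richness) -> int:
    """Smallest richness among samples eligible for hull metrics (S >= 3)."""
    eligible = [int(s) for s in richness if s >= 3]
    if not eligible:
        raise ValidationError("no sample has the minimum richness (3) for hull metrics")
    return min(eligible)
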