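"""Per-sample taxonomic/functional diversity metrics and community-weighted means.

The individual index functions (`simpson_diversity`, `rao_quadratic_entropy`,
...) operate on plain arrays so they can be tested against brute-force
oracles.  :class:`MetricEngine` wires them to a fixed trait space and is the
single evaluation path used for observed communities and null draws alike,
which keeps standardized effect sizes internally consistent.

Weighting conventions (per basis):

* incidence: every present species gets weight 1/S;
* biomass: FD indices use Hellinger-transformed rows renormalized to sum 1,
  CWM uses raw relative biomass.

Simpson's D is computed on the same weights as RaoQ so the redundancy
identity FRed = 1 - RaoQ/D stays within [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .core_data import CommunityMatrix, TraitCodebook, TraitTable, ValidationError
from .trait_space import DissimilarityMatrix, TraitSpace

logger = logging.getLogger(__name__)

FD_METRICS = ("S", "D", "FRic", "FEve", "FDiv", "FDis", "RaoQ", "FRed", "FD")

# NA reason codes
R_EMPTY = "empty_sample"
R_MIN_RICHNESS = "richness_below_min"
R_FEW_POINTS = "too_few_unique_points"
R_DEGENERATE = "degenerate_hull"
R_ZERO_D = "zero_simpson"


def species_richness(row: np.ndarray) -> int:
    """Count of nonzero entries in a sample row."""
    return int(np.count_nonzero(np.asarray(row)))


def simpson_diversity(p: np.ndarray) -> float:
    """Simpson's D = 1 - sum(p_i^2) for a weight vector summing to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty weight vector")
    return float(1.0 - p @ p)


def rao_quadratic_entropy(
    d: np.ndarray, p: np.ndarray, convention: str = "raw"
) -> float:
    """Rao's quadratic entropy Q = sum_ij p_i p_j d_ij.

    ``convention="raw"`` uses the dissimilarities as given (the default,
    keeping FRed = 1 - Q/D in [0, 1] for d in [0, 1]); ``"d2half"`` uses
    d^2/2 for parity with implementations that square distances.
    """
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    if d.shape != (p.size, p.size):
        raise ValidationError("dissimilarity/weight dimension mismatch")
    if convention == "d2half":
        d = d**2 / 2.0
    elif convention != "raw":
        raise ValidationError(f"unknown RaoQ convention {convention!r}")
    return float(p @ d @ p)


def functional_redundancy(raoq: float, d_simpson: float) -> float:
    """FRed = 1 - RaoQ/D; NaN for monocultures (D = 0)."""
    if np.isnan(raoq) or np.isnan(d_simpson):
        return float("nan")
    if d_simpson < 0:
        raise ValidationError("Simpson diversity cannot be negative")
    if d_simpson == 0:
        return float("nan")
    if raoq > d_simpson * (1 + 1e-9) + 1e-12:
        raise ValidationError(
            f"RaoQ ({raoq}) exceeds Simpson D ({d_simpson}); upstream corruption"
        )
    return float(1.0 - raoq / d_simpson)


def _hull_volume(points: np.ndarray) -> tuple[float | None, ConvexHull | None]:
    """Convex-hull volume of unique points; (None, None) when degenerate."""
    m = points.shape[1]
    if m == 1:
        lo, hi = points.min(), points.max()
        return (float(hi - lo) if hi > lo else None), None
    try:
        hull = ConvexHull(points)
    except QhullError:
        return None, None
    return float(hull.volume), hull


def functional_richness(coords: np.ndarray) -> float:
    """Convex-hull volume of the present species' coordinates.

    ``coords`` is the (s x m) coordinate block of present species;
    duplicated rows are collapsed first.  Returns NaN when fewer than
    m + 1 unique points remain or the hull is degenerate.
    """
    pts = np.unique(np.asarray(coords, dtype=float), axis=0)
    if pts.shape[0] <= pts.shape[1]:
        return float("nan")
    vol, _ = _hull_volume(pts)
    return float("nan") if vol is None else vol


def _mst_edges(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Kruskal MST with deterministic (length, i, j) tie-breaking."""
    s = dist.shape[0]
    ii, jj = np.triu_indices(s, 1)
    dd = dist[ii, jj]
    order = np.lexsort((jj, ii, dd))
    parent = list(range(s))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, float]] = []
    for k in order:
        a, b = find(int(ii[k])), find(int(jj[k]))
        if a != b:
            parent[a] = b
            edges.append((int(ii[k]), int(jj[k]), float(dd[k])))
            if len(edges) == s - 1:
                break
    return edges


def functional_evenness(coords: np.ndarray, p: np.ndarray) -> float:
    """FEve: regularity of the minimum spanning tree, abundance-weighted.

    EW_l = dist(i,j)/(p_i + p_j) on MST edges, PEW_l = EW_l / sum(EW),
    FEve = (sum_l min(PEW_l, 1/(s-1)) - 1/(s-1)) / (1 - 1/(s-1)).
    Needs s >= 3; returns NaN otherwise.
    """
    coords = np.asarray(coords, dtype=float)
    p = np.asarray(p, dtype=float)
    s = coords.shape[0]
    if s < 3:
        return float("nan")
    dist = squareform(pdist(coords))
    edges = _mst_edges(dist)
    ew = np.array([d / (p[i] + p[j]) for i, j, d in edges])
    total = ew.sum()
    if total == 0:
        return float("nan")
    pew = ew / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_divergence(coords: np.ndarray, p: np.ndarray) -> float:
    """FDiv: abundance-weighted divergence from the hull-vertex centroid.

    G = centroid of the convex-hull vertices (unique points), dG_i the
    distance of each species to G; with dd = dG - mean(dG),
    FDiv = (sum p*dd + mean_dG) / (sum p*|dd| + mean_dG).
    Needs s >= 3 and a computable hull.
    """
    coords = np.asarray(coords, dtype=float)
    p = np.asarray(p, dtype=float)
    if coords.shape[0] < 3:
        return float("nan")
    pts = np.unique(coords, axis=0)
    if pts.shape[0] <= pts.shape[1]:
        return float("nan")
    vol, hull = _hull_volume(pts)
    if vol is None:
        return float("nan")
    if hull is None:  # 1-D case: vertices are the two extremes
        vertices = np.array([[pts.min()], [pts.max()]])
    else:
        vertices = pts[hull.vertices]
    g = vertices.mean(axis=0)
    dg = np.linalg.norm(coords - g, axis=1)
    mean_dg = dg.mean()
    dd = dg - mean_dg
    denom = float(p @ np.abs(dd) + mean_dg)
    if denom == 0:
        return float("nan")
    return float((p @ dd + mean_dg) / denom)


def functional_dispersion(coords: np.ndarray, p: np.ndarray) -> float:
    """FDis: weighted mean distance to the weighted centroid."""
    coords = np.asarray(coords, dtype=float)
    p = np.asarray(p, dtype=float)
    if coords.shape[0] == 0:
        raise ValidationError("empty community")
    c = p @ coords
    return float(p @ np.linalg.norm(coords - c, axis=1))


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

@dataclass
class MetricEngine:
    """Evaluates metrics for sample rows against a fixed species-pool trait space.

    Rows must be aligned to ``dissimilarity.species_ids``; use
    :meth:`align_matrix` to map a community matrix onto the pool order.
    """

    dissimilarity: DissimilarityMatrix
    space: TraitSpace
    m: int
    traits: TraitTable | None = None
    rao_convention: str = "raw"
    _coords: np.ndarray = field(init=False, repr=False)
    _coords_full: np.ndarray = field(init=False, repr=False)
    _cwm_membership: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.space.species_ids != self.dissimilarity.species_ids:
            raise ValidationError("trait space and dissimilarity matrix species differ")
        # hull/MST metrics work in the first m axes; FDis uses all positive
        # axes so distances approximate the corrected dissimilarities
        self._coords = self.space.axes(self.m)
        self._coords_full = self.space.coordinates
        self._cwm_membership = {}
        if self.traits is not None:
            tdata = self.traits.data.loc[list(self.dissimilarity.species_ids)]
            for trait, cat in self.traits.codebook.pairs():
                key = f"CWM:{trait}:{cat}"
                self._cwm_membership[key] = (tdata[trait] == cat).to_numpy(dtype=float)

    @property
    def species_ids(self) -> tuple[str, ...]:
        return self.dissimilarity.species_ids

    @property
    def cwm_metrics(self) -> tuple[str, ...]:
        return tuple(self._cwm_membership)

    def align_matrix(self, m: CommunityMatrix) -> np.ndarray:
        """(n_samples x n_pool) array with matrix columns mapped to pool order."""
        index = {s: i for i, s in enumerate(self.species_ids)}
        missing = [s for s in m.species_ids if s not in index]
        nonzero = m.values().sum(axis=0) > 0
        bad = [s for s, nz in zip(m.species_ids, nonzero) if nz and s in set(missing)]
        if bad:
            raise ValidationError(f"species not in the trait space: {bad}")
        out = np.zeros((len(m.sample_ids), len(self.species_ids)))
        for j, s in enumerate(m.species_ids):
            if s in index:
                out[:, index[s]] = m.values()[:, j]
        return out

    def metrics_for_row(
        self,
        row: np.ndarray,
        mode: str,
        metrics: tuple[str, ...] = FD_METRICS,
        with_reasons: bool = False,
    ):
        """Metric dict for one pool-aligned sample row.

        NaN entries carry a reason code when ``with_reasons`` is set.
        ``metrics`` may include FD metric names and ``CWM:trait:category``
        keys (biomass mode only uses raw relative weights for the latter).
        """
        out: dict[str, float] = {}
        reasons: dict[str, str] = {}
        idx = np.flatnonzero(row > 0)
        s = idx.size
        want = set(metrics)
        cwm_keys = [k for k in metrics if k.startswith("CWM:")]

        if "S" in want:
            out["S"] = float(s)
        if s == 0:
            for k in want - {"S"}:
                out[k] = float("nan")
                reasons[k] = R_EMPTY
            return (out, reasons) if with_reasons else out

        vals = row[idx]
        if mode == "incidence":
            w = np.full(s, 1.0 / s)
            q = w
        else:
            q = vals / vals.sum()
            w = np.sqrt(vals)
            w = w / w.sum()

        coords = self._coords[idx]
        need_hull = bool({"FRic", "FDiv"} & want)

        d_simp = float("nan")
        if {"D", "FRed"} & want:
            d_simp = simpson_diversity(w)
            if "D" in want:
                out["D"] = d_simp
        raoq = float("nan")
        if {"RaoQ", "FRed", "FD"} & want:
            dsub = self.dissimilarity.values[np.ix_(idx, idx)]
            raoq = rao_quadratic_entropy(dsub, w, self.rao_convention)
            if "RaoQ" in want:
                out["RaoQ"] = raoq
        if "FRed" in want:
            if d_simp == 0:
                out["FRed"] = float("nan")
                reasons["FRed"] = R_ZERO_D
            else:
                out["FRed"] = functional_redundancy(raoq, d_simp)
        fdis = float("nan")
        if {"FDis", "FD"} & want:
            fdis = functional_dispersion(self._coords_full[idx], w)
            if "FDis" in want:
                out["FDis"] = fdis
        if "FD" in want:
            out["FD"] = (fdis + raoq) / 2.0
        if "FEve" in want:
            v = functional_evenness(coords, w)
            out["FEve"] = v
            if np.isnan(v):
                reasons["FEve"] = R_MIN_RICHNESS
        if need_hull:
            pts = np.unique(coords, axis=0)
            if pts.shape[0] <= self.m:
                if "FRic" in want:
                    out["FRic"] = float("nan")
                    reasons["FRic"] = R_FEW_POINTS
                if "FDiv" in want:
                    out["FDiv"] = float("nan")
                    reasons["FDiv"] = R_FEW_POINTS
            else:
                vol, hull = _hull_volume(pts)
                if vol is None:
                    if "FRic" in want:
                        out["FRic"] = float("nan")
                        reasons["FRic"] = R_DEGENERATE
                    if "FDiv" in want:
                        out["FDiv"] = float("nan")
                        reasons["FDiv"] = R_DEGENERATE
                else:
                    if "FRic" in want:
                        out["FRic"] = vol
                    if "FDiv" in want:
                        if s < 3:
                            out["FDiv"] = float("nan")
                            reasons["FDiv"] = R_MIN_RICHNESS
                        else:
                            if hull is None:
                                vertices = np.array([[pts.min()], [pts.max()]])
                            else:
                                vertices = pts[hull.vertices]
                            g = vertices.mean(axis=0)
                            dg = np.linalg.norm(coords - g, axis=1)
                            dd = dg - dg.mean()
                            denom = float(w @ np.abs(dd) + dg.mean())
                            out["FDiv"] = (
                                float((w @ dd + dg.mean()) / denom) if denom > 0 else float("nan")
                            )
        for key in cwm_keys:
            out[key] = float(q @ self._cwm_membership[key][idx])
        return (out, reasons) if with_reasons else out


# ---------------------------------------------------------------------------
# Table-level operations
# ---------------------------------------------------------------------------

def community_weighted_means(
    m: CommunityMatrix,
    traits: TraitTable,
    codebook: TraitCodebook | None = None,
) -> pd.DataFrame:
    """Long-format CWM table: sample, trait, category, cwm.

    The CWM of a category is the summed relative abundance (raw relative
    biomass, or 1/S shares for incidence) of the species carrying it;
    categories of one trait partition each sample's total.
    """
    codebook = codebook or traits.codebook
    vals = m.values()
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValidationError(f"samples with zero total: {bad}")
    missing = sorted(set(m.species_ids) - set(traits.species_ids))
    if missing:
        raise ValidationError(f"species missing trait values: {missing}")
    rel = vals / totals[:, None]
    tdata = traits.data.loc[list(m.species_ids)]
    records = []
    for trait, cat in codebook.pairs():
        member = (tdata[trait] == cat).to_numpy(dtype=float)
        cwm = rel @ member
        for sid, v in zip(m.sample_ids, cwm):
            records.append((sid, trait, cat, float(v)))
    return pd.DataFrame(records, columns=["sample_id", "trait", "category", "cwm"])


def fd_profile(
    m: CommunityMatrix,
    engine: MetricEngine,
    metrics: tuple[str, ...] = FD_METRICS,
) -> pd.DataFrame:
    """One row of FD metrics per sample for the matrix's basis.

    NaN metrics carry their reason code in a ``reason_<metric>`` column.
    """
    aligned = engine.align_matrix(m)
    rows = []
    for sid, row in zip(m.sample_ids, aligned):
        vals, reasons = engine.metrics_for_row(row, m.mode, metrics, with_reasons=True)
        rec = {"sample_id": sid, "basis": m.mode, **vals}
        for k, why in reasons.items():
            rec[f"reason_{k}"] = why
        rows.append(rec)
    df = pd.DataFrame(rows)
    ordered = ["sample_id", "basis"] + [c for c in metrics if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + sorted(extra)]


def fd_profile_long(profile: pd.DataFrame) -> pd.DataFrame:
    """Wide fd_profile -> long (sample_id, basis, metric, value, reason_code)."""
    metrics = [c for c in profile.columns
               if c not in ("sample_id", "basis") and not c.startswith("reason_")]
    records = []
    for _, row in profile.iterrows():
        for met in metrics:
            records.append((
                row["sample_id"], row["basis"], met, row[met],
                row.get(f"reason_{met}", "") if pd.notna(row.get(f"reason_{met}", "")) else "",
            ))
    return pd.DataFrame(records,
                        columns=["sample_id", "basis", "metric", "value", "reason_code"])
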