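"""Constrained randomizations, standardized effect sizes, and assembly rules.

Both randomizers permute each species column independently across samples,
which preserves species frequencies (and, for biomass, each species' value
multiset) exactly while letting sample richness vary.  Null ensembles are
built by randomizing the whole matrix once per iteration and recomputing
metrics on the fixed species-pool trait space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import CommunityMatrix, EnvironmentTable, ValidationError
from .diversity_metrics import FD_METRICS, MetricEngine

logger = logging.getLogger(__name__)

MIN_VALID_DEFAULT = 100
ALPHA = 0.05

FD_LABELS = {"negative": "habitat_filtering", "positive": "limiting_similarity",
             "none": "random"}
CWM_LABELS = {"negative": "trait_convergence", "positive": "trait_divergence",
              "none": "random"}


def _permute_columns(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        out[:, j] = values[rng.permutation(n), j]
    return out


def randomize_c0(m: CommunityMatrix, rng: np.random.Generator) -> CommunityMatrix:
    """Incidence randomization: each species' presences land on a uniformly
    random sample subset of the same size (columns independent).  Column
    sums are preserved exactly; row richness is free to vary."""
    if m.mode != "incidence":
        raise ValidationError("c0 requires an incidence matrix")
    out = _permute_columns(m.values(), rng)
    return CommunityMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                           mode="incidence", transformed=m.transformed)


def randomize_c0_samp(m: CommunityMatrix, rng: np.random.Generator) -> CommunityMatrix:
    """Biomass randomization: each species column's value multiset is permuted
    across samples (columns independent).  Column totals, occurrence counts
    and nonzero value sets are preserved exactly."""
    if m.mode != "biomass":
        raise ValidationError("c0_samp requires a biomass matrix")
    out = _permute_columns(m.values(), rng)
    return CommunityMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                           mode="biomass", transformed=m.transformed)


def build_null_ensemble(
    m: CommunityMatrix,
    engine: MetricEngine,
    metrics: tuple[str, ...],
    n_iter: int = 1000,
    seed: int | None = None,
    min_valid: int = MIN_VALID_DEFAULT,
    keep_values: bool = False,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Null distributions of per-sample metrics under whole-matrix randomization.

    Returns one row per (sample, metric) with ``n_valid``, ``null_mean``,
    ``null_sd`` (NaN null draws dropped; ensembles with fewer than
    ``min_valid`` valid values flagged unusable) and optionally the raw
    null values.
    """
    if seed is None:
        raise ValidationError("a seed is required for reproducible null ensembles")
    base = engine.align_matrix(m)
    sample_ids = list(m.sample_ids) if sample_ids is None else list(sample_ids)
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    rows = [pos[s] for s in sample_ids]
    children = np.random.SeedSequence(seed).spawn(n_iter)
    nulls = np.empty((n_iter, len(rows), len(metrics)))
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        shuffled = _permute_columns(base, rng)
        for k, r in enumerate(rows):
            vals = engine.metrics_for_row(shuffled[r], m.mode, metrics)
            for c, met in enumerate(metrics):
                nulls[it, k, c] = vals[met]
    records = []
    for k, sid in enumerate(sample_ids):
        for c, met in enumerate(metrics):
            col = nulls[:, k, c]
            valid = col[~np.isnan(col)]
            rec = {
                "sample_id": sid, "metric": met, "basis": m.mode,
                "n_iter": int(valid.size),
                "null_mean": float(valid.mean()) if valid.size else float("nan"),
                "null_sd": float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
                "usable": bool(valid.size >= min_valid),
            }
            if keep_values:
                rec["null_values"] = valid.copy()
            records.append(rec)
    return pd.DataFrame(records)


def standardized_effect_size(observed: float, null_mean: float, null_sd: float,
                             usable: bool = True) -> float:
    """SES = (observed - null_mean)/null_sd; NaN for unusable or flat nulls."""
    if not usable or np.isnan(observed) or np.isnan(null_sd) or null_sd == 0:
        return float("nan")
    return float((observed - null_mean) / null_sd)


def compute_ses(
    m: CommunityMatrix,
    engine: MetricEngine,
    metrics: tuple[str, ...] = FD_METRICS,
    n_iter: int = 1000,
    seed: int | None = None,
    min_valid: int = MIN_VALID_DEFAULT,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Observed metrics, null moments and SES per (sample, metric)."""
    ensemble = build_null_ensemble(m, engine, metrics, n_iter=n_iter, seed=seed,
                                   min_valid=min_valid, sample_ids=sample_ids)
    aligned = engine.align_matrix(m)
    pos = {s: i for i, s in enumerate(m.sample_ids)}
    observed: dict[tuple[str, str], float] = {}
    ids = list(m.sample_ids) if sample_ids is None else list(sample_ids)
    for sid in ids:
        vals = engine.metrics_for_row(aligned[pos[sid]], m.mode, metrics)
        for met in metrics:
            observed[(sid, met)] = vals[met]
    ensemble["observed"] = [
        observed[(r.sample_id, r.metric)] for r in ensemble.itertuples()
    ]
    ensemble["ses"] = [
        standardized_effect_size(r.observed, r.null_mean, r.null_sd, r.usable)
        for r in ensemble.itertuples()
    ]
    return ensemble[["sample_id", "basis", "metric", "observed",
                     "null_mean", "null_sd", "n_iter", "usable", "ses"]]


# ---------------------------------------------------------------------------
# Group testing and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SesTestResult:
    test_used: str  # "t" | "wilcoxon"
    p_value: float
    direction: str  # "negative" | "positive" | "none"
    n: int


def test_ses_zero(values) -> SesTestResult:
    """Two-sided test of SES against zero with Shapiro branching.

    Shapiro-Wilk at alpha=0.05 decides between a one-sample t-test
    (normal-looking samples) and a Wilcoxon signed-rank test (exact p for
    n <= 25 after dropping zeros, normal approximation with continuity
    correction otherwise; constant samples fall through to Wilcoxon with a
    warning).  Direction is the sign of the sample median when p < 0.05.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 non-NA SES values, got {n}")
    constant = bool(np.ptp(x) == 0)
    if constant:
        logger.warning("constant SES sample; Shapiro undefined, using Wilcoxon")
        use_t = False
    else:
        use_t = stats.shapiro(x).pvalue >= ALPHA
    if use_t:
        test_used = "t"
        p = float(stats.ttest_1samp(x, 0.0).pvalue)
    else:
        test_used = "wilcoxon"
        nz = x[x != 0]
        if nz.size == 0:
            p = 1.0
        else:
            method = "exact" if nz.size <= 25 else "approx"
            try:
                res = stats.wilcoxon(nz, alternative="two-sided",
                                     correction=True, method=method)
            except ValueError:
                res = stats.wilcoxon(nz, alternative="two-sided",
                                     correction=True, method="approx")
            p = float(res.pvalue)
    med = float(np.median(x))
    if p < ALPHA and med != 0:
        direction = "negative" if med < 0 else "positive"
    else:
        direction = "none"
    return SesTestResult(test_used=test_used, p_value=p, direction=direction, n=n)


def classify_assembly(metric_family: str, result: SesTestResult) -> str:
    """Map a significant SES direction onto an assembly-rule label.

    fd family: negative -> habitat_filtering, positive -> limiting_similarity;
    cwm family: negative -> trait_convergence, positive -> trait_divergence;
    non-significant -> random.
    """
    if metric_family == "fd":
        return FD_LABELS[result.direction]
    if metric_family == "cwm":
        return CWM_LABELS[result.direction]
    raise ValidationError(f"unknown metric family {metric_family!r}")


def ses_trend(ses, tp) -> tuple[float, float]:
    """Spearman rank correlation of SES against log10(TP), two-sided p."""
    ses = np.asarray(ses, dtype=float)
    tp = np.asarray(tp, dtype=float)
    if ses.size != tp.size:
        raise ValidationError("SES/TP length mismatch")
    mask = ~(np.isnan(ses) | np.isnan(tp))
    ses, tp = ses[mask], tp[mask]
    if ses.size < 5:
        raise ValidationError("need at least 5 paired values for a trend test")
    if np.ptp(ses) == 0 or np.ptp(tp) == 0:
        raise ValidationError("constant input in trend test")
    rho, p = stats.spearmanr(np.log10(tp), ses)
    return float(rho), float(p)


def assembly_calls(
    ses_table: pd.DataFrame,
    env: EnvironmentTable,
    groupings: tuple[str, ...] = ("entire", "trophic_state"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Per (group, basis, metric) SES-vs-zero tests and assembly labels.

    ``ses_table`` is the output of :func:`compute_ses` (metric names
    starting with ``CWM:`` form the cwm family, the rest fd).  Groups are
    the entire dataset and/or the trophic states from ``env``.
    """
    df = ses_table.copy()
    df["trophic_state"] = [
        env.data.loc[s, "trophic_state"] if s in env.data.index else None
        for s in df["sample_id"]
    ]
    group_frames: list[tuple[str, pd.DataFrame]] = []
    if "entire" in groupings:
        group_frames.append(("entire", df))
    if "trophic_state" in groupings:
        for state, sub in df.groupby("trophic_state"):
            group_frames.append((str(state), sub))
    records = []
    for gname, sub in group_frames:
        for (basis, metric), cell in sub.groupby(["basis", "metric"]):
            family = "cwm" if str(metric).startswith("CWM:") else "fd"
            vals = cell["ses"].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size < min_n:
                records.append({
                    "group": gname, "basis": basis, "metric_family": family,
                    "metric": metric, "test_used": "", "n": int(vals.size),
                    "p_value": float("nan"), "direction": "none", "label": "random",
                })
                continue
            res = test_ses_zero(vals)
            records.append({
                "group": gname, "basis": basis, "metric_family": family,
                "metric": metric, "test_used": res.test_used, "n": res.n,
                "p_value": res.p_value, "direction": res.direction,
                "label": classify_assembly(family, res),
            })
    return pd.DataFrame(records)


def ses_trends(ses_table: pd.DataFrame, env: EnvironmentTable,
               min_n: int = 5) -> pd.DataFrame:
    """Spearman SES-vs-log10(TP) trend per (basis, metric)."""
    tp = env.data["TP"].astype(float)
    records = []
    for (basis, metric), cell in ses_table.groupby(["basis", "metric"]):
        pair_tp = np.array([tp.get(s, np.nan) for s in cell["sample_id"]])
        ses = cell["ses"].to_numpy(dtype=float)
        mask = ~(np.isnan(ses) | np.isnan(pair_tp))
        rec = {"basis": basis, "metric": metric, "n": int(mask.sum())}
        try:
            rho, p = ses_trend(ses[mask], pair_tp[mask])
            rec.update(spearman_rho=rho, p_value=p)
        except ValidationError as exc:
            rec.update(spearman_rho=float("nan"), p_value=float("nan"), note=str(exc))
        records.append(rec)
    return pd.DataFrame(records)
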