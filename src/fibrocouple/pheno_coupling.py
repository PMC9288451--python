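"""Coupling longitudinal expression changes to the lung-function trajectory.

A feature's per-day log2FC trajectory (5 points per model) is correlated with
the treated-arm group-mean lung compliance trajectory of the same model.
Upregulated fibrosis genes anti-correlate with compliance (r ≤ −0.85 under the
default threshold); selection additionally requires day-21 significance and a
consistent direction of change in both models, and ranks by the mean day-21
log2FC.  Correlations over as few as 5 points are granular, so thresholds are
used without attached p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import log2fc_profiles
from .formats_io import FormatsError, PhenotypeTrajectory

DEFAULT_R_THRESHOLD = 0.85
DEFAULT_PARTITION_CUTOFF = 0.6


class UndefinedCorrelationError(FormatsError):
    """Correlation is undefined (zero variance / all ties / too few points)."""


def pearson_r(x, y) -> float:
    """Product-moment correlation; raises on zero-variance or short input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatsError("pearson_r expects two equal-length 1-D vectors")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def spearman_rho(x, y) -> float:
    """Rank correlation: Pearson r of average-ranked values (ties → mean rank)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FormatsError("spearman_rho expects two equal-length 1-D vectors")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 points")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("all-tied input")
    return pearson_r(rx, ry)


def correlate_with_lung_function(
        contrasts: pd.DataFrame,
        trajectories: dict[str, PhenotypeTrajectory]) -> pd.DataFrame:
    """Pearson r of each feature's log2FC trajectory vs compliance, per model.

    Returns one row per feature with ``r_bleomycin``, ``r_aav``, their mean,
    the number of time points, and an ``undefined`` flag set when either
    model's correlation does not exist (constant trajectory).  Undefined
    correlations are NaN — explicit missing values, never silent zeros.
    """
    per_model = {}
    for model, traj in trajectories.items():
        prof = log2fc_profiles(contrasts, model)
        if tuple(prof.columns) != tuple(traj.days):
            raise FormatsError(
                f"{model}: contrast days {tuple(prof.columns)} do not match "
                f"trajectory days {traj.days}")
        comp = np.asarray(traj.compliance, dtype=float)
        vals = prof.to_numpy()
        r = _rowwise_pearson(vals, comp)
        per_model[model] = pd.Series(r, index=prof.index)
    frame = pd.DataFrame({
        "r_bleomycin": per_model["bleomycin"],
        "r_aav": per_model["aav_tgfb1"],
    })
    frame["mean_r"] = frame[["r_bleomycin", "r_aav"]].mean(axis=1, skipna=False)
    frame["n_points"] = len(next(iter(trajectories.values())).days)
    frame["undefined"] = frame[["r_bleomycin", "r_aav"]].isna().any(axis=1)
    frame.index.name = "feature_id"
    return frame.reset_index()


def _rowwise_pearson(mat: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Pearson r of every matrix row against one vector; NaN where undefined."""
    mc = mat - mat.mean(axis=1, keepdims=True)
    vc = vec - vec.mean()
    denom = np.sqrt((mc ** 2).sum(axis=1) * (vc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc @ vc) / denom
    r[denom == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def select_phenotype_coupled_genes(
        corr: pd.DataFrame, contrasts: pd.DataFrame, direction: str,
        r_threshold: float = DEFAULT_R_THRESHOLD, alpha: float = 0.05,
        top_n: int | None = None, day: int = 21, strict: bool = False) -> pd.DataFrame:
    """Filter-and-rank genes coupled to lung-function decline.

    direction='up': mean_r ≤ −r_threshold, adjusted p ≤ alpha at the reference
    day in BOTH models, log2FC at that day ≥ 0 in BOTH models; ranked by mean
    reference-day log2FC descending.  direction='down' mirrors all signs and
    ranks ascending.  ``strict`` requires the r threshold in each model
    separately instead of on the mean.
    """
    if direction not in ("up", "down"):
        raise FormatsError("direction must be 'up' or 'down'")
    at_day = contrasts[contrasts["day"] == day]
    lfc = at_day.pivot(index="feature_id", columns="model", values="log2fc")
    adj = at_day.pivot(index="feature_id", columns="model", values="adj_p")
    tab = corr.set_index("feature_id").join(
        lfc.add_prefix("lfc_")).join(adj.add_prefix("adj_"))
    tab["mean_lfc_day"] = tab[["lfc_bleomycin", "lfc_aav_tgfb1"]].mean(axis=1)

    sig = (tab["adj_bleomycin"] <= alpha) & (tab["adj_aav_tgfb1"] <= alpha)
    if direction == "up":
        if strict:
            r_ok = (tab["r_bleomycin"] <= -r_threshold) & (tab["r_aav"] <= -r_threshold)
        else:
            r_ok = tab["mean_r"] <= -r_threshold
        dir_ok = (tab["lfc_bleomycin"] >= 0) & (tab["lfc_aav_tgfb1"] >= 0)
        ascending = False
    else:
        if strict:
            r_ok = (tab["r_bleomycin"] >= r_threshold) & (tab["r_aav"] >= r_threshold)
        else:
            r_ok = tab["mean_r"] >= r_threshold
        dir_ok = (tab["lfc_bleomycin"] <= 0) & (tab["lfc_aav_tgfb1"] <= 0)
        ascending = True
    keep = r_ok.fillna(False) & sig.fillna(False) & dir_ok.fillna(False)
    selected = tab[keep].sort_values("mean_lfc_day", ascending=ascending)
    if top_n is not None:
        selected = selected.head(top_n)
    cols = ["r_bleomycin", "r_aav", "mean_r",
            "lfc_bleomycin", "lfc_aav_tgfb1", "mean_lfc_day",
            "adj_bleomycin", "adj_aav_tgfb1"]
    return selected[cols].reset_index()


def pattern_rank(contrasts: pd.DataFrame, pattern, model: str) -> pd.DataFrame:
    """Rank features by Pearson correlation to a pre-defined temporal pattern.

    The pattern is one value per study day (e.g. a day-3 spike ``(1,0,0,0,0)``).
    Features whose correlation is undefined (constant profile) rank last with
    NaN r.
    """
    pattern = np.asarray(pattern, dtype=float)
    if np.ptp(pattern) == 0:
        raise UndefinedCorrelationError("constant pattern has no direction")
    prof = log2fc_profiles(contrasts, model)
    if prof.shape[1] != pattern.size:
        raise FormatsError(
            f"pattern length {pattern.size} != number of days {prof.shape[1]}")
    r = _rowwise_pearson(prof.to_numpy(), pattern)
    out = pd.DataFrame({"feature_id": prof.index, "r": r})
    out = out.sort_values("r", ascending=False, na_position="last",
                          kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class ModelSpecificityPartition:
    """Per-day partition of features by which model crosses the log2FC cutoff."""

    day: int
    exclusive_bleomycin: list[str]
    exclusive_aav: list[str]
    common: list[str]
    r_squared: dict[str, float]  # per set name; NaN when |set| < 3


def partition_model_specificity(contrasts: pd.DataFrame, day: int,
                                cutoff: float = DEFAULT_PARTITION_CUTOFF
                                ) -> ModelSpecificityPartition:
    """Split features into model-exclusive and common DE sets at one day.

    Magnitude-only cutoffs: a feature is "common" when |log2FC| ≥ cutoff in
    both models regardless of sign (direction consistency is enforced later,
    in gene selection).  Each set's R² is the squared Pearson r between the
    two models' log2FC values over that set.
    """
    at_day = contrasts[contrasts["day"] == day]
    lfc = at_day.pivot(index="feature_id", columns="model", values="log2fc")
    b = lfc["bleomycin"].abs() >= cutoff
    a = lfc["aav_tgfb1"].abs() >= cutoff
    sets = {
        "exclusive_bleomycin": list(lfc.index[b & ~a]),
        "exclusive_aav": list(lfc.index[a & ~b]),
        "common": list(lfc.index[a & b]),
    }
    r_squared = {}
    for name, members in sets.items():
        if len(members) < 3:
            r_squared[name] = float("nan")
            continue
        sub = lfc.loc[members]
        try:
            r = pearson_r(sub["bleomycin"], sub["aav_tgfb1"])
            r_squared[name] = r ** 2
        except UndefinedCorrelationError:
            r_squared[name] = float("nan")
    return ModelSpecificityPartition(day=day, r_squared=r_squared, **sets)
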