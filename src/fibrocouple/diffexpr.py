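"""Desk-scale differential expression per model × day contrast.

The engine is a Welch t-test on log-CPM values with Benjamini–Hochberg
adjustment within each single contrast (all features at one model × day).
This replaces a moderated-variance linear-model fit with a documented,
dependency-light equivalent; contrast pairing (treated vs same-day control
of the same model) and the calling thresholds |log2FC| ≥ 0.6, adjusted
p ≤ 0.05 are preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import ExpressionMatrix, FormatsError, SampleSheet

PRIOR_CPM = 0.5
DEFAULT_LFC_THRESHOLD = 0.6
DEFAULT_ALPHA = 0.05


class ZeroLibraryError(FormatsError):
    """A sample has zero total counts and cannot be CPM-normalised."""


class TooFewSamplesError(FormatsError):
    """A contrast group has fewer than two samples."""


def normalize_log_cpm(counts: ExpressionMatrix, prior: float = PRIOR_CPM) -> ExpressionMatrix:
    """log2(CPM + prior) library-size normalisation.

    value = log2(count / library_size * 1e6 + prior); library size is the
    per-sample column sum.  A zero count maps to log2(prior) regardless of
    library size.
    """
    if counts.scale != "counts":
        raise FormatsError("normalize_log_cpm expects a counts-scale matrix")
    libsize = counts.values.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ZeroLibraryError(f"samples with zero library size: {bad}")
    cpm = counts.values / libsize * 1e6
    log_cpm = np.log2(cpm + prior)
    return ExpressionMatrix(values=log_cpm, kind=counts.kind, scale="log_cpm")


def filter_low_expression(matrix: ExpressionMatrix, design: SampleSheet,
                          min_cpm: float = 1.0,
                          min_samples: int | None = None) -> ExpressionMatrix:
    """Drop lowly expressed features.

    Keeps features with CPM ≥ ``min_cpm`` in at least ``min_samples`` samples
    (inclusive boundary).  ``min_samples`` defaults to the size of the smallest
    (model, arm, day) group so a feature expressed in one full group survives.
    """
    if matrix.scale != "counts":
        raise FormatsError("filter_low_expression expects a counts-scale matrix")
    if min_samples is None:
        min_samples = design.smallest_group_size()
    libsize = matrix.values.sum(axis=0)
    if (libsize <= 0).any():
        raise ZeroLibraryError("zero library size sample")
    cpm = matrix.values / libsize * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return ExpressionMatrix(values=matrix.values.loc[keep].copy(),
                            kind=matrix.kind, scale=matrix.scale)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (one family)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(log_cpm: ExpressionMatrix, design: SampleSheet, model: str,
                 day: int, lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
                 alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Treated vs same-day control contrast for one model and day.

    Returns a tidy frame with one row per feature: log2fc (difference of group
    mean log-CPM), Welch two-sided p, BH-adjusted p across all features of
    this contrast, mean log-CPM, and the DE call under the run thresholds.
    Features with zero variance in both groups get p = 1 (no evidence).
    """
    if log_cpm.scale != "log_cpm":
        raise FormatsError("run_contrast expects a log_cpm-scale matrix")
    treated_ids = design.group(model, "treated", day)
    control_ids = design.group(model, "control", day)
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise TooFewSamplesError(
            f"contrast ({model}, day {day}): groups of sizes "
            f"{len(treated_ids)}/{len(control_ids)}, need ≥2 each")
    treated = log_cpm.values[treated_ids].to_numpy()
    control = log_cpm.values[control_ids].to_numpy()

    log2fc = treated.mean(axis=1) - control.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(treated, control, axis=1, equal_var=False)
    # zero within-group variance on both sides: identical values -> p undefined
    p = np.where(np.isnan(p), 1.0, p)
    adj_p = bh_adjust(p)
    mean_log_cpm = log_cpm.values.mean(axis=1).to_numpy()
    de_flag = (np.abs(log2fc) >= lfc_threshold) & (adj_p <= alpha)
    return pd.DataFrame({
        "feature_id": log_cpm.feature_ids,
        "model": model,
        "day": day,
        "log2fc": log2fc,
        "p_value": p,
        "adj_p": adj_p,
        "mean_log_cpm": mean_log_cpm,
        "de_flag": de_flag,
    })


def run_all_contrasts(log_cpm: ExpressionMatrix, design: SampleSheet,
                      lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
                      alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Every (model, day) contrast present in the design, concatenated."""
    groups = sorted({(d.model, d.day) for d in design if d.arm == "treated"},
                    key=lambda md: (md[0], md[1]))
    frames = [run_contrast(log_cpm, design, model, day,
                           lfc_threshold=lfc_threshold, alpha=alpha)
              for model, day in groups]
    return pd.concat(frames, ignore_index=True)


def count_de_over_time(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Number of DE-flagged features per (model, day)."""
    counts = (contrasts.groupby(["model", "day"])["de_flag"]
              .sum().astype(int).rename("n_de").reset_index())
    return counts.sort_values(["model", "day"]).reset_index(drop=True)


def log2fc_profiles(contrasts: pd.DataFrame, model: str) -> pd.DataFrame:
    """Per-feature log2FC trajectory over days for one model (features × days)."""
    sub = contrasts[contrasts["model"] == model]
    return sub.pivot(index="feature_id", columns="day", values="log2fc").sort_index(axis=1)
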