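"""miRNA–mRNA anticorrelation, prediction intersection and network assembly.

Candidate regulatory pairs are every (miRNA, mRNA) combination, correlated by
Spearman's rho across ALL samples of both models and all time points on
log-CPM values.  The high-confidence set intersects expression anticorrelation
(rho ≤ −0.6) with sequence-based predictions supported by at least two of the
five prediction tools.  The network adds co-expression edges between included
mRNAs (correlation ≥ 0.75, inclusive) and annotates every node with its day-21
log2FC in the AAV model, its number of significant contrasts, and its
lung-function correlation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import (
    ExpressionMatrix,
    FormatsError,
    InvalidAlphabetError,
    MiRNARecord,
    PredictionTable,
)
from .synthstudy import reverse_complement

DEFAULT_RHO_MAX = -0.6
DEFAULT_MIN_TOOLS = 2
DEFAULT_MRNA_MIN_R = 0.75


class SampleMismatchError(FormatsError):
    """The two expression matrices do not cover the same samples."""


class MissingAnnotationError(FormatsError):
    """A node to be emitted has no annotation record."""


def _ranked(matrix: pd.DataFrame) -> np.ndarray:
    """Row-wise average ranks, standardised; rows with all ties become NaN."""
    ranks = stats.rankdata(matrix.to_numpy(), axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered ** 2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norm
    z[np.repeat(norm == 0, ranks.shape[1], axis=1)] = np.nan
    return z


def correlate_all_pairs(mirna_log_cpm: ExpressionMatrix,
                        mrna_log_cpm: ExpressionMatrix) -> pd.DataFrame:
    """Spearman rho for every (miRNA, mRNA) pair across all shared samples.

    Computed as the Pearson correlation of average-ranked rows (ties get mean
    ranks), vectorised as a rank-matrix product.  Pairs involving an all-tied
    feature have NaN rho and are flagged ``undefined``.
    """
    if list(mirna_log_cpm.sample_ids) != list(mrna_log_cpm.sample_ids):
        if set(mirna_log_cpm.sample_ids) != set(mrna_log_cpm.sample_ids):
            raise SampleMismatchError(
                "miRNA and mRNA matrices cover different sample sets")
        mrna_log_cpm = ExpressionMatrix(
            values=mrna_log_cpm.values[mirna_log_cpm.sample_ids],
            kind=mrna_log_cpm.kind, scale=mrna_log_cpm.scale)
    n = len(mirna_log_cpm.sample_ids)
    if n < 3:
        raise FormatsError("need at least 3 shared samples")
    z_mi = _ranked(mirna_log_cpm.values)
    z_mr = _ranked(mrna_log_cpm.values)
    rho = np.clip(z_mi @ z_mr.T, -1.0, 1.0)
    mi_ids = np.asarray(mirna_log_cpm.feature_ids)
    mr_ids = np.asarray(mrna_log_cpm.feature_ids)
    out = pd.DataFrame({
        "mirna": np.repeat(mi_ids, len(mr_ids)),
        "mrna": np.tile(mr_ids, len(mi_ids)),
        "rho": rho.ravel(),
        "n_samples": n,
    })
    out["undefined"] = out["rho"].isna()
    return out


def intersect_high_confidence(corr: pd.DataFrame, preds: PredictionTable,
                              rho_max: float = DEFAULT_RHO_MAX,
                              min_tools: int = DEFAULT_MIN_TOOLS) -> pd.DataFrame:
    """High-confidence pairs: rho ≤ rho_max AND prediction by ≥ min_tools tools."""
    if len(preds.tools) < min_tools:
        raise FormatsError(
            f"tool vocabulary has {len(preds.tools)} members, need ≥ {min_tools}")
    anticorr = corr[corr["rho"] <= rho_max]
    support = preds.tool_counts()
    support = support[support["n_tools"] >= min_tools]
    merged = anticorr.merge(support, left_on=["mirna", "mrna"],
                            right_on=["mirna", "target"], how="inner")
    return (merged[["mirna", "mrna", "rho", "n_samples", "n_tools"]]
            .sort_values(["mirna", "mrna"]).reset_index(drop=True))


def predict_targets_seed_match(mirna: MiRNARecord, target_seqs: Mapping[str, str]
                               ) -> pd.DataFrame:
    """Built-in stand-alone predictor: seed-site scan (tool name "seedmatch").

    A target is predicted when the reverse complement of the miRNA's 6-nt seed
    occurs at least once in the target sequence; the occurrence count is kept.
    Exists so synthetic pipelines need no external prediction databases.
    """
    site = reverse_complement(mirna.seed)
    rows = []
    for gene, seq in target_seqs.items():
        seq = seq.upper().replace("T", "U")
        if set(seq) - set("ACGU"):
            raise InvalidAlphabetError(f"non-nucleotide symbols in {gene!r}")
        count = _count_overlapping(seq, site)
        if count >= 1:
            rows.append((mirna.name, gene, "seedmatch", count))
    return pd.DataFrame(rows, columns=["mirna", "target", "tool", "n_sites"])


def _count_overlapping(seq: str, site: str) -> int:
    count = start = 0
    while True:
        pos = seq.find(site, start)
        if pos == -1:
            return count
        count += 1
        start = pos + 1


def build_network(pairs: pd.DataFrame, mrna_log_cpm: ExpressionMatrix,
                  annotations: Mapping[str, Mapping],
                  mrna_mrna_min_r: float = DEFAULT_MRNA_MIN_R,
                  corr_kind: str = "spearman") -> nx.DiGraph:
    """Assemble the annotated regulatory network.

    Nodes are the miRNAs of the high-confidence pair list plus their
    first-neighbour mRNAs; each miRNA→mRNA edge carries its rho.  mRNA–mRNA
    co-expression edges (inclusive threshold) connect included mRNAs, stored
    once per unordered pair.  Every node must have an annotation mapping with
    keys ``log2fc_day21_aav``, ``n_significant_contrasts`` and
    ``lung_function_r``.
    """
    if corr_kind not in ("spearman", "pearson"):
        raise FormatsError(f"unknown correlation kind {corr_kind!r}")
    net = nx.DiGraph()
    mirnas = sorted(pairs["mirna"].unique())
    mrnas = sorted(pairs["mrna"].unique())
    for node, kind in [(m, "mirna") for m in mirnas] + [(g, "mrna") for g in mrnas]:
        if node not in annotations:
            raise MissingAnnotationError(f"no annotation for node {node!r}")
        ann = annotations[node]
        net.add_node(node, kind=kind,
                     log2fc_day21_aav=float(ann["log2fc_day21_aav"]),
                     n_significant_contrasts=int(ann["n_significant_contrasts"]),
                     lung_function_r=float(ann["lung_function_r"]))
    for row in pairs.itertuples(index=False):
        net.add_edge(row.mirna, row.mrna, kind="mirna_mrna", weight=float(row.rho))
    if len(mrnas) >= 2:
        sub = mrna_log_cpm.values.loc[[g for g in mrnas
                                       if g in mrna_log_cpm.values.index]]
        missing = set(mrnas) - set(sub.index)
        if missing:
            raise FormatsError(f"mRNAs absent from expression matrix: {sorted(missing)}")
        mat = sub.to_numpy()
        if corr_kind == "spearman":
            mat = stats.rankdata(mat, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cc = np.corrcoef(mat)
        order = list(sub.index)
        for i in range(len(order)):
            for j in range(i + 1, len(order)):
                r = cc[i, j]
                if np.isfinite(r) and r >= mrna_mrna_min_r:
                    net.add_edge(order[i], order[j], kind="mrna_mrna",
                                 weight=float(r))
    return net
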