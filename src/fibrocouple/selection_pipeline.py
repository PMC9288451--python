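"""Staged miRNA hit selection and end-to-end pipeline orchestration.

The staged selection applies, in order: (1) lung-function correlation
|mean r| ≥ 0.85, the sign of r defining the direction of deregulation
(anti-correlated with compliance ⇒ UP); (2) differential expression
(|log2FC| ≥ 0.6, adjusted p ≤ 0.05) at at least one time point in each model;
(3) cross-model consistency of the day-21 fold-change sign, cross-checked
against the correlation-derived direction; (4) exclusion of upregulated,
non-conserved candidates (they cannot be targeted in humans); (5) attachment
of the candidate's high-confidence mRNA targets for reporting.  An audit
table records every candidate's fate at every stage.

``run_full_pipeline`` wires the whole package together from one YAML config
(synthetic simulation block or real input paths) and writes every artifact
with a config-hash stamp.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from importlib import resources

from . import diffexpr, formats_io, pheno_coupling, seed_conservation, synthstudy
from . import target_network
from .formats_io import FormatsError, InvalidAlphabetError


class ConfigurationError(FormatsError):
    pass


class UniverseMismatchError(FormatsError):
    """Selection inputs were not computed on the same miRNA universe."""


@dataclass
class SelectionConfig:
    """All thresholds of the staged selection, logged with every run."""

    r_threshold: float = 0.85
    lfc_threshold: float = 0.6
    alpha: float = 0.05
    min_de_timepoints: int = 1
    require_direction_consistency: bool = True
    exclude_up_nonconserved: bool = True
    rho_max: float = -0.6
    min_tools: int = 2
    mature_threshold: float = 20.0
    mature_inclusive: bool = True
    de_in_each_model: bool = True  # False: either model suffices at stage 2

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold <= 1:
            raise ConfigurationError("r_threshold must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.lfc_threshold < 0:
            raise ConfigurationError("lfc_threshold must be ≥ 0")
        if not -1 <= self.rho_max <= 0:
            raise ConfigurationError("rho_max must lie in [-1, 0]")
        if self.min_de_timepoints < 0 or self.min_tools < 1:
            raise ConfigurationError("counts must be positive")


def run_staged_selection(mirna_contrasts: pd.DataFrame,
                         mirna_corr: pd.DataFrame,
                         conservation: pd.DataFrame,
                         hc_pairs: pd.DataFrame,
                         config: SelectionConfig | None = None,
                         day: int = 21) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the staged filter cascade; return (hit list, audit table).

    The audit table has one row per stage-1 candidate and a ``fate`` column
    naming the stage that removed it (or ``hit``).
    """
    config = config or SelectionConfig()
    universe = set(mirna_contrasts["feature_id"])
    if not set(mirna_corr["feature_id"]) <= universe or not universe:
        raise UniverseMismatchError(
            "correlation table covers miRNAs absent from the contrasts")

    corr = mirna_corr.set_index("feature_id")
    cons = conservation.set_index("mouse_name")

    # stage 1: lung-function (anti-)correlation defines candidacy + direction
    stage1 = corr[corr["mean_r"].abs() >= config.r_threshold].copy()
    stage1["direction"] = np.where(stage1["mean_r"] < 0, "UP", "DOWN")

    audit_rows = []
    hits = []
    de = mirna_contrasts[mirna_contrasts["de_flag"]
                         & (mirna_contrasts["log2fc"].abs() >= config.lfc_threshold)
                         & (mirna_contrasts["adj_p"] <= config.alpha)]
    de_counts = de.groupby(["feature_id", "model"]).size().unstack(fill_value=0)
    lfc_day = (mirna_contrasts[mirna_contrasts["day"] == day]
               .pivot(index="feature_id", columns="model", values="log2fc"))

    for name, row in stage1.iterrows():
        fate = "hit"
        # stage 2: DE at ≥ min_de_timepoints time points (per model or either)
        n_b = int(de_counts.at[name, "bleomycin"]) \
            if name in de_counts.index and "bleomycin" in de_counts else 0
        n_a = int(de_counts.at[name, "aav_tgfb1"]) \
            if name in de_counts.index and "aav_tgfb1" in de_counts else 0
        if config.de_in_each_model:
            de_ok = (n_b >= config.min_de_timepoints
                     and n_a >= config.min_de_timepoints)
        else:
            de_ok = max(n_b, n_a) >= config.min_de_timepoints
        if not de_ok:
            fate = "stage2_differential_expression"
        # stage 3: consistent deregulation across the models at the anchor day
        if fate == "hit" and config.require_direction_consistency:
            lb = lfc_day.at[name, "bleomycin"] if name in lfc_day.index else np.nan
            la = lfc_day.at[name, "aav_tgfb1"] if name in lfc_day.index else np.nan
            signs_agree = np.isfinite(lb) and np.isfinite(la) and \
                np.sign(lb) == np.sign(la) and np.sign(lb) != 0
            expected = 1.0 if row["direction"] == "UP" else -1.0
            if not signs_agree or np.sign(lb) != expected:
                fate = "stage3_model_consistency"
        # stage 4: upregulated, non-conserved candidates cannot be targeted
        category = cons.at[name, "category"] if name in cons.index else "unpaired"
        if fate == "hit" and config.exclude_up_nonconserved \
                and row["direction"] == "UP" and category != "conserved":
            fate = "stage4_conservation"
        audit_rows.append({
            "mirna": name, "direction": row["direction"], "mean_r": row["mean_r"],
            "n_de_bleomycin": n_b, "n_de_aav": n_a,
            "conservation": category, "fate": fate,
        })
        if fate == "hit":
            targets = hc_pairs[hc_pairs["mirna"] == name]["mrna"].tolist() \
                if len(hc_pairs) else []
            hits.append({
                "mirna": name,
                "direction": row["direction"],
                "mature_seq": cons.at[name, "mouse_mature_seq"]
                if name in cons.index else "",
                "mean_r": row["mean_r"],
                "conservation": category,
                "n_targets": len(targets),
                "targets": ",".join(sorted(targets)),
            })

    hit_list = pd.DataFrame(
        hits, columns=["mirna", "direction", "mature_seq", "mean_r",
                       "conservation", "n_targets", "targets"])
    if hit_list["mirna"].duplicated().any():
        raise FormatsError("duplicate miRNA in hit list")
    audit = pd.DataFrame(
        audit_rows, columns=["mirna", "direction", "mean_r", "n_de_bleomycin",
                             "n_de_aav", "conservation", "fate"])
    return (hit_list.sort_values(["direction", "mirna"]).reset_index(drop=True),
            audit.sort_values("mirna").reset_index(drop=True))


# ---------------------------------------------------------------------------
# Reference hit-list fixture
# ---------------------------------------------------------------------------

def load_reference_hits() -> pd.DataFrame:
    """Packaged reference hit list of lung-function-associated mouse miRNAs.

    28 transcribed entries (16 up-, 12 down-regulated) with mature sequences;
    used as a parsing fixture and as a realistic input example.
    """
    with resources.files("fibrocouple.data").joinpath(
            "mirna_hits_reference.tsv").open("r") as fh:
        return parse_hit_list(fh)


def parse_hit_list(source) -> pd.DataFrame:
    """Parse a hit-list TSV (columns mirna, direction, mature_seq) into a
    validated frame: unique names, UP/DOWN directions, RNA sequences."""
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"mirna", "direction", "mature_seq"}
    if not required <= set(df.columns):
        raise FormatsError(f"hit list needs columns {sorted(required)}")
    if df["mirna"].duplicated().any():
        raise formats_io.DuplicateIdError("duplicate miRNA in hit list")
    bad_dir = set(df["direction"]) - {"UP", "DOWN"}
    if bad_dir:
        raise formats_io.UnknownTokenError(f"unknown directions {sorted(bad_dir)}")
    for seq in df["mature_seq"]:
        if set(str(seq).upper().replace("T", "U")) - formats_io.RNA_ALPHABET:
            raise InvalidAlphabetError(f"non-RNA hit sequence {seq!r}")
    df["mature_seq"] = [s.upper().replace("T", "U") for s in df["mature_seq"]]
    return df


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def config_hash(config: Mapping) -> str:
    """Stable short hash of a config mapping (stamped on every output file)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_pipeline(config: Mapping | str | Path, out_dir: str | Path,
                      seed: int | None = None) -> dict:
    """Run simulate → DE → coupling → conservation → network → selection.

    ``config`` is a mapping or a YAML file path with a ``simulate`` block (or
    ``inputs`` paths), optional ``selection`` overrides and optional ``de``
    thresholds.  Returns a dict of the in-memory artifacts; writes TSV/SIF/
    GraphML files plus a run log, all stamped with the config hash.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    if seed is not None:
        config.setdefault("simulate", {})
        config["simulate"]["rng_seed"] = int(seed)
    chash = config_hash(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config_hash={chash}"]

    sel_cfg = SelectionConfig(**config.get("selection", {}))
    de_cfg = config.get("de", {})
    lfc_thr = float(de_cfg.get("lfc_threshold", diffexpr.DEFAULT_LFC_THRESHOLD))
    alpha = float(de_cfg.get("alpha", diffexpr.DEFAULT_ALPHA))
    min_cpm = float(de_cfg.get("min_cpm", 1.0))
    for key, val in sorted({**asdict(sel_cfg), "lfc_threshold_de": lfc_thr,
                            "alpha_de": alpha, "min_cpm": min_cpm}.items()):
        log_lines.append(f"threshold {key}={val}")

    if "simulate" in config:
        sim_cfg = synthstudy.SimulationConfig.from_dict(config["simulate"])
        (mrna, mirna, design, trajectories, mouse_recs, human_recs,
         predictions, truth) = synthstudy.generate_study(sim_cfg)
        log_lines.append(f"simulated study with seed {sim_cfg.rng_seed}")
    elif "inputs" in config:
        paths = config["inputs"]
        for key in ("mrna_counts", "mirna_counts", "sample_sheet", "phenotype",
                    "mouse_fasta", "human_fasta", "predictions"):
            if key not in paths:
                raise ConfigurationError(f"inputs block is missing {key!r}")
            if not Path(paths[key]).exists():
                raise ConfigurationError(f"input path does not exist: {paths[key]}")
        mrna = formats_io.read_counts(paths["mrna_counts"], "mrna")
        mirna = formats_io.read_counts(paths["mirna_counts"], "mirna")
        design = formats_io.read_sample_sheet(paths["sample_sheet"])
        trajectories = formats_io.read_phenotype(paths["phenotype"])
        mouse_recs = formats_io.read_mirna_fasta(paths["mouse_fasta"], "mouse")
        human_recs = formats_io.read_mirna_fasta(paths["human_fasta"], "human")
        predictions = formats_io.read_predictions(paths["predictions"])
        truth = None
    else:
        raise ConfigurationError(
            "config must contain a 'simulate' block or an 'inputs' block")

    # differential expression on both matrices
    artifacts = {}
    filtered = {}
    contrasts = {}
    for label, mat in (("mrna", mrna), ("mirna", mirna)):
        kept = diffexpr.filter_low_expression(mat, design, min_cpm=min_cpm)
        log_cpm = diffexpr.normalize_log_cpm(kept)
        res = diffexpr.run_all_contrasts(log_cpm, design,
                                         lfc_threshold=lfc_thr, alpha=alpha)
        filtered[label] = log_cpm
        contrasts[label] = res
        formats_io.write_contrasts(
            res, out_dir / f"contrasts_{label}.tsv",
            header_comment=f"config_hash={chash}")
        log_lines.append(
            f"{label}: {mat.shape[0]} features, {kept.shape[0]} after filtering, "
            f"{int(res['de_flag'].sum())} DE calls over "
            f"{res[['model', 'day']].drop_duplicates().shape[0]} contrasts")

    # phenotype coupling
    coupling = {
        label: pheno_coupling.correlate_with_lung_function(contrasts[label],
                                                           trajectories)
        for label in ("mrna", "mirna")
    }
    for label, corr in coupling.items():
        formats_io._write_tsv(corr, out_dir / f"lung_function_corr_{label}.tsv",
                              header_comment=f"config_hash={chash}")

    # conservation
    conservation = seed_conservation.classify_all(
        mouse_recs, human_recs, mature_threshold=sel_cfg.mature_threshold,
        inclusive=sel_cfg.mature_inclusive)
    formats_io._write_tsv(conservation, out_dir / "conservation_calls.tsv",
                          header_comment=f"config_hash={chash}")
    log_lines.append(
        "conservation: "
        f"{int((conservation['category'] == 'conserved').sum())} conserved, "
        f"{int((conservation['category'] == 'non_conserved').sum())} non-conserved, "
        f"{int((conservation['category'] == 'unpaired').sum())} unpaired")

    # miRNA-mRNA pairing and network
    pair_corr = target_network.correlate_all_pairs(filtered["mirna"],
                                                   filtered["mrna"])
    hc_pairs = target_network.intersect_high_confidence(
        pair_corr, predictions, rho_max=sel_cfg.rho_max,
        min_tools=sel_cfg.min_tools)
    formats_io._write_tsv(hc_pairs, out_dir / "high_confidence_pairs.tsv",
                          header_comment=f"config_hash={chash}")
    log_lines.append(f"pairing: {len(pair_corr)} pairs scored, "
                     f"{len(hc_pairs)} high-confidence")

    annotations = _collect_annotations(contrasts, coupling, hc_pairs)
    network = target_network.build_network(hc_pairs, filtered["mrna"], annotations)
    network.graph["config_hash"] = chash
    formats_io.write_network(network, out_dir / "network.sif", "sif")
    formats_io.write_network(network, out_dir / "network.graphml", "graphml")
    log_lines.append(f"network: {network.number_of_nodes()} nodes, "
                     f"{network.number_of_edges()} edges "
                     "(network.sif, network.graphml)")

    # staged selection
    hit_list, audit = run_staged_selection(contrasts["mirna"], coupling["mirna"],
                                           conservation, hc_pairs, sel_cfg)
    formats_io._write_tsv(hit_list, out_dir / "hit_list.tsv",
                          header_comment=f"config_hash={chash}")
    formats_io._write_tsv(audit, out_dir / "selection_audit.tsv",
                          header_comment=f"config_hash={chash}")
    log_lines.append(
        f"selection: {len(audit)} stage-1 candidates in, {len(hit_list)} hits out "
        f"({int((hit_list['direction'] == 'UP').sum())} UP, "
        f"{int((hit_list['direction'] == 'DOWN').sum())} DOWN)")

    (out_dir / "run_log.txt").write_text(
        f"# config_hash={chash}\n" + "\n".join(log_lines) + "\n")

    artifacts.update({
        "contrasts": contrasts, "coupling": coupling,
        "conservation": conservation, "pair_corr": pair_corr,
        "hc_pairs": hc_pairs, "network": network,
        "hit_list": hit_list, "audit": audit, "truth": truth,
        "trajectories": trajectories, "config_hash": chash,
        "design": design, "log_cpm": filtered,
    })
    return artifacts


def _collect_annotations(contrasts: Mapping[str, pd.DataFrame],
                         coupling: Mapping[str, pd.DataFrame],
                         hc_pairs: pd.DataFrame) -> dict[str, dict]:
    """Node annotations: AAV day-21 log2FC, #significant contrasts, lung r."""
    annotations: dict[str, dict] = {}
    for label in ("mirna", "mrna"):
        res = contrasts[label]
        aav21 = res[(res["model"] == "aav_tgfb1") & (res["day"] == 21)] \
            .set_index("feature_id")["log2fc"]
        n_sig = res[res["de_flag"]].groupby("feature_id").size()
        corr = coupling[label].set_index("feature_id")["mean_r"]
        for fid in res["feature_id"].unique():
            annotations[fid] = {
                "log2fc_day21_aav": float(aav21.get(fid, np.nan)),
                "n_significant_contrasts": int(n_sig.get(fid, 0)),
                "lung_function_r": float(corr.get(fid, np.nan)),
            }
    return annotations
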