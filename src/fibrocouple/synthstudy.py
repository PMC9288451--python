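"""Synthetic two-model longitudinal fibrosis study with planted ground truth.

Emulates the study design the pipeline analyses: five sampling days (3, 7, 14,
21, 28 post-administration), an AAV-TGFβ1 arm (treated n=5, stuffer controls
n=5) and a Bleomycin arm (treated n=8, NaCl controls n=6), negative-binomial
bulk counts for mRNA and miRNA, a declining lung-compliance trajectory per
model with delayed onset in the AAV arm, planted gene/miRNA modules whose
log2FC trajectories track (or anti-track) the compliance deficit, planted
miRNA→target repression, and mouse–human miRNA ortholog pairs with controlled
seed conservation.

The disease signal is a logistic ramp of the compliance deficit: Bleomycin
declines from the first sampling day, the AAV model stays near baseline until
the onset delay and then declines, and both models reach comparable minima
around day 21.  Planted features scale this deficit so their log2 fold change
reaches ``effect_size_log2fc_day21`` at day 21.

Everything is driven by one integer seed; identical configs yield identical
outputs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .formats_io import (
    DEFAULT_DAYS,
    ExpressionMatrix,
    FormatsError,
    MiRNARecord,
    PhenotypeTrajectory,
    PredictionTable,
    SampleDesign,
    SampleSheet,
)

PREDICTION_TOOLS = ("diana", "miranda", "pictar", "targetscan", "mirdb")

RNA_BASES = np.array(list("ACGU"))
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; the defaults are the study conditions."""

    rng_seed: int
    n_genes: int = 2000
    n_mirnas: int = 300
    group_sizes: Mapping[tuple[str, str], int] = field(default_factory=lambda: {
        ("aav_tgfb1", "treated"): 5,
        ("aav_tgfb1", "control"): 5,
        ("bleomycin", "treated"): 8,
        ("bleomycin", "control"): 6,
    })
    days: tuple[int, ...] = DEFAULT_DAYS
    library_size_mean: float = 1e6
    library_size_log_sd: float = 0.15
    dispersion: float = 0.05
    baseline_log_sd: float = 1.5
    # planted phenotype-tracking genes
    n_tracking_up: int = 20
    n_tracking_down: int = 10
    # planted miRNAs, by direction × conservation
    n_mirna_up_conserved: int = 4
    n_mirna_up_nonconserved: int = 2
    n_mirna_down_conserved: int = 4
    n_mirna_down_nonconserved: int = 2
    targets_per_mirna: int = 3
    effect_size_log2fc_day21: float = 2.0
    onset_delay_days: float = 7.0
    repression_strength: float = 0.8
    # compliance trajectory (mL/cmH2O)
    baseline_compliance: float = 0.06
    compliance_drop_frac: float = 0.5
    compliance_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise FormatsError("rng_seed is required: no implicit randomness")
        if self.dispersion <= 0:
            raise FormatsError("dispersion must be > 0")
        if self.effect_size_log2fc_day21 <= 0:
            raise FormatsError("effect size must be > 0")
        if not 0 <= self.repression_strength <= 1:
            raise FormatsError("repression_strength must lie in [0, 1]")
        if self.n_tracking_up + self.n_tracking_down > self.n_genes:
            raise FormatsError("more planted tracking genes than genes")
        n_planted_mirnas = (self.n_mirna_up_conserved + self.n_mirna_up_nonconserved
                            + self.n_mirna_down_conserved + self.n_mirna_down_nonconserved)
        if n_planted_mirnas > self.n_mirnas:
            raise FormatsError("more planted miRNAs than miRNAs")
        n_targets = n_planted_mirnas * self.targets_per_mirna
        if n_targets + self.n_tracking_up + self.n_tracking_down > self.n_genes:
            raise FormatsError("not enough genes for planted targets")
        if len(self.days) < 2:
            raise FormatsError("need at least two study days")

    @property
    def n_planted_mirnas(self) -> int:
        return (self.n_mirna_up_conserved + self.n_mirna_up_nonconserved
                + self.n_mirna_down_conserved + self.n_mirna_down_nonconserved)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "group_sizes" in d and not isinstance(next(iter(d["group_sizes"])), tuple):
            d["group_sizes"] = {
                tuple(k.split("/")): v for k, v in d["group_sizes"].items()}
        if "days" in d:
            d["days"] = tuple(int(x) for x in d["days"])
        return cls(**d)


@dataclass
class GroundTruth:
    """The planted structure a recovery analysis is measured against."""

    genes_up: list[str]
    genes_down: list[str]
    mirnas: pd.DataFrame            # name, direction, conserved, paired
    mirna_targets: list[tuple[str, str]]
    expected_hit_mirnas: list[str]  # planted minus (UP and non-conserved)
    deficit: dict[str, np.ndarray]  # noiseless generating deficit per model
    trajectories: dict[str, PhenotypeTrajectory]


# ---------------------------------------------------------------------------
# Compliance trajectories
# ---------------------------------------------------------------------------

def _deficit_curve(model: str, days: np.ndarray, onset_delay: float,
                   drop_frac: float) -> np.ndarray:
    """Noiseless fractional compliance deficit: a logistic ramp over days.

    Bleomycin ramps from the first sampling day (midpoint day 6); the AAV
    model's midpoint is shifted by the onset delay, leaving it near baseline
    at day 3 for the default delay of 7 days.  Both saturate near
    ``drop_frac`` by day 21.
    """
    days = np.asarray(days, dtype=float)
    if model == "bleomycin":
        t0, tau = 6.0, 4.0
    else:
        t0, tau = 6.0 + onset_delay, 3.0
    return drop_frac / (1.0 + np.exp(-(days - t0) / tau))


def generate_compliance(model: str, days=DEFAULT_DAYS, seed: int = 0,
                        onset_delay: float = 7.0, baseline: float = 0.06,
                        drop_frac: float = 0.5,
                        noise_sd: float = 0.005) -> PhenotypeTrajectory:
    """Group-mean lung compliance over the study days, with measurement noise.

    Values are strictly positive; the Bleomycin mean declines from day 3 while
    the AAV-TGFβ1 mean stays near baseline until the onset delay has passed.
    """
    days = tuple(int(d) for d in days)
    rng = np.random.default_rng(seed)
    deficit = _deficit_curve(model, np.asarray(days), onset_delay, drop_frac)
    values = baseline * (1.0 - deficit) * np.exp(rng.normal(0, noise_sd, len(days)))
    return PhenotypeTrajectory(model=model, days=days,
                               compliance=tuple(float(v) for v in values))


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RNA_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    out = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGU" if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------

def _build_design(config: SimulationConfig) -> SampleSheet:
    designs = []
    for day in config.days:
        for (model, arm), n in sorted(config.group_sizes.items()):
            for i in range(1, n + 1):
                sid = f"{model}_{arm}_d{day}_{i}"
                designs.append(SampleDesign(sample_id=sid, model=model, arm=arm,
                                            day=day, animal_id=sid))
    return SampleSheet(designs, days=config.days)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts via a gamma–Poisson mixture."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(float)


def _signal_matrix(feature_ids: list[str], design: SampleSheet,
                   signals: Mapping[str, Mapping[str, np.ndarray]],
                   days: tuple[int, ...]) -> np.ndarray:
    """Per-feature per-sample log2 signal (0 for controls and unplanted)."""
    day_index = {d: i for i, d in enumerate(days)}
    sig = np.zeros((len(feature_ids), len(design)))
    fid_index = {f: i for i, f in enumerate(feature_ids)}
    for j, d in enumerate(design):
        if d.arm != "treated":
            continue
        per_model = signals.get(d.model)
        if per_model is None:
            continue
        for fid, curve in per_model.items():
            sig[fid_index[fid], j] = curve[day_index[d.day]]
    return sig


def generate_study(config: SimulationConfig):
    """Generate the complete synthetic study.

    Returns ``(mrna, mirna, design, trajectories, mouse_records, human_records,
    predictions, truth)`` where trajectories is a dict keyed by model.
    """
    rng = np.random.default_rng(config.rng_seed)
    days = tuple(config.days)
    design = _build_design(config)
    models = ("bleomycin", "aav_tgfb1")

    # --- disease signal per model (noiseless deficit, normalised to day 21) ---
    deficit = {m: _deficit_curve(m, np.asarray(days, float),
                                 config.onset_delay_days,
                                 config.compliance_drop_frac) for m in models}
    day21 = 21 if 21 in days else days[-1]
    i21 = days.index(day21)
    s_norm = {m: deficit[m] / deficit[m][i21] for m in models}

    trajectories = {
        m: generate_compliance(
            m, days=days, seed=int(rng.integers(2 ** 31)),
            onset_delay=config.onset_delay_days,
            baseline=config.baseline_compliance,
            drop_frac=config.compliance_drop_frac,
            noise_sd=config.compliance_noise_sd)
        for m in models
    }

    # --- feature universes and planted assignments ---
    gene_ids = [f"gene{i:05d}" for i in range(config.n_genes)]
    mirna_specs = _plant_mirnas(config)
    mirna_ids = [spec["name"] for spec in mirna_specs]

    genes_up = gene_ids[:config.n_tracking_up]
    genes_down = gene_ids[config.n_tracking_up:
                          config.n_tracking_up + config.n_tracking_down]
    n_reserved = config.n_tracking_up + config.n_tracking_down
    target_pool = gene_ids[n_reserved:
                           n_reserved + config.n_planted_mirnas * config.targets_per_mirna]

    planted = [s for s in mirna_specs if s["direction"] is not None]
    mirna_targets: list[tuple[str, str]] = []
    for k, spec in enumerate(planted):
        targets = target_pool[k * config.targets_per_mirna:
                              (k + 1) * config.targets_per_mirna]
        spec["targets"] = targets
        mirna_targets.extend((spec["name"], g) for g in targets)

    eff = config.effect_size_log2fc_day21
    gene_signals = {m: {} for m in models}
    for g in genes_up:
        for m in models:
            gene_signals[m][g] = eff * s_norm[m]
    for g in genes_down:
        for m in models:
            gene_signals[m][g] = -eff * s_norm[m]

    mirna_signals = {m: {} for m in models}
    for spec in planted:
        sign = 1.0 if spec["direction"] == "UP" else -1.0
        for m in models:
            mirna_signals[m][spec["name"]] = sign * eff * s_norm[m]
        # repression couples the target's mean to the miRNA's disease signal:
        # an induced miRNA suppresses its targets, a lost miRNA de-represses them
        for g in spec["targets"]:
            for m in models:
                factor = 1.0 - sign * config.repression_strength * s_norm[m]
                factor = np.maximum(factor, 0.05)
                gene_signals[m][g] = np.log2(factor)

    # --- count matrices ---
    mrna = _simulate_counts(rng, gene_ids, design, gene_signals, config, "mrna",
                            high_expr_ids=set(genes_up) | set(genes_down)
                            | set(target_pool))
    mirna = _simulate_counts(rng, mirna_ids, design, mirna_signals, config, "mirna",
                             high_expr_ids={s["name"] for s in planted})

    # --- sequences and orthologs ---
    mouse_records, human_records = _make_sequences(rng, mirna_specs)

    # --- prediction table: planted pairs under ≥2 tools, decoys under 1 ---
    predictions = _make_predictions(rng, planted, mirna_ids, gene_ids,
                                    mirna_targets, config)

    mirna_truth = pd.DataFrame([
        {"name": s["name"], "direction": s["direction"],
         "conserved": s["conserved"], "paired": s["paired"]}
        for s in mirna_specs if s["direction"] is not None])
    expected_hits = [s["name"] for s in planted
                     if not (s["direction"] == "UP" and not s["conserved"])]
    truth = GroundTruth(
        genes_up=genes_up, genes_down=genes_down, mirnas=mirna_truth,
        mirna_targets=mirna_targets, expected_hit_mirnas=expected_hits,
        deficit=deficit, trajectories=trajectories,
    )
    return mrna, mirna, design, trajectories, mouse_records, human_records, \
        predictions, truth


def _plant_mirnas(config: SimulationConfig) -> list[dict]:
    """Assign direction/conservation labels to the miRNA universe."""
    specs = []
    blocks = [
        ("UP", True, config.n_mirna_up_conserved),
        ("UP", False, config.n_mirna_up_nonconserved),
        ("DOWN", True, config.n_mirna_down_conserved),
        ("DOWN", False, config.n_mirna_down_nonconserved),
    ]
    idx = 0
    for direction, conserved, n in blocks:
        for _ in range(n):
            specs.append({"name": f"mmu-miR-s{idx:03d}-5p", "direction": direction,
                          "conserved": conserved, "paired": True, "targets": []})
            idx += 1
    for i in range(idx, config.n_mirnas):
        specs.append({"name": f"mmu-miR-s{i:03d}-5p", "direction": None,
                      "conserved": None, "paired": None, "targets": []})
    return specs


def _simulate_counts(rng: np.random.Generator, feature_ids: list[str],
                     design: SampleSheet,
                     signals: Mapping[str, Mapping[str, np.ndarray]],
                     config: SimulationConfig, kind: str,
                     high_expr_ids: set[str]) -> ExpressionMatrix:
    n_feat = len(feature_ids)
    weights = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=n_feat)
    # planted features sit in a well-expressed stratum, as fibrosis markers do
    for i, fid in enumerate(feature_ids):
        if fid in high_expr_ids:
            weights[i] = rng.lognormal(mean=1.5, sigma=0.5)
    base = weights / weights.sum() * config.library_size_mean
    lib_factor = rng.lognormal(mean=0.0, sigma=config.library_size_log_sd,
                               size=len(design))
    sig = _signal_matrix(feature_ids, design, signals, tuple(config.days))
    mu = base[:, None] * (2.0 ** sig) * lib_factor[None, :]
    counts = _nb_counts(rng, mu, config.dispersion)
    values = pd.DataFrame(counts, index=feature_ids, columns=design.sample_ids)
    return ExpressionMatrix(values=values, kind=kind, scale="counts")


def _make_sequences(rng: np.random.Generator, mirna_specs: list[dict]
                    ) -> tuple[list[MiRNARecord], list[MiRNARecord]]:
    mouse_records, human_records = [], []
    for spec in mirna_specs:
        mature = _random_rna(rng, 22)
        mouse_records.append(MiRNARecord(name=spec["name"], species="mouse",
                                         mature_seq=mature))
        if spec["paired"] is None:
            # background miRNAs: most have a human partner, some do not
            spec["paired"] = bool(rng.random() < 0.8)
            spec_conserved = bool(rng.random() < 0.5)
        else:
            spec_conserved = spec["conserved"]
        if not spec["paired"]:
            continue
        human_seq = mature
        if spec_conserved:
            # seed (positions 2-7, indices 1..6) kept identical; ≤2 mutations
            # elsewhere keep the mature alignment score at or above 20/22
            n_mut = int(rng.integers(0, 3))
            allowed = np.array([p for p in range(22) if not 1 <= p <= 6])
            pos = rng.choice(allowed, size=n_mut, replace=False)
            human_seq = _mutate(rng, human_seq, pos)
        else:
            n_seed_mut = int(rng.integers(1, 3))
            seed_pos = rng.choice(np.arange(1, 7), size=n_seed_mut, replace=False)
            human_seq = _mutate(rng, human_seq, seed_pos)
        human_name = "hsa-" + spec["name"].split("-", 1)[1]
        human_records.append(MiRNARecord(name=human_name, species="human",
                                         mature_seq=human_seq))
    return mouse_records, human_records


def _make_predictions(rng: np.random.Generator, planted: list[dict],
                      mirna_ids: list[str], gene_ids: list[str],
                      mirna_targets: list[tuple[str, str]],
                      config: SimulationConfig) -> PredictionTable:
    tools = np.array(PREDICTION_TOOLS)
    rows = []
    for mi, g in mirna_targets:
        n_tools = int(rng.integers(2, 4))
        for tool in rng.choice(tools, size=n_tools, replace=False):
            rows.append((mi, g, tool))
    # decoys under a single tool: random pairs, plus anticorrelated-but-
    # unsupported pairs (a planted miRNA with another planted miRNA's target)
    # so the ≥2-tool filter has work to do
    planted_names = [s["name"] for s in planted]
    target_by_mirna = {s["name"]: s["targets"] for s in planted}
    for _ in range(150):
        mi = mirna_ids[rng.integers(len(mirna_ids))]
        g = gene_ids[rng.integers(len(gene_ids))]
        rows.append((mi, g, tools[rng.integers(len(tools))]))
    if len(planted_names) >= 2:
        for _ in range(20):
            a, b = rng.choice(len(planted_names), size=2, replace=False)
            other_targets = target_by_mirna[planted_names[b]]
            if not other_targets:
                continue
            g = other_targets[rng.integers(len(other_targets))]
            rows.append((planted_names[a], g, tools[rng.integers(len(tools))]))
    # two-tool decoys on uncorrelated pairs: pass the tool filter, fail rho
    for _ in range(50):
        mi = mirna_ids[rng.integers(len(mirna_ids))]
        g = gene_ids[rng.integers(len(gene_ids))]
        for tool in rng.choice(tools, size=2, replace=False):
            rows.append((mi, g, tool))
    df = pd.DataFrame(rows, columns=["mirna", "target", "tool"])
    df = df.drop_duplicates(["mirna", "target", "tool"]).reset_index(drop=True)
    return PredictionTable(table=df, tools=PREDICTION_TOOLS)
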