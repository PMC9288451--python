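"""Correlation primitives, lung-function coupling, selection and partitions."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fibrocouple import diffexpr, pheno_coupling as pc
from fibrocouple.formats_io import FormatsError, PhenotypeTrajectory
from fibrocouple.synthstudy import SimulationConfig, generate_study


def _pearson_formula_oracle(x, y):
    """Direct evaluation of the product-moment covariance formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum()))


class TestPearson:
    def test_perfect_linearity(self):
        assert pc.pearson_r([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]) == pytest.approx(1.0)

    def test_reflection(self):
        assert pc.pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x, y = (3, 7, 14, 21, 28), (1, 2, 2, 3, 6)
        assert pc.pearson_r(x, y) == pytest.approx(_pearson_formula_oracle(x, y),
                                                   abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(pc.UndefinedCorrelationError):
            pc.pearson_r([1.0, 1.0, 1.0], [1, 2, 3])

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=rng.integers(3, 30))
            y = rng.normal(size=x.size)
            assert pc.pearson_r(x, y) == pytest.approx(
                _pearson_formula_oracle(x, y), abs=1e-12)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pc.spearman_rho(x, x ** 3) == pytest.approx(1.0)

    def test_hand_ranked_tie_case(self):
        # ranks of y=(10,10,5,1) are (3.5, 3.5, 2, 1)
        expected = _pearson_formula_oracle([1, 2, 3, 4], [3.5, 3.5, 2, 1])
        assert pc.spearman_rho([1, 2, 3, 4], [10, 10, 5, 1]) == pytest.approx(
            expected, abs=1e-12)

    def test_all_tied_raises(self):
        with pytest.raises(pc.UndefinedCorrelationError):
            pc.spearman_rho([5, 5, 5, 5], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=20, unique=True),
           st.lists(st.integers(-1000, 1000), min_size=3, max_size=20))
    def test_invariant_under_strictly_monotone_transform(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        if np.ptp(y) == 0:
            return
        direct = pc.spearman_rho(x, y)
        # x**3 is strictly monotone and exact for |x| <= 1000 in float64
        transformed = pc.spearman_rho(x ** 3, y)
        assert direct == pytest.approx(transformed, abs=1e-12)


def _toy_contrasts(profiles_by_model):
    """Build a contrast table from {model: {feature: [lfc per day]}}."""
    days = (3, 7, 14, 21, 28)
    rows = []
    for model, feats in profiles_by_model.items():
        for fid, prof in feats.items():
            for d, v in zip(days, prof):
                rows.append({"feature_id": fid, "model": model, "day": d,
                             "log2fc": v, "p_value": 0.5, "adj_p": 0.5,
                             "mean_log_cpm": 5.0, "de_flag": False})
    return pd.DataFrame(rows)


def _toy_trajectories():
    days = (3, 7, 14, 21, 28)
    return {
        "bleomycin": PhenotypeTrajectory("bleomycin", days,
                                         (0.055, 0.045, 0.035, 0.030, 0.030)),
        "aav_tgfb1": PhenotypeTrajectory("aav_tgfb1", days,
                                         (0.060, 0.058, 0.044, 0.032, 0.030)),
    }


class TestCorrelateWithLungFunction:
    def test_affine_anticorrelation_gives_minus_one(self):
        traj = _toy_trajectories()
        profiles = {m: {"g": [5.0 - 50.0 * c for c in traj[m].compliance]}
                    for m in traj}
        corr = pc.correlate_with_lung_function(_toy_contrasts(profiles), traj)
        row = corr.set_index("feature_id").loc["g"]
        assert row["r_bleomycin"] == pytest.approx(-1.0)
        assert row["r_aav"] == pytest.approx(-1.0)
        assert row["mean_r"] == pytest.approx(-1.0)
        assert not row["undefined"]

    def test_constant_profile_flagged_undefined_not_zero(self):
        traj = _toy_trajectories()
        profiles = {m: {"g": [0.7] * 5} for m in traj}
        corr = pc.correlate_with_lung_function(_toy_contrasts(profiles), traj)
        row = corr.set_index("feature_id").loc["g"]
        assert row["undefined"]
        assert np.isnan(row["mean_r"])

    def test_mismatched_day_grid_rejected(self):
        traj = _toy_trajectories()
        bad = {"bleomycin": PhenotypeTrajectory("bleomycin", (3, 7, 14),
                                                (0.05, 0.04, 0.03)),
               "aav_tgfb1": traj["aav_tgfb1"]}
        profiles = {m: {"g": [1, 2, 3, 4, 5]} for m in traj}
        with pytest.raises(FormatsError):
            pc.correlate_with_lung_function(_toy_contrasts(profiles), bad)

    def test_planted_up_genes_strongly_anticorrelated_across_seeds(self):
        hits = total = 0
        for seed in range(20):
            cfg = SimulationConfig(rng_seed=seed + 300, n_genes=300, n_mirnas=60)
            mrna, _, design, traj, *_, truth = generate_study(cfg)
            log_cpm = diffexpr.normalize_log_cpm(
                diffexpr.filter_low_expression(mrna, design))
            contrasts = diffexpr.run_all_contrasts(log_cpm, design)
            corr = pc.correlate_with_lung_function(contrasts, traj)
            sub = corr.set_index("feature_id")
            present = [g for g in truth.genes_up if g in sub.index]
            hits += int((sub.loc[present, "mean_r"] <= -0.85).sum())
            total += len(present)
        assert hits / total >= 0.9


def _random_selection_fixture(seed=0, n=200):
    rng = np.random.default_rng(seed)
    feats = [f"g{i}" for i in range(n)]
    corr = pd.DataFrame({
        "feature_id": feats,
        "r_bleomycin": rng.uniform(-1, 1, n),
        "r_aav": rng.uniform(-1, 1, n),
        "n_points": 5, "undefined": False,
    })
    corr["mean_r"] = corr[["r_bleomycin", "r_aav"]].mean(axis=1)
    rows = []
    for model in ("bleomycin", "aav_tgfb1"):
        for fid in feats:
            rows.append({"feature_id": fid, "model": model, "day": 21,
                         "log2fc": rng.normal(scale=2),
                         "p_value": rng.uniform(), "adj_p": rng.uniform(),
                         "mean_log_cpm": 5.0, "de_flag": False})
    return corr, pd.DataFrame(rows)


class TestSelectPhenotypeCoupledGenes:
    def test_rule_application_up(self):
        corr = pd.DataFrame({"feature_id": ["g"], "r_bleomycin": [-0.9],
                             "r_aav": [-0.9], "mean_r": [-0.9],
                             "n_points": 5, "undefined": False})
        contrasts = pd.DataFrame([
            {"feature_id": "g", "model": "bleomycin", "day": 21, "log2fc": 2.0,
             "p_value": 0.001, "adj_p": 0.01, "mean_log_cpm": 5.0, "de_flag": True},
            {"feature_id": "g", "model": "aav_tgfb1", "day": 21, "log2fc": 1.0,
             "p_value": 0.001, "adj_p": 0.01, "mean_log_cpm": 5.0, "de_flag": True},
        ])
        sel = pc.select_phenotype_coupled_genes(corr, contrasts, "up")
        assert list(sel["feature_id"]) == ["g"]
        assert sel["mean_lfc_day"].iloc[0] == pytest.approx(1.5)

    def test_direction_inconsistency_excluded(self):
        corr = pd.DataFrame({"feature_id": ["g"], "r_bleomycin": [-0.9],
                             "r_aav": [-0.9], "mean_r": [-0.9],
                             "n_points": 5, "undefined": False})
        contrasts = pd.DataFrame([
            {"feature_id": "g", "model": "bleomycin", "day": 21, "log2fc": 2.0,
             "p_value": 0.001, "adj_p": 0.01, "mean_log_cpm": 5.0, "de_flag": True},
            {"feature_id": "g", "model": "aav_tgfb1", "day": 21, "log2fc": -0.1,
             "p_value": 0.001, "adj_p": 0.01, "mean_log_cpm": 5.0, "de_flag": True},
        ])
        sel = pc.select_phenotype_coupled_genes(corr, contrasts, "up")
        assert sel.empty

    def test_matches_filter_then_sort_oracle(self):
        corr, contrasts = _random_selection_fixture(seed=4)
        sel = pc.select_phenotype_coupled_genes(corr, contrasts, "up",
                                                r_threshold=0.5, alpha=0.3)
        at21 = contrasts[contrasts["day"] == 21]
        lfc = at21.pivot(index="feature_id", columns="model", values="log2fc")
        adj = at21.pivot(index="feature_id", columns="model", values="adj_p")
        expected = []
        for row in corr.itertuples(index=False):
            f = row.feature_id
            if (row.mean_r <= -0.5
                    and adj.at[f, "bleomycin"] <= 0.3 and adj.at[f, "aav_tgfb1"] <= 0.3
                    and lfc.at[f, "bleomycin"] >= 0 and lfc.at[f, "aav_tgfb1"] >= 0):
                expected.append((f, (lfc.at[f, "bleomycin"] + lfc.at[f, "aav_tgfb1"]) / 2))
        expected.sort(key=lambda t: -t[1])
        assert list(sel["feature_id"]) == [f for f, _ in expected]

    def test_up_down_are_sign_flip_images(self):
        corr, contrasts = _random_selection_fixture(seed=9)
        up = pc.select_phenotype_coupled_genes(corr, contrasts, "up",
                                               r_threshold=0.4, alpha=0.5)
        flipped_corr = corr.copy()
        for col in ("r_bleomycin", "r_aav", "mean_r"):
            flipped_corr[col] = -flipped_corr[col]
        flipped_contrasts = contrasts.copy()
        flipped_contrasts["log2fc"] = -flipped_contrasts["log2fc"]
        down = pc.select_phenotype_coupled_genes(flipped_corr, flipped_contrasts,
                                                 "down", r_threshold=0.4, alpha=0.5)
        assert list(up["feature_id"]) == list(down["feature_id"])

    def test_top_n_truncates_after_ranking(self):
        corr, contrasts = _random_selection_fixture(seed=2)
        full = pc.select_phenotype_coupled_genes(corr, contrasts, "up",
                                                 r_threshold=0.2, alpha=0.8)
        top = pc.select_phenotype_coupled_genes(corr, contrasts, "up",
                                                r_threshold=0.2, alpha=0.8, top_n=5)
        assert list(top["feature_id"]) == list(full["feature_id"])[:5]


class TestPatternRank:
    def test_profile_equal_to_pattern_ranks_first(self):
        profiles = {m: {"match": [1, 0, 0, 0, 0], "other": [0, 1, 1, 1, 1]}
                    for m in ("bleomycin", "aav_tgfb1")}
        ranked = pc.pattern_rank(_toy_contrasts(profiles), [1, 0, 0, 0, 0],
                                 "bleomycin")
        assert ranked.iloc[0]["feature_id"] == "match"
        assert ranked.iloc[0]["r"] == pytest.approx(1.0)

    def test_day3_spike_outranks_day28_spike(self):
        profiles = {m: {"early": [5, 0, 0, 0, 0], "late": [0, 0, 0, 0, 5]}
                    for m in ("bleomycin", "aav_tgfb1")}
        ranked = pc.pattern_rank(_toy_contrasts(profiles), [1, 0, 0, 0, 0],
                                 "bleomycin").set_index("feature_id")
        assert ranked.at["early", "rank"] < ranked.at["late", "rank"]

    def test_constant_pattern_rejected(self):
        profiles = {m: {"g": [1, 2, 3, 4, 5]} for m in ("bleomycin", "aav_tgfb1")}
        with pytest.raises(pc.UndefinedCorrelationError):
            pc.pattern_rank(_toy_contrasts(profiles), [1, 1, 1, 1, 1], "bleomycin")

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(21)
        profiles = {"bleomycin": {f"g{i}": rng.normal(size=5).tolist()
                                  for i in range(40)},
                    "aav_tgfb1": {f"g{i}": [0.0] * 5 for i in range(40)}}
        pattern = rng.normal(size=5)
        ranked = pc.pattern_rank(_toy_contrasts(profiles), pattern, "bleomycin")
        brute = sorted(
            ((f, _pearson_formula_oracle(profiles["bleomycin"][f], pattern))
             for f in profiles["bleomycin"]), key=lambda t: -t[1])
        assert list(ranked["feature_id"]) == [f for f, _ in brute]


class TestPartitionModelSpecificity:
    def _contrasts(self, pairs):
        rows = []
        for fid, (lb, la) in pairs.items():
            rows.append({"feature_id": fid, "model": "bleomycin", "day": 21,
                         "log2fc": lb, "p_value": 0.5, "adj_p": 0.5,
                         "mean_log_cpm": 1.0, "de_flag": False})
            rows.append({"feature_id": fid, "model": "aav_tgfb1", "day": 21,
                         "log2fc": la, "p_value": 0.5, "adj_p": 0.5,
                         "mean_log_cpm": 1.0, "de_flag": False})
        return pd.DataFrame(rows)

    def test_rule_assignment(self):
        part = pc.partition_model_specificity(
            self._contrasts({"b_only": (1.0, 0.1), "a_only": (0.2, -0.9),
                             "both": (0.7, -0.8), "neither": (0.1, 0.1)}), 21)
        assert part.exclusive_bleomycin == ["b_only"]
        assert part.exclusive_aav == ["a_only"]
        assert part.common == ["both"]       # magnitude criterion, signs free

    def test_sets_are_disjoint_and_cover(self):
        rng = np.random.default_rng(5)
        pairs = {f"g{i}": (rng.normal(scale=1), rng.normal(scale=1))
                 for i in range(100)}
        part = pc.partition_model_specificity(self._contrasts(pairs), 21)
        sets = [set(part.exclusive_bleomycin), set(part.exclusive_aav),
                set(part.common)]
        assert sum(len(s) for s in sets) == len(set().union(*sets))
        neither = set(pairs) - set().union(*sets)
        assert all(abs(pairs[f][0]) < 0.6 and abs(pairs[f][1]) < 0.6
                   for f in neither)

    def test_identical_lfc_vectors_give_r_squared_one(self):
        pairs = {f"g{i}": (v, v) for i, v in enumerate([1.0, 2.0, -1.5, 0.8])}
        part = pc.partition_model_specificity(self._contrasts(pairs), 21)
        assert part.r_squared["common"] == pytest.approx(1.0)

    def test_small_sets_have_nan_r_squared(self):
        part = pc.partition_model_specificity(
            self._contrasts({"only": (1.0, 0.0)}), 21)
        assert np.isnan(part.r_squared["exclusive_bleomycin"])
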