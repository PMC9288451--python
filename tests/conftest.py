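"""Shared fixtures: a scaled-down synthetic study, generated once per session.

The small study keeps the real design (5 days; treated n=5 AAV / n=8
Bleomycin; controls n=5 / n=6) but fewer features, so unit tests stay fast
while exercising the same code paths as a full-size run.
"""

import numpy as np
import pandas as pd
import pytest

from fibrocouple import diffexpr, pheno_coupling, synthstudy
from fibrocouple.formats_io import ExpressionMatrix, SampleDesign, SampleSheet

SMALL = dict(n_genes=300, n_mirnas=60)


@pytest.fixture(scope="session")
def small_config():
    return synthstudy.SimulationConfig(rng_seed=2024, **SMALL)


@pytest.fixture(scope="session")
def small_study(small_config):
    (mrna, mirna, design, trajectories, mouse, human,
     predictions, truth) = synthstudy.generate_study(small_config)
    return {
        "mrna": mrna, "mirna": mirna, "design": design,
        "trajectories": trajectories, "mouse": mouse, "human": human,
        "predictions": predictions, "truth": truth,
    }


@pytest.fixture(scope="session")
def small_contrasts(small_study):
    """Per-kind contrast tables and log-CPM matrices for the small study."""
    out = {}
    for label in ("mrna", "mirna"):
        kept = diffexpr.filter_low_expression(small_study[label],
                                              small_study["design"])
        log_cpm = diffexpr.normalize_log_cpm(kept)
        out[label] = {
            "log_cpm": log_cpm,
            "contrasts": diffexpr.run_all_contrasts(log_cpm, small_study["design"]),
        }
    return out


@pytest.fixture(scope="session")
def small_coupling(small_study, small_contrasts):
    return {
        label: pheno_coupling.correlate_with_lung_function(
            small_contrasts[label]["contrasts"], small_study["trajectories"])
        for label in ("mrna", "mirna")
    }


def minimal_design(n_per_group: int = 3, days=(3, 7, 14, 21, 28)) -> SampleSheet:
    """Tiny balanced design: n per (model, arm, day)."""
    designs = []
    for day in days:
        for model in ("bleomycin", "aav_tgfb1"):
            for arm in ("treated", "control"):
                for i in range(n_per_group):
                    sid = f"{model}_{arm}_d{day}_{i}"
                    designs.append(SampleDesign(sid, model, arm, day, sid))
    return SampleSheet(designs, days=days)


def matrix_from_array(arr, design: SampleSheet, kind="mrna",
                      scale="counts") -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    features = [f"f{i}" for i in range(arr.shape[0])]
    values = pd.DataFrame(arr, index=features, columns=design.sample_ids)
    return ExpressionMatrix(values=values, kind=kind, scale=scale)
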