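import numpy as np
import pandas as pd
import pytest

from panelforge.cohort import CohortConfig, MarkerSpec, generate_cohort


@pytest.fixture
def mu_markers():
    """Three M/U-ratio markers with case-control separation around 1."""
    def spec(name, medians, sd=0.6):
        return MarkerSpec(
            name=name,
            kind="mu_ratio",
            group_location=dict(zip(("control", "benign", "DCIS", "invasive"), medians)),
            group_scale=sd,
        )

    return [
        spec("geneA_meth", (0.30, 0.40, 2.2, 3.3)),
        spec("geneB_meth", (0.32, 0.42, 2.2, 3.2)),
        spec("geneC_meth", (0.28, 0.38, 2.6, 3.4)),
    ]


@pytest.fixture
def small_cohort(mu_markers):
    cfg = CohortConfig(
        group_sizes={"control": 60, "benign": 12, "DCIS": 6, "invasive": 60},
        markers=mu_markers,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def score_table_factory():
    """Random per-marker binary call tables for combination-rule checks."""

    def make(rng, n_cases=None, n_controls=None, n_markers=None):
        n_cases = n_cases or int(rng.integers(5, 40))
        n_controls = n_controls or int(rng.integers(5, 40))
        n_markers = n_markers or int(rng.integers(2, 6))
        groups = ["invasive"] * n_cases + ["control"] * n_controls
        table = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(groups))],
                "group": groups,
            }
        )
        markers = [f"m{j}" for j in range(n_markers)]
        for m in markers:
            p = rng.uniform(0.1, 0.9)
            table[f"call_{m}"] = (rng.random(len(groups)) < p).astype(int)
        return table, markers

    return make
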