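"""Shared fixtures: the planted-driver simulation study, computed once.

The driver-recovery fixtures are session-scoped because each seed runs
the full preprocess -> modules -> fusion -> permutation -> score -> GSEA
chain; several test modules score different aspects of the same runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from glycofuse import scenarios

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

N_DRIVER_SEEDS = 50


@pytest.fixture(scope="session")
def driver_runs():
    """One fitted pipeline per seed on the planted-driver design.

    99 consensus-OPLS permutations per seed; the enrichment stage uses
    a 999-draw gene-label null (the permutation floor of a 99-draw null
    cannot reach adj-p <= 0.05 after BH over ~14 terms).
    """
    runs = []
    for seed in range(N_DRIVER_SEEDS):
        data = scenarios.driver_dataset(seed)
        run = scenarios.run_driver_pipeline(
            data, seed=seed, n_perm=99, with_gsea=True, gsea_n_perm=999
        )
        runs.append((data, run))
    return runs


@pytest.fixture()
def small_design():
    """Tiny factorial design (2 x 1 x 2 groups, 3 mice each)."""
    from glycofuse import simulate

    spec = simulate.DesignSpec(
        strains=["A", "B"], diets=["RC"], timepoints=[1, 2], mice_per_group=(3, 3), seed=0
    )
    return simulate.generate_design(spec)


@pytest.fixture()
def random_blocks():
    """Two random group x module blocks plus a random outcome (18 groups)."""
    rng = np.random.default_rng(42)
    groups = [f"g{i:02d}" for i in range(18)]
    blocks = {
        "alpha": pd.DataFrame(
            rng.standard_normal((18, 4)), index=groups, columns=[f"M{j+1}" for j in range(4)]
        ),
        "beta": pd.DataFrame(
            rng.standard_normal((18, 7)), index=groups, columns=[f"M{j+1}" for j in range(7)]
        ),
    }
    y = pd.Series(rng.standard_normal(18), index=groups, name="glycemia")
    return blocks, y
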