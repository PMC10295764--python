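"""Shared fixtures: hand-written matrices and randomized summary factories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pooldeg import CountMatrix, GroupSummary


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 samples (2 wt + 2 mut), hand-written integers."""
    counts = pd.DataFrame(
        {
            "wt_1": [10, 30, 60],
            "wt_2": [20, 20, 60],
            "mut_1": [40, 10, 50],
            "mut_2": [50, 10, 40],
        },
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {"genotype": ["wt", "wt", "mut", "mut"],
         "pooled": [False, False, False, False]},
        index=list(counts.columns),
    )
    return CountMatrix(counts, meta)


def make_random_summary(rng: np.random.Generator,
                        n_genes: int = 60) -> GroupSummary:
    """Randomized GroupSummary exercising the zero-mean / zero-sd conventions."""
    mw = rng.lognormal(2.0, 1.0, n_genes)
    mm = rng.lognormal(2.0, 1.0, n_genes)
    sd = rng.gamma(2.0, 0.8, n_genes)
    mw[rng.random(n_genes) < 0.05] = 0.0
    mm[rng.random(n_genes) < 0.05] = 0.0
    sd[rng.random(n_genes) < 0.08] = 0.0
    table = pd.DataFrame(
        {"mean_wt": mw, "mean_mut": mm, "sd_wt": sd},
        index=[f"g{i:04d}" for i in range(n_genes)],
    )
    return GroupSummary(table, n_wt=6, n_mut=6)


@pytest.fixture
def summary_factory():
    return make_random_summary
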