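"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stratmeta as sm


@pytest.fixture(scope="session")
def small_sim():
    """Three planted control subgroups, 10 treated samples, 300 genes."""
    cfg = sm.SimConfig(
        n_genes=300, n_subgroups=3, controls_per_subgroup=[25, 25, 30],
        n_treated=10, frac_de=0.1, effect_mean_log2=2.0,
        effect_heterogeneity_tau=0.0, subgroup_shift_sd=0.5, seed=7)
    counts, samples, truth = sm.simulate(cfg)
    return cfg, counts, samples, truth


@pytest.fixture(scope="session")
def planted_scores():
    """Five well-separated Gaussian clusters in 6-D, sizes 30/30/30/36/54."""
    rng = np.random.default_rng(11)
    sizes = [30, 30, 30, 36, 54]
    centers = rng.normal(0.0, 6.0, size=(5, 6))
    rows, labels = [], []
    for c, n in enumerate(sizes):
        rows.append(centers[c] + rng.normal(0.0, 0.8, size=(n, 6)))
        labels.extend([c + 1] * n)
    X = np.vstack(rows)
    scores = pd.DataFrame(
        X, index=[f"s{i}" for i in range(len(X))],
        columns=[f"PC{i + 1}" for i in range(6)])
    return scores, np.array(labels)


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        [[10, 20, 30, 5], [0, 1, 2, 3], [100, 50, 80, 120]],
        index=["g1", "g2", "g3"], columns=["s1", "s2", "s3", "s4"])
    return sm.CountMatrix(df)
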