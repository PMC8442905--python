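import logging

import numpy as np
import pandas as pd
import pytest

import cfmodal as cf

logging.getLogger("cfmodal").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_atlas():
    return cf.make_atlas(n_tissues=3, n_regions=300, effect=0.4, seed=11)


@pytest.fixture(scope="session")
def atlas_replicates(small_atlas):
    return cf.make_atlas_replicates(small_atlas, n_replicates=3, seed=12)


@pytest.fixture(scope="session")
def signal_cohort():
    """20 vs 20 cohort with planted DMRs at effect 0.15, coverage 10."""
    atlas = cf.make_atlas(5, 600, 0.4, seed=21)
    calls, truth = cf.make_cohort(
        atlas, {"control": 20, "cancer": 20}, dmr_effect=0.15, coverage=10,
        seed=21, n_dmrs_per_group=50)
    matrix = cf.window_levels(calls, width=1000, min_mean_cov=2)
    return atlas, calls, truth, matrix


@pytest.fixture(scope="session")
def tiny_matrix():
    """Hand-sized window matrix: 8 samples x 6 windows, no missing values."""
    rng = np.random.default_rng(5)
    windows = [f"chr1:{i * 1000}-{(i + 1) * 1000}" for i in range(6)]
    levels = pd.DataFrame(rng.uniform(0.2, 0.9, size=(8, 6)),
                          index=[f"s{i}" for i in range(8)], columns=windows)
    cov = pd.DataFrame(5.0, index=levels.index, columns=levels.columns)
    return cf.WindowMethylationMatrix(levels=levels, coverage=cov, window_width=1000,
                                      n_positions=pd.Series(10, index=windows))


def brute_force_auc(scores, labels) -> float:
    """O(n^2) pairwise AUC oracle: mean over positive-negative pairs of
    1/0/0.5 for win/loss/tie."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
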