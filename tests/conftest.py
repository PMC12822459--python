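import numpy as np
import pandas as pd
import pytest

import neotls as nt


@pytest.fixture(scope="session")
def small_cohort():
    """An 800-cell cohort with default study-shaped structure."""
    cfg = nt.default_cohort_config(seed=11, n_cells=800, n_genes=600)
    matrix, cells, truth = nt.simulate_cohort(cfg)
    return cfg, matrix, cells, truth


@pytest.fixture(scope="session")
def lognorm_cohort(small_cohort):
    cfg, matrix, cells, truth = small_cohort
    return cfg, nt.lognormalize(matrix), cells, truth


@pytest.fixture(scope="session")
def spatial_grid():
    """A 60x60 spatial grid with three planted TLS discs."""
    cfg = nt.default_spatial_config(seed=7)
    gene_ids = cfg.gene_ids()
    t_sig = nt.GeneSignature("T-cell", tuple(gene_ids[500:520]))
    b_sig = nt.GeneSignature("B-cell", tuple(gene_ids[600:620]))
    sample, truth = nt.simulate_spatial(cfg, t_sig, b_sig)
    lognorm = nt.SpatialSample(nt.lognormalize(sample.matrix), sample.coords,
                               sample.sample_label)
    return cfg, lognorm, truth, t_sig, b_sig


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs AUC oracle: P(random positive outranks random negative)."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        total += (p > neg).sum() + 0.5 * (p == neg).sum()
    return total / (len(pos) * len(neg))


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Brute-force Benjamini-Hochberg step-up oracle."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
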