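"""Shared builders for the test suite: small experiments with known structure."""

from __future__ import annotations

import numpy as np
import pandas as pd

from oodyn import ExpressionExperiment


def two_group_experiment(
    mu_control: np.ndarray,
    mu_mutant: np.ndarray,
    dispersion: float,
    n_per_group: int = 3,
    stage: str = "MII",
    seed: int = 0,
) -> ExpressionExperiment:
    """NB counts for one stage, two genotypes, gene-wise means given directly."""
    rng = np.random.default_rng(seed)
    n_genes = len(mu_control)

    def draw(mu: np.ndarray) -> np.ndarray:
        shape = (n_genes, n_per_group)
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, dispersion * mu[:, None] * np.ones(shape))
        else:
            lam = mu[:, None] * np.ones(shape)
        return rng.poisson(lam)

    counts = np.hstack([draw(np.asarray(mu_control)), draw(np.asarray(mu_mutant))])
    gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"ctrl_{i}" for i in range(n_per_group)] + [
        f"mut_{i}" for i in range(n_per_group)
    ]
    return ExpressionExperiment(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_meta=pd.DataFrame(
            {"length": 1000.0, "is_spike_in": False}, index=gene_ids
        ),
        sample_meta=pd.DataFrame(
            {
                "stage": stage,
                "genotype": ["control"] * n_per_group + ["mutant"] * n_per_group,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )


def toy_experiment(
    counts: np.ndarray,
    stages: list[str],
    genotypes: list[str],
    lengths: np.ndarray | None = None,
    is_spike: np.ndarray | None = None,
) -> ExpressionExperiment:
    """Wrap a literal count matrix (genes x samples) in a validated experiment."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{i}" for i in range(n_samples)]
    return ExpressionExperiment(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        gene_meta=pd.DataFrame(
            {
                "length": lengths if lengths is not None else np.full(n_genes, 1000.0),
                "is_spike_in": is_spike if is_spike is not None else np.zeros(n_genes, bool),
            },
            index=gene_ids,
        ),
        sample_meta=pd.DataFrame(
            {"stage": stages, "genotype": genotypes},
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Naive O(m^2) Benjamini–Hochberg oracle: padj_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
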