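"""Small-n negative-binomial differential expression between genotypes.

Per-gene counts within one developmental stage are compared between mutant
and control with a documented NB/Wald procedure built from first
principles:

1.  size factors by the median-of-ratios rule over genes observed in every
    sample (library-size ratios as fallback);
2.  per-gene method-of-moments dispersion on size-factor-scaled counts,
    pooled across the two groups after centring group means, shrunk halfway
    toward a mean-dispersion trend;
3.  a Wald statistic on the log2 ratio of scaled group means, with NB
    variance mu + alpha * mu^2 propagated to the log-ratio by the delta
    method, two-sided normal p values;
4.  Benjamini–Hochberg adjustment and a fold-change + adjusted-p call rule
    (|log2 FC| > 1 and adjusted p < 0.05 by default, both strict).

A pseudocount of 0.5 inside the fold-change ratio stabilises zeros at
n <= 3; thresholds and the pseudocount are recorded with the results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionExperiment, ValidationError

FC_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8
TREND_SHRINKAGE_WEIGHT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; library-size ratios as fallback.

    Ratios are taken against the per-gene geometric mean over genes with
    all-nonzero counts.  If no gene is observed in every sample, falls back
    to library sizes normalised to geometric mean 1.
    """
    x = counts.to_numpy(dtype=float)
    all_nonzero = np.all(x > 0, axis=1)
    if all_nonzero.any():
        sub = x[all_nonzero]
        log_geo = np.mean(np.log(sub), axis=1)
        sf = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    else:
        lib = x.sum(axis=0)
        if np.any(lib == 0):
            raise ValidationError("cannot compute size factors: empty library")
        sf = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors_: pd.Series,
    groups: pd.Series | None = None,
) -> pd.Series:
    """Per-gene NB dispersion, moment-estimated then shrunk toward a trend.

    The raw estimate is alpha_hat = max(0, (s^2 - mu) / mu^2) on scaled
    counts, with the variance pooled within groups (group means centred
    out) when ``groups`` is given.  Raw estimates are shrunk toward a
    fitted mean-dispersion trend alpha(mu) = a0 + a1/mu with weight 0.5,
    then floored at 1e-8.  All-zero genes get dispersion 0 (flagged by the
    zero mean downstream).
    """
    if counts.shape[1] < 2:
        raise ValidationError("dispersion estimation needs >= 2 samples")
    scaled = counts.to_numpy(dtype=float) / size_factors_.to_numpy()
    mu = scaled.mean(axis=1)
    if groups is None:
        var = scaled.var(axis=1, ddof=1)
    else:
        g = np.asarray(groups)
        levels = np.unique(g)
        resid = scaled.copy()
        for lvl in levels:
            cols = g == lvl
            resid[:, cols] -= scaled[:, cols].mean(axis=1, keepdims=True)
        dof = scaled.shape[1] - len(levels)
        if dof < 1:
            raise ValidationError("not enough replication to pool variance across groups")
        var = (resid**2).sum(axis=1) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu**2), 0.0)

    expressed = mu > 0
    trend = _dispersion_trend(mu[expressed], raw[expressed])
    alpha = raw.copy()
    alpha[expressed] = (
        (1 - TREND_SHRINKAGE_WEIGHT) * raw[expressed]
        + TREND_SHRINKAGE_WEIGHT * trend
    )
    alpha[expressed] = np.maximum(alpha[expressed], DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _dispersion_trend(mu: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by least squares on positive raw estimates."""
    pos = raw > 0
    if pos.sum() < 10:
        return np.full_like(mu, float(np.median(raw[pos])) if pos.any() else 0.0)
    x = np.column_stack([np.ones(pos.sum()), 1.0 / mu[pos]])
    coef, *_ = np.linalg.lstsq(x, raw[pos], rcond=None)
    a0, a1 = coef
    fitted = a0 + a1 / mu
    return np.clip(fitted, 0.0, None)


def nb_wald_test(
    exp: ExpressionExperiment,
    stage: str,
    dispersion: pd.Series | None = None,
    endogenous_only: bool = True,
) -> pd.DataFrame:
    """Per-gene mutant-vs-control log2 fold change and Wald p at one stage.

    Returns a frame indexed by gene with columns ``mean_control``,
    ``mean_mutant`` (size-factor-scaled means), ``log2_fc`` and ``p``.
    """
    ctrl_ids = exp.samples_for(stage, "control")
    mut_ids = exp.samples_for(stage, "mutant")
    if len(ctrl_ids) == 0 or len(mut_ids) == 0:
        raise ValidationError(f"both genotypes must be present at stage {stage!r}")
    sample_ids = ctrl_ids.append(mut_ids)
    genes = exp.endogenous_ids if endogenous_only else exp.gene_ids
    counts = exp.counts.loc[genes, sample_ids]
    sf = size_factors(counts)
    if dispersion is None:
        groups = exp.sample_meta.loc[sample_ids, "genotype"]
        dispersion = estimate_dispersion(counts, sf, groups=groups)
    alpha = dispersion.reindex(genes).to_numpy()

    scaled = counts.to_numpy(dtype=float) / sf.to_numpy()
    is_ctrl = np.isin(sample_ids, ctrl_ids)
    xc, xm = scaled[:, is_ctrl], scaled[:, ~is_ctrl]
    nc, nm = xc.shape[1], xm.shape[1]
    qc, qm = xc.mean(axis=1), xm.mean(axis=1)

    log2_fc = np.log2((qm + FC_PSEUDOCOUNT) / (qc + FC_PSEUDOCOUNT))

    # Var of a scaled-count group mean under NB(mu = s_i q, var = mu + a mu^2):
    # Var(mean) = q * sum(1/s_i)/n^2 + a q^2 / n.
    inv_sc = float(np.sum(1.0 / sf.to_numpy()[is_ctrl]))
    inv_sm = float(np.sum(1.0 / sf.to_numpy()[~is_ctrl]))
    var_qc = qc * inv_sc / nc**2 + alpha * qc**2 / nc
    var_qm = qm * inv_sm / nm**2 + alpha * qm**2 / nm
    ln2sq = np.log(2.0) ** 2
    se2 = var_qc / ((qc + FC_PSEUDOCOUNT) ** 2 * ln2sq) + var_qm / (
        (qm + FC_PSEUDOCOUNT) ** 2 * ln2sq
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, log2_fc / np.sqrt(se2), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where((qc == 0) & (qm == 0), 1.0, p)

    return pd.DataFrame(
        {
            "mean_control": qc,
            "mean_mutant": qm,
            "log2_fc": log2_fc,
            "p": np.clip(p, 0.0, 1.0),
        },
        index=genes,
    )


def bh_adjust(p: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values.

    Sorted ascending, padj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1,
    mapped back to input order.  NaN inputs propagate NaN and are excluded
    from m.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-d vector")
    finite = ~np.isnan(arr)
    vals = arr[finite]
    if np.any((vals < 0) | (vals > 1)):
        raise ValidationError("p values must lie in [0, 1]")
    m = vals.size
    out = np.full_like(arr, np.nan)
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        restored = np.empty(m)
        restored[order] = adj
        out[finite] = restored
    return out


def call_degs(
    table: pd.DataFrame,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Add BH-adjusted p values and an up/down/ns call to a test table.

    ``up`` iff log2_fc > fc_threshold and padj < alpha; ``down``
    symmetrically; both inequalities strict.  Thresholds are attached to
    the frame via ``attrs`` for provenance.
    """
    if not (np.isfinite(fc_threshold) and np.isfinite(alpha)):
        raise ValidationError("thresholds must be finite")
    out = table.copy()
    out["padj"] = bh_adjust(out["p"].to_numpy())
    sig = out["padj"] < alpha
    call = np.where(
        sig & (out["log2_fc"] > fc_threshold), "up",
        np.where(sig & (out["log2_fc"] < -fc_threshold), "down", "ns"),
    )
    out["call"] = call
    out.attrs["fc_threshold"] = fc_threshold
    out.attrs["alpha"] = alpha
    out.attrs["fc_pseudocount"] = FC_PSEUDOCOUNT
    return out


def deg_per_stage(
    exp: ExpressionExperiment,
    stages: tuple[str, ...] = ("GV", "MII", "D3"),
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Run the full test + call pipeline for each stage; returns stage -> DegTable."""
    return {
        stage: call_degs(nb_wald_test(exp, stage), fc_threshold=fc_threshold, alpha=alpha)
        for stage in stages
    }
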