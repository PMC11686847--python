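"""TPM quantification, spike-in calibration, dosage and distribution summaries.

TPM is computed over *all* rows — endogenous genes and spike-ins share the
per-million denominator — because only then can the constant absolute
spike-in amount carry information about a sample's total endogenous mRNA
content.  Calibration rescales every sample so its spike-in TPM mass
matches the cohort median; after that, endogenous totals are comparable
across samples as absolute per-cell dosage.  Dosage summaries are reported
over endogenous rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    ExpressionExperiment,
    SpikeInReference,
    ValidationError,
    GENOTYPES,
    STAGES,
)


@dataclass
class CalibratedMatrix:
    """TPM matrix plus per-sample scale factors mapping it to absolute dosage.

    ``calibrated`` is ``tpm * scale_factor`` column-wise; ``scale_factor``
    is 1 for an uncalibrated matrix.  ``pseudocount`` is the offset used by
    downstream log transforms (log2(x + 1)).
    """

    tpm: pd.DataFrame
    scale_factor: pd.Series
    pseudocount: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.scale_factor <= 0).any():
            raise ValidationError("scale factors must be positive")
        if not np.isfinite(self.tpm.to_numpy()).all():
            raise ValidationError("TPM values must be finite")

    @property
    def calibrated(self) -> pd.DataFrame:
        return self.tpm * self.scale_factor

    @property
    def sample_ids(self) -> pd.Index:
        return self.tpm.columns


def compute_tpm(exp: ExpressionExperiment) -> CalibratedMatrix:
    """Transcripts-per-million from counts and effective lengths (k_s = 1).

    tpm[g, s] = 1e6 * (count[g, s] / length[g]) / sum_g'(count[g', s] / length[g']).
    A sample with zero total signal yields an all-zero column, flagged in
    provenance rather than silently normalised.
    """
    lengths = exp.gene_length.to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValidationError("gene lengths must be positive")
    rate = exp.counts.to_numpy(dtype=float) / lengths[:, None]
    totals = rate.sum(axis=0)
    all_zero = totals == 0
    safe = np.where(all_zero, 1.0, totals)
    tpm = pd.DataFrame(1e6 * rate / safe, index=exp.gene_ids, columns=exp.sample_ids)
    tpm.loc[:, all_zero] = 0.0
    return CalibratedMatrix(
        tpm=tpm,
        scale_factor=pd.Series(1.0, index=exp.sample_ids, name="scale_factor"),
        provenance={
            "normalisation": "TPM",
            "all_zero_samples": list(exp.sample_ids[all_zero]),
        },
    )


def spike_in_calibrate(
    mat: CalibratedMatrix, exp: ExpressionExperiment, ref: SpikeInReference
) -> CalibratedMatrix:
    """Rescale each sample by its spike-in TPM mass relative to the cohort median.

    k_s = median_over_samples(spike TPM sum) / (spike TPM sum of sample s);
    the median sample anchors the scale, which is robust to a single
    degenerate oocyte.  Requires nonzero spike signal in every sample.
    Spike sums are taken on the current calibrated values, which makes the
    operation idempotent in effect: recalibrating a calibrated matrix
    yields a unit correction.
    """
    ref.check_against(exp)
    spike_ids = exp.spike_ids.intersection(ref.spike_ids)
    if len(spike_ids) == 0:
        raise ValidationError("no spike-in genes shared between experiment and reference")
    spike_sums = mat.calibrated.loc[spike_ids].sum(axis=0)
    zero = spike_sums[spike_sums <= 0]
    if len(zero):
        raise ValidationError(f"zero spike-in signal in sample(s): {list(zero.index)}")
    k = float(spike_sums.median()) / spike_sums
    return CalibratedMatrix(
        tpm=mat.tpm,
        scale_factor=(mat.scale_factor * k).rename("scale_factor"),
        pseudocount=mat.pseudocount,
        provenance={
            **mat.provenance,
            "calibration": "spike-in, median-sample anchor",
            "n_spike_ins_used": int(len(spike_ids)),
        },
    )


@dataclass
class DosageResult:
    per_sample: pd.Series  # calibrated endogenous total per sample
    group_summary: pd.DataFrame  # stage x genotype: n, mean, sd
    stage_tests: pd.DataFrame  # per stage: Welch t and two-sided p, mutant vs control


def total_dosage(mat: CalibratedMatrix, exp: ExpressionExperiment) -> DosageResult:
    """Per-sample calibrated endogenous totals plus per-stage group comparison.

    Spike-in rows are excluded from the totals.  Each stage with both
    genotypes present gets a two-sided Welch two-sample test on the
    per-sample totals (unequal-variance form, chosen for tiny n).
    """
    totals = mat.calibrated.loc[exp.endogenous_ids].sum(axis=0).rename("endogenous_total")
    meta = exp.sample_meta
    rows = []
    for stage in STAGES:
        for geno in GENOTYPES:
            sids = exp.samples_for(stage, geno)
            if len(sids) == 0:
                raise ValidationError(f"no samples for stage={stage}, genotype={geno}")
            vals = totals[sids]
            rows.append({
                "stage": stage, "genotype": geno, "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            })
    summary = pd.DataFrame(rows).set_index(["stage", "genotype"])

    test_rows = []
    for stage in STAGES:
        ctrl = totals[exp.samples_for(stage, "control")]
        mut = totals[exp.samples_for(stage, "mutant")]
        if ctrl.std(ddof=1) == 0 and mut.std(ddof=1) == 0 and ctrl.mean() == mut.mean():
            t, p = 0.0, 1.0  # identical degenerate groups
        else:
            t, p = stats.ttest_ind(mut, ctrl, equal_var=False)
        test_rows.append({"stage": stage, "t": float(t), "p": float(p),
                          "mean_ratio_mut_ctrl": float(mut.mean() / ctrl.mean())})
    tests = pd.DataFrame(test_rows).set_index("stage")
    return DosageResult(per_sample=totals, group_summary=summary, stage_tests=tests)


DEFAULT_BIN_EDGES = (0.0, 2.0, 10.0, np.inf)


def expression_bins(
    mat: CalibratedMatrix,
    exp: ExpressionExperiment,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Mean number of endogenous genes per expression bin, per (stage, genotype).

    Per sample, endogenous genes are counted into half-open bins
    [edge_i, edge_{i+1}) of calibrated TPM; group means are returned.  The
    default edges (0, 2, 10, inf) bracket the analysis floor (TPM > 2) and
    the high-expression remark (TPM > 10).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValidationError("bin edges must be strictly increasing with >=2 entries")
    cal = mat.calibrated.loc[exp.endogenous_ids]
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    per_sample = pd.DataFrame(
        {s: np.histogram(cal[s].to_numpy(), bins=edges)[0] for s in cal.columns},
        index=labels,
    ).T
    grouped = per_sample.groupby(
        [exp.sample_meta["stage"], exp.sample_meta["genotype"]], observed=True
    ).mean()
    grouped.index.names = ["stage", "genotype"]
    return grouped


@dataclass
class PcaResult:
    coordinates: pd.DataFrame  # samples x (PC1, PC2)
    explained_variance_ratio: np.ndarray
    n_genes_used: int


def pca_qc(
    mat: CalibratedMatrix, exp: ExpressionExperiment, n_top_variable: int = 500
) -> PcaResult:
    """Sample coordinates on the first two principal axes of log expression.

    Computed on log2(calibrated + 1) of the ``n_top_variable`` most variable
    endogenous genes, centred per gene; coordinates are deterministic up to
    a sign flip per axis.  If fewer genes are available than requested, all
    are used.
    """
    if mat.tpm.shape[1] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    logx = np.log2(mat.calibrated.loc[exp.endogenous_ids] + mat.pseudocount)
    variances = logx.var(axis=1)
    n_use = min(n_top_variable, logx.shape[0])
    top = variances.nlargest(n_use).index
    x = logx.loc[top].to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    # samples are observations: SVD of the genes x samples centred matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = pd.DataFrame(
        (vt[:2].T * s[:2]), index=mat.sample_ids, columns=["PC1", "PC2"]
    )
    total_var = float(np.sum(s**2))
    ratio = s[:2] ** 2 / total_var if total_var > 0 else np.zeros(2)
    return PcaResult(coordinates=coords, explained_variance_ratio=ratio, n_genes_used=n_use)
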