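"""Maternal transcript decay taxonomy, transitions and quadrant analysis.

The per-gene trajectory summary is the median over replicate samples of
log2(calibrated TPM + 1), per stage and genotype.  Genes passing the
expression floor (calibrated TPM above 2 in the control stage summaries at
at least one stage) are classified by the signs of their two control stage
transitions — GV→MII (delta1) and MII→D3 (delta2) — into the nine clusters
of :mod:`oodyn.clusters`.  A transition of at least ``fc_log2`` (default 1,
i.e. 2-fold) in magnitude counts as degraded/elevated; the boundary is
inclusive, so "2-fold" means at-least-2-fold.  Clusters are defined on
control trajectories only; mutant genes inherit the control-defined
cluster, which is how mutant trajectories are overlaid on the control
taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import CLUSTERS, CLUSTER_STEPS, STATUS_TO_CLUSTER
from .io_formats import (
    ExpressionExperiment,
    ValidationError,
    GENOTYPES,
    STAGES,
)
from .quantify import CalibratedMatrix


@dataclass
class StageProfile:
    """Per-gene stage summaries (median log2(calibrated TPM + 1)) per genotype.

    ``log_summary`` has a (genotype, stage) column MultiIndex;
    ``tpm_summary`` holds the matching medians on the calibrated TPM scale
    (used by the expression filter).
    """

    log_summary: pd.DataFrame
    tpm_summary: pd.DataFrame
    pseudocount: float = 1.0

    def value(self, genotype: str, stage: str) -> pd.Series:
        return self.log_summary[(genotype, stage)]

    def deltas(self, genotype: str) -> pd.DataFrame:
        """delta1 = MII - GV, delta2 = D3 - MII on the log2 scale."""
        return pd.DataFrame(
            {
                "delta1": self.value(genotype, "MII") - self.value(genotype, "GV"),
                "delta2": self.value(genotype, "D3") - self.value(genotype, "MII"),
            }
        )


def stage_profiles(mat: CalibratedMatrix, exp: ExpressionExperiment) -> StageProfile:
    """Median over samples of log2(calibrated TPM + 1), per (genotype, stage)."""
    missing = [
        (stage, geno)
        for geno in GENOTYPES
        for stage in STAGES
        if len(exp.samples_for(stage, geno)) == 0
    ]
    if missing:
        raise ValidationError(f"no samples for (stage, genotype) cell(s): {missing}")
    cal = mat.calibrated
    log_cols, tpm_cols = {}, {}
    for geno in GENOTYPES:
        for stage in STAGES:
            sids = exp.samples_for(stage, geno)
            tpm_cols[(geno, stage)] = cal[sids].median(axis=1)
            log_cols[(geno, stage)] = np.log2(cal[sids] + mat.pseudocount).median(axis=1)
    log_summary = pd.DataFrame(log_cols)
    log_summary.columns = pd.MultiIndex.from_tuples(log_summary.columns,
                                                    names=["genotype", "stage"])
    tpm_summary = pd.DataFrame(tpm_cols)
    tpm_summary.columns = log_summary.columns
    return StageProfile(log_summary=log_summary, tpm_summary=tpm_summary,
                        pseudocount=mat.pseudocount)


@dataclass
class DecayClusterMap:
    """Per-gene cluster assignment (I–IX or ``filtered``) with the rule record."""

    assignment: pd.Series  # gene -> cluster label or "filtered"
    fc_log2: float
    expr_floor: float

    def cluster_counts(self) -> pd.Series:
        counts = self.assignment[self.assignment != "filtered"].value_counts()
        return counts.reindex(CLUSTERS, fill_value=0).rename("n_genes")

    def members(self, cluster: str) -> pd.Index:
        return self.assignment.index[self.assignment == cluster]


def transition_status(delta: np.ndarray | pd.Series, fc_log2: float = 1.0) -> np.ndarray:
    """Status per transition: degraded (<= -fc), elevated (>= +fc), else stable."""
    d = np.asarray(delta, dtype=float)
    return np.where(d <= -fc_log2, "degraded", np.where(d >= fc_log2, "elevated", "stable"))


def classify_decay_clusters(
    profile: StageProfile,
    fc_log2: float = 1.0,
    expr_floor: float = 2.0,
) -> DecayClusterMap:
    """Assign every gene to a trajectory cluster from its control profile.

    Genes whose control stage-summary calibrated TPM never exceeds
    ``expr_floor`` (strict >) at any stage are labelled ``filtered``.  The
    remainder are mapped through the 3 × 3 status truth table of their
    control delta1/delta2.
    """
    ctrl_tpm = profile.tpm_summary["control"]
    keep = (ctrl_tpm > expr_floor).any(axis=1)
    deltas = profile.deltas("control")
    s1 = transition_status(deltas["delta1"], fc_log2)
    s2 = transition_status(deltas["delta2"], fc_log2)
    labels = np.array([STATUS_TO_CLUSTER[(a, b)] for a, b in zip(s1, s2)], dtype=object)
    labels[~keep.to_numpy()] = "filtered"
    return DecayClusterMap(
        assignment=pd.Series(labels, index=profile.log_summary.index, name="cluster"),
        fc_log2=fc_log2,
        expr_floor=expr_floor,
    )


@dataclass
class ClusterTrajectories:
    """Per-cluster median stage trajectories per genotype, plus impairment stats.

    ``impairment`` holds, per cluster with a degrading defining transition,
    the median over member genes of (mutant delta − control delta) summed
    over the cluster's degrading transition(s) — positive when mutant decay
    is impaired — with a one-sided Wilcoxon signed-rank p.  ``elevation_deficit``
    is the symmetric statistic (control − mutant) over elevating
    transitions, positive when mutant elevation (e.g. ZGA) is impaired.
    """

    trajectories: pd.DataFrame  # (cluster, genotype) x stage medians
    impairment: pd.DataFrame
    elevation_deficit: pd.DataFrame


def cluster_trajectories(
    cmap: DecayClusterMap, profile: StageProfile
) -> ClusterTrajectories:
    traj_rows = {}
    imp_rows, elev_rows = [], []
    d_ctrl = profile.deltas("control")
    d_mut = profile.deltas("mutant")
    for cluster in CLUSTERS:
        members = cmap.members(cluster)
        if len(members) == 0:
            continue
        for geno in GENOTYPES:
            traj_rows[(cluster, geno)] = {
                stage: float(profile.value(geno, stage)[members].median())
                for stage in STAGES
            }
        s1, s2 = CLUSTER_STEPS[cluster]
        deg_cols = [c for sign, c in ((s1, "delta1"), (s2, "delta2")) if sign < 0]
        elev_cols = [c for sign, c in ((s1, "delta1"), (s2, "delta2")) if sign > 0]
        if deg_cols:
            diff = (d_mut[deg_cols].sum(axis=1) - d_ctrl[deg_cols].sum(axis=1))[members]
            imp_rows.append({
                "cluster": cluster,
                "transitions": "+".join(deg_cols),
                "statistic": float(diff.median()),
                "p": _wilcoxon_greater(diff),
                "n_genes": len(members),
            })
        if elev_cols:
            diff = (d_ctrl[elev_cols].sum(axis=1) - d_mut[elev_cols].sum(axis=1))[members]
            elev_rows.append({
                "cluster": cluster,
                "transitions": "+".join(elev_cols),
                "statistic": float(diff.median()),
                "p": _wilcoxon_greater(diff),
                "n_genes": len(members),
            })
    traj = pd.DataFrame(traj_rows).T
    traj.index.names = ["cluster", "genotype"]
    return ClusterTrajectories(
        trajectories=traj[list(STAGES)],
        impairment=pd.DataFrame(imp_rows).set_index("cluster") if imp_rows else pd.DataFrame(),
        elevation_deficit=pd.DataFrame(elev_rows).set_index("cluster") if elev_rows else pd.DataFrame(),
    )


def _wilcoxon_greater(diff: pd.Series) -> float:
    """One-sided signed-rank p for median(diff) > 0; 1.0 on degenerate input."""
    d = diff.to_numpy(dtype=float)
    d = d[np.isfinite(d)]
    if len(d) == 0 or np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(d, alternative="greater").pvalue)


STATUS_LEVELS = ("up", "down", "ns")


def transition_sankey(deg_by_stage: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """3 × 3 flow counts of DEG status between consecutive stages.

    Works on the intersection of the gene universes of the per-stage call
    tables; row sums of a flow equal the earlier stage's status counts on
    the common universe (and column sums the later stage's).
    """
    stages = [s for s in STAGES if s in deg_by_stage]
    if len(stages) < 2:
        raise ValidationError("need call tables for >= 2 consecutive stages")
    universe = deg_by_stage[stages[0]].index
    for s in stages[1:]:
        universe = universe.intersection(deg_by_stage[s].index)
    if len(universe) == 0:
        raise ValidationError("empty common gene universe across stages")
    flows = {}
    for a, b in zip(stages[:-1], stages[1:]):
        ct = pd.crosstab(
            deg_by_stage[a].loc[universe, "call"],
            deg_by_stage[b].loc[universe, "call"],
        ).reindex(index=STATUS_LEVELS, columns=STATUS_LEVELS, fill_value=0)
        ct.index.name, ct.columns.name = a, b
        flows[f"{a}->{b}"] = ct
    return flows


QUADRANTS = {
    ("up", "degraded"): "up_in_mutant__degraded_in_control",   # decay escape
    ("up", "elevated"): "up_in_mutant__elevated_in_control",
    ("down", "degraded"): "down_in_mutant__degraded_in_control",
    ("down", "elevated"): "down_in_mutant__elevated_in_control",
}


@dataclass
class QuadrantResult:
    labels: pd.Series  # gene -> quadrant name or "unassigned"
    counts: pd.Series  # per-quadrant gene counts
    headline: pd.Index  # up in mutant MII & degraded across control maturation


def quadrant_analysis(
    deg_mii: pd.DataFrame,
    profile: StageProfile,
    fc_log2: float = 1.0,
) -> QuadrantResult:
    """Cross the MII mutant-vs-control calls with the control GV→MII change.

    x-axis: control delta1 (developmental change across maturation);
    y-axis: the MII DEG call.  Genes with an up/down call and |delta1| at
    least ``fc_log2`` land in one of four quadrants.  The headline subset
    is up-in-mutant genes whose control trajectory says they should have
    been degraded (delta1 <= -fc_log2): transcripts that escape clearance.
    """
    shared = deg_mii.index.intersection(profile.log_summary.index)
    call = deg_mii.loc[shared, "call"]
    d1 = profile.deltas("control").loc[shared, "delta1"]
    status = transition_status(d1, fc_log2)
    labels = pd.Series("unassigned", index=shared, name="quadrant")
    for (c, s), name in QUADRANTS.items():
        labels[(call == c) & (status == s)] = name
    counts = labels[labels != "unassigned"].value_counts().reindex(
        list(QUADRANTS.values()), fill_value=0
    )
    headline = shared[(call == "up") & (d1 <= -fc_log2)]
    return QuadrantResult(labels=labels, counts=counts, headline=headline)
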