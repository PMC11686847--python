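"""Differential co-IP interactome calling from bait-pulldown intensities.

A protein counts as a bait interactor when its pulldown intensity exceeds
the empty-vector background more than 10-fold (strict, positive direction
only — bait enrichment is one-sided despite the absolute-value phrasing
such thresholds are often quoted with).  Among wild-type interactors, a
protein shows *reduced binding* to the mutant bait when the mutant/WT
intensity ratio drops to 2/3 or below, i.e. at least a 30% reduction
(inclusive).  Zero and missing intensities are guarded by a small
pseudo-intensity rather than imputed; the rule stays monotone in the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ProteinIntensityTable, ValidationError

ENRICH_LOG2_DEFAULT = math.log2(10.0)
REDUCE_LOG2_DEFAULT = math.log2(2.0 / 3.0)
PSEUDO_DEFAULT = 0.01


@dataclass
class InteractomeCalls:
    """Per-protein log ratios and boolean classifications plus thresholds used."""

    table: pd.DataFrame
    enrich_log2: float = ENRICH_LOG2_DEFAULT
    reduce_log2: float = REDUCE_LOG2_DEFAULT
    pseudo: float = PSEUDO_DEFAULT

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def geometric_mean_replicates(
    intensity: pd.DataFrame, condition_of: dict[str, str]
) -> pd.DataFrame:
    """Collapse replicate columns per condition by geometric mean of positives.

    ``condition_of`` maps each column to its condition label.  Columns with
    no positive observation for a protein collapse to 0.
    """
    out = {}
    for cond in sorted(set(condition_of.values())):
        cols = [c for c, k in condition_of.items() if k == cond]
        block = intensity[cols].to_numpy(dtype=float)
        pos = block > 0
        with np.errstate(divide="ignore"):
            logs = np.where(pos, np.log(np.where(pos, block, 1.0)), 0.0)
        npos = pos.sum(axis=1)
        gm = np.where(npos > 0, np.exp(logs.sum(axis=1) / np.maximum(npos, 1)), 0.0)
        out[cond] = gm
    return pd.DataFrame(out, index=intensity.index)


def call_interactors(
    table: ProteinIntensityTable,
    enrich_log2: float = ENRICH_LOG2_DEFAULT,
    pseudo: float = PSEUDO_DEFAULT,
) -> InteractomeCalls:
    """Classify WT and mutant bait interactors by enrichment over vector.

    log2fc_x_vec = log2((I_x + pseudo) / (I_vector + pseudo)); interactor
    iff log2fc > enrich_log2 (strict).
    """
    if pseudo < 0:
        raise ValidationError("pseudo-intensity must be non-negative")
    i = table.intensity
    vec = i["Vector"].to_numpy() + pseudo
    wt = i["WT"].to_numpy() + pseudo
    mut = i["Mut"].to_numpy() + pseudo
    if np.any(vec <= 0) or np.any(wt <= 0) or np.any(mut <= 0):
        raise ValidationError("zero intensity with zero pseudo-intensity is undefined")
    out = pd.DataFrame(
        {
            "log2fc_wt_vec": np.log2(wt / vec),
            "log2fc_mut_vec": np.log2(mut / vec),
            "log2fc_mut_wt": np.log2(mut / wt),
        },
        index=i.index,
    )
    out["is_wt_interactor"] = out["log2fc_wt_vec"] > enrich_log2
    out["is_mut_interactor"] = out["log2fc_mut_vec"] > enrich_log2
    out["is_shared"] = out["is_wt_interactor"] & out["is_mut_interactor"]
    return InteractomeCalls(table=out, enrich_log2=enrich_log2, pseudo=pseudo)


def differential_binding(
    calls: InteractomeCalls, reduce_log2: float = REDUCE_LOG2_DEFAULT
) -> InteractomeCalls:
    """Flag WT interactors whose mutant/WT binding drops to 2^reduce_log2 or below.

    With the default threshold log2(2/3), reduced means Mut/WT <= 2/3 —
    a binding reduction of at least 30% (inclusive boundary).  Gated on WT
    interactor status: background proteins cannot be "reduced".
    """
    t = calls.table.copy()
    t["is_reduced_binding"] = t["is_wt_interactor"] & (t["log2fc_mut_wt"] <= reduce_log2)
    return InteractomeCalls(
        table=t, enrich_log2=calls.enrich_log2, reduce_log2=reduce_log2, pseudo=calls.pseudo
    )


def venn_sets(calls: InteractomeCalls) -> dict[str, int]:
    """Disjoint partition of interactors: WT-only, Mut-only, shared (+ shared∩reduced)."""
    t = calls.table
    wt_only = int((t["is_wt_interactor"] & ~t["is_mut_interactor"]).sum())
    mut_only = int((t["is_mut_interactor"] & ~t["is_wt_interactor"]).sum())
    shared = int(t["is_shared"].sum())
    out = {"wt_only": wt_only, "mut_only": mut_only, "shared": shared}
    if "is_reduced_binding" in t:
        out["shared_reduced"] = int((t["is_shared"] & t["is_reduced_binding"]).sum())
        out["reduced"] = int(t["is_reduced_binding"].sum())
    return out
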