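"""End-to-end wiring: quantify → differential → decay taxonomy → overlaps.

The pipeline is a pure function of (inputs, config, seed): no stage mutates
another stage's outputs, and a rerun with the same inputs produces
identical tables and manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decay, differential, genesets, interactome, quantify
from .io_formats import (
    ExpressionExperiment,
    GeneSet,
    SpikeInReference,
    ValidationError,
    read_expression_experiment,
    read_gene_sets,
    read_protein_intensities,
    read_spike_in_reference,
    write_results,
    STAGES,
)


@dataclass
class PipelineConfig:
    """Input paths and every analysis threshold, with their defaults.

    Thresholds: ``fc_log2`` (2-fold on the log2 scale) drives both DEG
    calling and the decay taxonomy; ``alpha`` is the BH-adjusted
    significance level; ``expr_floor`` the control TPM analysis floor;
    ``enrich_log2``/``reduce_log2`` the interactome thresholds (10-fold
    enrichment over vector; Mut/WT at or below 2/3).
    """

    counts: str | None = None
    gene_meta: str | None = None
    sample_meta: str | None = None
    spike_reference: str | None = None
    gene_sets: str | None = None
    intensities: str | None = None
    out_dir: str = "results"
    fc_log2: float = 1.0
    alpha: float = 0.05
    expr_floor: float = 2.0
    high_expr: float = 10.0
    enrich_log2: float = float(np.log2(10.0))
    reduce_log2: float = float(np.log2(2.0 / 3.0))
    n_top_variable: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        for name in ("fc_log2", "expr_floor", "high_expr", "enrich_log2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _checksum(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(df.to_csv(sep="\t").encode())
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    exp: ExpressionExperiment | None = None,
    spike_ref: SpikeInReference | None = None,
    gene_sets: list[GeneSet] | None = None,
) -> dict:
    """Run the full analysis; write result tables + manifest; return the manifest.

    In-memory objects may be passed directly (as the simulator does);
    otherwise they are read from the configured paths.  Any stage failure
    propagates with the stage name prefixed.
    """
    config.validate()
    inputs: dict[str, str] = {}
    if exp is None:
        for name in ("counts", "gene_meta", "sample_meta"):
            if getattr(config, name) is None:
                raise ValidationError(f"missing required input: {name}")
        exp = read_expression_experiment(config.counts, config.gene_meta, config.sample_meta)
        inputs.update(counts=config.counts, gene_meta=config.gene_meta,
                      sample_meta=config.sample_meta)
    if spike_ref is None:
        if config.spike_reference is None:
            raise ValidationError(
                "missing required input: spike_reference (needed for dosage calibration)"
            )
        spike_ref = read_spike_in_reference(config.spike_reference)
        inputs["spike_reference"] = config.spike_reference
    if gene_sets is None and config.gene_sets is not None:
        gene_sets = read_gene_sets(config.gene_sets)
        inputs["gene_sets"] = config.gene_sets

    tables: dict[str, pd.DataFrame] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return wrap

    # quantify
    mat = stage("quantify")(quantify.compute_tpm, exp)
    mat = stage("quantify")(quantify.spike_in_calibrate, mat, exp, spike_ref)
    dosage = stage("quantify")(quantify.total_dosage, mat, exp)
    bins = stage("quantify")(
        quantify.expression_bins, mat, exp,
        (0.0, config.expr_floor, config.high_expr, np.inf),
    )
    pca = stage("quantify")(quantify.pca_qc, mat, exp, config.n_top_variable)
    tables["dosage_per_sample"] = dosage.per_sample.to_frame()
    tables["dosage_groups"] = dosage.group_summary.reset_index().set_index("stage")
    tables["dosage_tests"] = dosage.stage_tests
    tables["expression_bins"] = bins.reset_index().set_index("stage")
    tables["pca_coordinates"] = pca.coordinates

    # differential expression per stage
    degs = stage("differential")(
        differential.deg_per_stage, exp,
        STAGES, config.fc_log2, config.alpha,
    )
    for s, table in degs.items():
        tables[f"deg_{s}"] = table

    # decay taxonomy
    profile = stage("decay")(decay.stage_profiles, mat, exp)
    cmap = stage("decay")(
        decay.classify_decay_clusters, profile, config.fc_log2, config.expr_floor
    )
    traj = stage("decay")(decay.cluster_trajectories, cmap, profile)
    flows = stage("decay")(decay.transition_sankey, degs)
    quad = stage("decay")(decay.quadrant_analysis, degs["MII"], profile, config.fc_log2)
    tables["decay_clusters"] = cmap.assignment.to_frame()
    tables["decay_cluster_counts"] = cmap.cluster_counts().to_frame()
    tables["cluster_trajectories"] = traj.trajectories.reset_index().set_index("cluster")
    if len(traj.impairment):
        tables["decay_impairment"] = traj.impairment
    if len(traj.elevation_deficit):
        tables["elevation_deficit"] = traj.elevation_deficit
    for name, flow in flows.items():
        tables[f"sankey_{name.replace('->', '_to_')}"] = flow
    tables["quadrant_labels"] = quad.labels.to_frame()
    tables["quadrant_counts"] = quad.counts.to_frame("n_genes")

    # gene-set overlaps on the D3 DEG lists
    if gene_sets:
        by_name = {gs.name: gs for gs in gene_sets}
        rows = []
        universe = len(degs["D3"])
        for set_name, direction in (("ZGA", "down"), ("M-decay", "up")):
            if set_name not in by_name:
                continue
            ids = degs["D3"].index[degs["D3"]["call"] == direction]
            if len(ids) == 0:
                continue
            stat = genesets.overlap_percentage(ids, by_name[set_name],
                                               list_name=f"D3_{direction}")
            genesets.annotate_enrichment(stat, universe)
            rows.append({
                "set_name": stat.set_name, "list_name": stat.list_name,
                "overlap": stat.overlap, "list_size": stat.list_size,
                "set_size": stat.set_size, "universe": stat.universe,
                "percent": stat.percent, "display_percent": stat.display_percent,
                "p_hyper": stat.p_hyper,
            })
        if rows:
            tables["geneset_overlaps"] = pd.DataFrame(rows).set_index("set_name")

    # interactome (optional)
    if config.intensities is not None:
        itab = read_protein_intensities(config.intensities)
        inputs["intensities"] = config.intensities
        calls = stage("interactome")(
            interactome.call_interactors, itab, config.enrich_log2
        )
        calls = stage("interactome")(
            interactome.differential_binding, calls, config.reduce_log2
        )
        tables["interactome_calls"] = calls.table
        tables["interactome_venn"] = pd.Series(
            interactome.venn_sets(calls), name="n_proteins"
        ).to_frame()

    parameters = {k: v for k, v in asdict(config).items()
                  if k not in ("counts", "gene_meta", "sample_meta", "spike_reference",
                               "gene_sets", "intensities", "out_dir")}
    manifest = write_results(tables, config.out_dir, parameters=parameters,
                             inputs=inputs, seed=config.seed)
    manifest["checksums"] = {name: _checksum(df) for name, df in tables.items()}
    with open(Path(config.out_dir) / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
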