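"""Synthetic single-oocyte/embryo experiments with known ground truth.

The generator emulates the statistical structure the analysis assumes for a
control/mutant GV–MII–day-3 design: per-transcript expression rates laid
out on the nine trajectory clusters, external spike-ins added in the same
absolute amount to every sample, a global mRNA-dosage reduction in mutant
GV oocytes, attenuated degradation steps in mutants (impaired maternal
decay), and attenuated day-3 elevation steps in mutants (impaired zygotic
genome activation).

Counts are produced by sampling a per-library sequencing depth
(log-normal), allocating it across transcripts in proportion to
rate × effective length (longer transcripts yield more reads at the same
molar rate), and drawing gene-wise negative-binomial counts around the
expected values.  A single seeded generator drives all randomness, so a
given seed reproduces the experiment byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import CLUSTERS, CLUSTER_STEPS
from .io_formats import (
    ExpressionExperiment,
    GeneSet,
    SpikeInReference,
    ValidationError,
)

STAGES = ("GV", "MII", "D3")
GENOTYPES = ("control", "mutant")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    Defaults encode the study conditions the analysis is built for: a
    40% reduction of endogenous GV dosage in mutants
    (``mutant_gv_dosage_factor=0.6``), mutants retaining only 30% of each
    log2 degradation step (``mutant_decay_attenuation=0.3``, i.e. decay is
    impaired), mutants realising only 30% of each day-3 elevation step
    (``mutant_zga_attenuation=0.3``, i.e. ZGA is impaired), 4-fold
    (2 log2) trajectory steps, and spike-ins contributing 5% of a control
    GV library.
    """

    genes_per_cluster: tuple[int, ...] = (200,) * 9  # clusters I..IX
    n_samples: int = 3  # per (stage, genotype) cell
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    cluster_step_log2: float = 2.0
    nb_dispersion: float = 0.1
    library_size_mean: float = 2e6
    library_size_cv: float = 0.2
    n_spike_ins: int = 92
    spike_fraction: float = 0.05
    mutant_gv_dosage_factor: float = 0.6
    mutant_decay_attenuation: float = 0.3
    mutant_zga_attenuation: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if len(self.genes_per_cluster) != 9:
            raise ValidationError("genes_per_cluster must have 9 entries (clusters I-IX)")
        if any(g < 0 for g in self.genes_per_cluster):
            raise ValidationError("genes_per_cluster entries must be non-negative")
        if sum(self.genes_per_cluster) <= 0:
            raise ValidationError("at least one cluster must contain genes")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not 0 < self.spike_fraction < 1:
            raise ValidationError("spike_fraction must lie in (0, 1)")
        if not 0 < self.mutant_gv_dosage_factor <= 1:
            raise ValidationError("mutant_gv_dosage_factor must lie in (0, 1]")
        for name in ("mutant_decay_attenuation", "mutant_zga_attenuation"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.library_size_mean <= 0 or self.library_size_cv <= 0:
            raise ValidationError("library size parameters must be positive")
        if self.n_spike_ins < 1:
            raise ValidationError("n_spike_ins must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth for every simulated gene and sample."""

    cluster: pd.Series  # gene -> cluster I..IX or "spike"
    rates: pd.DataFrame  # genes x MultiIndex (stage, genotype): expected expression rate
    gene_sets: dict[str, frozenset[str]]  # "ZGA", "M-decay"
    sample_dosage: pd.Series  # sample -> true absolute endogenous dosage (sum of rates)
    config: SimulationConfig = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.sample_dosage <= 0).any():
            raise ValidationError("true dosage must be positive")


def _mutant_step(sign: int, step: float, decay_atten: float, zga_atten: float,
                 is_d3_transition: bool) -> float:
    """Signed log2 step realised by the mutant for one transition."""
    if sign < 0:
        return -step * decay_atten
    if sign > 0:
        return step * (zga_atten if is_d3_transition else 1.0)
    return 0.0


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExpressionExperiment, SpikeInReference, list[GeneSet], SimulationTruth]:
    """Generate a control/mutant GV–MII–D3 experiment with full ground truth.

    Returns the experiment (counts + metadata, spike rows flagged), the
    spike-in reference table, the ZGA and M-decay gene sets, and the truth
    record (per-gene cluster and stage × genotype rate matrix, per-sample
    absolute dosage).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_genes = int(sum(config.genes_per_cluster))
    gene_ids = np.array([f"gene_{i:05d}" for i in range(n_genes)])
    cluster_labels = np.repeat(list(CLUSTERS), config.genes_per_cluster)

    # Endogenous molar rates per (stage, genotype).  The baseline
    # distribution anchors each gene's day-3 control level; the GV level is
    # that anchor minus the trajectory's net signed step.  Transcripts
    # destined for degradation therefore start high (stockpiled maternal
    # mRNA) and transcripts elevated by day 3 start low (ZGA), which is
    # what makes the control total dosage decline GV -> MII -> D3.
    step = config.cluster_step_log2
    signs = np.array([CLUSTER_STEPS[c] for c in cluster_labels])  # (n_genes, 2)
    anchor = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    base = 2.0 ** (anchor - (signs[:, 0] + signs[:, 1]) * step)

    rates = {}
    rates[("GV", "control")] = base
    rates[("MII", "control")] = base * 2.0 ** (signs[:, 0] * step)
    rates[("D3", "control")] = rates[("MII", "control")] * 2.0 ** (signs[:, 1] * step)

    mut_d1 = np.array([
        _mutant_step(s, step, config.mutant_decay_attenuation,
                     config.mutant_zga_attenuation, is_d3_transition=False)
        for s in signs[:, 0]
    ])
    mut_d2 = np.array([
        _mutant_step(s, step, config.mutant_decay_attenuation,
                     config.mutant_zga_attenuation, is_d3_transition=True)
        for s in signs[:, 1]
    ])
    rates[("GV", "mutant")] = base * config.mutant_gv_dosage_factor
    rates[("MII", "mutant")] = rates[("GV", "mutant")] * 2.0 ** mut_d1
    rates[("D3", "mutant")] = rates[("MII", "mutant")] * 2.0 ** mut_d2

    # Gene effective lengths: log-uniform in [500, 5000] so TPM != raw proportions.
    lengths = np.exp(rng.uniform(np.log(500.0), np.log(5000.0), n_genes))

    # Spike-ins: identical absolute rate in every sample, nominal amounts
    # log-uniform over four decades, scaled so spikes make up spike_fraction
    # of the read mass of a control GV library.  Spike length fixed at 1 kb.
    spike_ids = np.array([f"ERCC-{i:05d}" for i in range(config.n_spike_ins)])
    nominal = 10.0 ** rng.uniform(-2, 2, config.n_spike_ins)
    spike_len = np.full(config.n_spike_ins, 1000.0)
    endo_read_mass = float(np.sum(rates[("GV", "control")] * lengths))
    spike_read_mass = endo_read_mass * config.spike_fraction / (1.0 - config.spike_fraction)
    spike_read_rates = nominal / nominal.sum() * spike_read_mass
    spike_rates = spike_read_rates / spike_len

    all_ids = np.concatenate([gene_ids, spike_ids])
    all_lengths = np.concatenate([lengths, spike_len])
    is_spike = np.concatenate([np.zeros(n_genes, bool), np.ones(config.n_spike_ins, bool)])

    # Samples and counts.
    sample_rows = []
    count_cols = {}
    dosage = {}
    alpha = config.nb_dispersion
    sigma2 = np.log1p(config.library_size_cv**2)
    mu_log = np.log(config.library_size_mean) - sigma2 / 2.0
    for genotype in GENOTYPES:
        for stage in STAGES:
            cell_rates = np.concatenate([rates[(stage, genotype)], spike_rates])
            read_rates = cell_rates * all_lengths
            props = read_rates / read_rates.sum()
            for i in range(config.n_samples):
                sid = f"{genotype}_{stage}_{i + 1}"
                lib = np.exp(rng.normal(mu_log, np.sqrt(sigma2)))
                mu = lib * props
                lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
                count_cols[sid] = rng.poisson(lam)
                sample_rows.append({"sample_id": sid, "stage": stage, "genotype": genotype})
                dosage[sid] = float(rates[(stage, genotype)].sum())

    gene_index = pd.Index(all_ids, name="gene_id")
    counts = pd.DataFrame(count_cols, index=gene_index)
    gene_meta = pd.DataFrame({"length": all_lengths, "is_spike_in": is_spike}, index=gene_index)
    sample_meta = pd.DataFrame(sample_rows).set_index("sample_id")
    exp = ExpressionExperiment(counts=counts, gene_meta=gene_meta, sample_meta=sample_meta)
    ref = SpikeInReference(
        amounts=pd.Series(nominal, index=pd.Index(spike_ids, name="spike_id"),
                          name="nominal_amount")
    )

    cluster = pd.Series(
        np.concatenate([cluster_labels, np.full(config.n_spike_ins, "spike")]),
        index=gene_index, name="cluster",
    )
    zga = frozenset(gene_ids[cluster_labels == "VI"])
    mdecay = frozenset(gene_ids[np.isin(cluster_labels, ["I", "III"])])
    gene_sets = [
        GeneSet(name, members, desc)
        for name, members, desc in (
            ("ZGA", zga, "day-3 elevated transcripts (cluster VI truth)"),
            ("M-decay", mdecay, "maturation-degraded transcripts (clusters I+III truth)"),
        )
        if members  # a cluster configured empty yields no set
    ]

    rate_df = pd.DataFrame(
        {(stage, geno): rates[(stage, geno)] for geno in GENOTYPES for stage in STAGES},
        index=gene_ids,
    )
    rate_df.columns = pd.MultiIndex.from_tuples(rate_df.columns, names=["stage", "genotype"])

    truth = SimulationTruth(
        cluster=cluster,
        rates=rate_df,
        gene_sets={"ZGA": zga, "M-decay": mdecay},
        sample_dosage=pd.Series(dosage, name="true_dosage"),
        config=config,
    )
    return exp, ref, gene_sets, truth


def truth_cluster_counts(truth: SimulationTruth) -> pd.Series:
    """Number of simulated genes per trajectory cluster I–IX (spikes excluded)."""
    counts = truth.cluster[truth.cluster != "spike"].value_counts()
    return counts.reindex(CLUSTERS, fill_value=0).rename("n_genes")
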