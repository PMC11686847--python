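"""Generate a synthetic oocyte/embryo experiment and measure absolute mRNA dosage.

Simulates control and mutant single-cell transcriptomes across GV, MII and
day-3 stages with spike-ins, computes TPM, calibrates to the spike-in
anchor and reports per-stage endogenous totals.  The mutant GV dosage is
planted at 60% of control; the recovered ratio should sit near 0.6.
"""

from oodyn import (
    SimulationConfig,
    compute_tpm,
    simulate_experiment,
    spike_in_calibrate,
    total_dosage,
)

config = SimulationConfig(n_samples=5, seed=42)
exp, spike_ref, gene_sets, truth = simulate_experiment(config)
print(f"simulated {exp.counts.shape[0]} transcripts x {exp.counts.shape[1]} samples "
      f"({len(exp.spike_ids)} spike-ins)")

mat = spike_in_calibrate(compute_tpm(exp), exp, spike_ref)
dosage = total_dosage(mat, exp)

print("\nmean calibrated endogenous total (absolute dosage) per group:")
print(dosage.group_summary["mean"].unstack().round(0))

gv_ratio = dosage.stage_tests.loc["GV", "mean_ratio_mut_ctrl"]
print(f"\nmutant/control GV dosage ratio: {gv_ratio:.3f} "
      f"(planted {config.mutant_gv_dosage_factor}); "
      f"Welch p = {dosage.stage_tests.loc['GV', 'p']:.2e}")
print("control totals should decline GV -> MII -> D3 as maternal mRNA decays;")
print("the mutant GV deficit reflects reduced maternal mRNA storage.")
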