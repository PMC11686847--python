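"""Overlap of day-3 DEG lists with the ZGA and maternal-decay gene sets.

Downregulated day-3 transcripts should be enriched for ZGA genes (zygotic
transcription fails) and upregulated ones for maternal-decay genes
(clearance fails).
"""

from oodyn import (
    SimulationConfig,
    annotate_enrichment,
    deg_per_stage,
    overlap_percentage,
    simulate_experiment,
)

exp, _, gene_sets, _ = simulate_experiment(SimulationConfig(seed=42))
deg_d3 = deg_per_stage(exp, stages=("D3",))["D3"]
by_name = {gs.name: gs for gs in gene_sets}

for set_name, direction in (("ZGA", "down"), ("M-decay", "up")):
    ids = deg_d3.index[deg_d3["call"] == direction]
    stat = overlap_percentage(ids, by_name[set_name], list_name=f"D3 {direction}")
    annotate_enrichment(stat, universe=len(deg_d3))
    print(f"{stat.overlap} of {stat.list_size} {direction}regulated day-3 transcripts "
          f"are {set_name} genes: {stat.display_percent}% "
          f"(hypergeometric p = {stat.p_hyper:.2e})")

print("\nhigh fractions with tiny p values tie the day-3 phenotype to failed ZGA")
print("and failed maternal decay respectively.")
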