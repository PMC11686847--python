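"""Per-stage mutant-vs-control differential expression with the NB/Wald test.

Counts are compared within each stage; a gene is called up/down when
|log2 FC| > 1 with BH-adjusted p < 0.05 (both strict).
"""

from oodyn import SimulationConfig, deg_per_stage, simulate_experiment

exp, *_ = simulate_experiment(SimulationConfig(seed=42))
degs = deg_per_stage(exp)

for stage, table in degs.items():
    up = int((table["call"] == "up").sum())
    down = int((table["call"] == "down").sum())
    print(f"{stage:>3}: {down:4d} transcripts down, {up:4d} up "
          f"(of {len(table)} tested)")

print("\nmutant MII/D3 samples accumulate 'up' transcripts: maternal mRNAs that")
print("should have been cleared persist when decay is impaired, and day-3")
print("'down' transcripts reflect the ZGA failure.")
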