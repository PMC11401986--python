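"""Simulate a single-cell SNP-array batch with WGA noise.

Generates a small haploid (sperm-like) two-family batch, then checks the
realized error rates against the configured ones.
"""

from pathlib import Path

from scsnp import SimulationConfig, simulate_batch

out = Path("scratch/example_batch")
config = SimulationConfig(
    n_samples=6, n_snps=4000, families=(("F1", 3), ("F2", 3)),
    ado_rate=0.20, adi_rate=0.10, nc_rate=0.03, seed=1,
)
paths, truth = simulate_batch(config, out)

print(f"fixture files written to {out}:")
for key in ("manifest", "cluster", "samplesheet", "truth"):
    print(f"  {key:12s} {paths[key].name}")

rates = truth["error_class"].value_counts(normalize=True)
print("\nrealized per-call error classes:")
print(rates.to_string())
# 'ADI' tracks adi_rate among homozygous templates; in a haploid batch 'NC'
# combines baseline no-calls with single-allele amplification failures
# (ado_rate), so it sits near 1 - (1-0.20)(1-0.03) ~= 0.22.
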