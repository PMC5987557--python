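"""QC statistics of a methylome pair: bimodality and replicate agreement.

CpG methylation is strongly bimodal genome-wide (most sites fully
methylated or fully unmethylated), and two technical replicates of the
same methylome should correlate very highly at adequate depth.  Both
properties are quick sanity checks before any differential analysis.
"""

from twindmr import (
    SimulationConfig, methylation_distribution, sample_correlation,
    simulate_methylome_pair,
)

cfg = SimulationConfig(seed=3, n_dmrs=0)  # replicate pair: no true differences
s1, s2, _ = simulate_methylome_pair(cfg)

counts, edges = methylation_distribution(s1, bins=10)
total = counts.sum()
print("per-site methylation level histogram (10 bins):")
for i, c in enumerate(counts):
    print(f"  [{edges[i]:.1f},{edges[i+1]:.1f}] {'#' * int(60 * c / total)} {c}")
print(f"extreme-decile mass: {(counts[0]+counts[-1])/total:.1%} (bimodal methylome)")

r = sample_correlation(s1, s2, min_depth=10)
print(f"inter-replicate Pearson r over shared deep CpGs: {r:.4f} (expect > 0.95)")
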