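"""Classify called DMRs into genomic categories and find TFBS overlaps.

Each DMR receives one of seven categories (upstream / UTR5 / exonic /
intronic / UTR3 / downstream / intergenic) by promoter-first priority;
"upstream" means the DMR overlaps the 2 kb flank 5' of a transcription
start site — the promoter proxy.
"""

from twindmr import (
    DMRParams, SimulationConfig, annotate_dmrs, call_dmrs,
    simulate_gene_models, simulate_methylome_pair, simulate_tfbs,
    summarize_categories, tfbs_in_dmrs,
)

cfg = SimulationConfig(seed=1)
s1, s2, truth = simulate_methylome_pair(cfg)
dmrs, _ = call_dmrs(s1, s2, DMRParams(), cfg.chrom_sizes)

# couple the first five planted regions to gene promoters
genes = simulate_gene_models(cfg, 30, promoter_regions=truth.regions[:5])
tfbs = simulate_tfbs(cfg, ["GATA4", "NKX2-5", "ZIC3", "NR2F2", "TBX5"], 300,
                     enrich_regions=truth.regions, enrichment=10.0)

annotated = annotate_dmrs(dmrs, genes, tfbs_records=tfbs)
summary = summarize_categories(annotated)
for direction, counts in summary.counts.items():
    nonzero = {c: n for c, n in counts.items() if n}
    print(f"{direction}: {nonzero}")
print(
    f"promoter DMRs: {summary.n_promoter_dmrs} "
    f"(linking {summary.n_tss} TSSs of {summary.n_genes} genes)"
)
_, tf_set = tfbs_in_dmrs(dmrs, tfbs)
print(f"distinct TFs with binding sites inside DMRs: {sorted(tf_set)}")
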