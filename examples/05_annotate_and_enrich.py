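"""Annotate CNVRs against genes, QTLs and known SVs, then test trait
enrichment.

Each overlapping (region, annotation) pair is reported with the shared bp
and percentages; genes are complete (contained in a region) or partial;
regions sharing no base with any known SV are novel. Traits whose QTLs
overlap regions more often than chance expects get small hypergeometric
p-values, adjusted by Benjamini-Hochberg FDR.
"""

import cnvrkit as ck

config = ck.SimulationConfig(seed=13, n_samples=150, n_loci=80,
                             chromosome_lengths_mb=(45.0, 40.0, 35.0))
genome = ck.make_genome(config)
snp_map = ck.make_snp_map(genome, config)
loci = ck.plant_loci(genome, config)
calls_a, calls_b, _ = ck.simulate_samples(loci, genome, snp_map, config)
hc = ck.intersect_datasets(ck.filter_calls(calls_a), ck.filter_calls(calls_b))
cnvrs = ck.build_cnvrs(hc)

genes, qtls, svs = ck.simulate_annotations(
    genome, loci[["chrom", "start", "end", "state"]], config)

gene_overlaps = ck.overlap(cnvrs, genes, kind="gene")
complete = (gene_overlaps["completeness"] == "complete").sum()
print(f"{gene_overlaps['annotation_id'].nunique()} genes overlapped "
      f"({complete} complete overlaps)")

novelty = ck.classify_novelty(cnvrs, svs)
print(novelty["category"].value_counts().to_string())

qtl_overlaps = ck.overlap(cnvrs, qtls.rename(columns={"qtl_id": "id"}),
                          kind="qtl")
results = ck.qtl_enrichment(qtls, qtl_overlaps)
print("\ntop enrichment results:")
print(results.head(3)[["category", "k", "S", "m", "N", "p_value", "p_fdr",
                       "enriched"]].to_string(index=False))
# k of S QTLs of the trait overlap regions, against m of N QTLs overall;
# the planted trait ('Milk yield') should top the table with p_fdr < 0.05.
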