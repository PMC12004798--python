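"""High-confidence intersection and density-trimmed CNVR construction.

A call is high-confidence when the same sample shows the exact same event
(chromosome, start, end, state) in both processed datasets. High-confidence
calls are merged into regions; bases supported by fewer than 10% of a
region's contributing calls are trimmed away.
"""

import cnvrkit as ck

config = ck.SimulationConfig(seed=11, n_samples=150, n_loci=80,
                             chromosome_lengths_mb=(45.0, 40.0, 35.0))
genome = ck.make_genome(config)
snp_map = ck.make_snp_map(genome, config)
loci = ck.plant_loci(genome, config)
calls_a, calls_b, _ = ck.simulate_samples(loci, genome, snp_map, config)

filtered_a = ck.filter_calls(calls_a)
filtered_b = ck.filter_calls(calls_b)
hc = ck.intersect_datasets(filtered_a, filtered_b)
nonredundant = ck.collapse_nonredundant(hc)
summary = ck.cohort_summary(hc, nonredundant)

print(f"high-confidence calls: {summary['total_calls']} "
      f"({summary['deletion_pct']:.1f}% deletions)")
print(f"non-redundant events: {summary['nonredundant_events']}, "
      f"mean carriers per event {summary['mean_carriers_per_event']:.2f}")

cnvrs = ck.build_cnvrs(hc, density=0.1)
print(ck.summarize(cnvrs, genome).to_text())
# Coverage is the fraction of the genome inside regions; the histogram uses
# inclusive upper bounds (a 200 kb region is "200 kb or shorter").
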