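"""Simulate an 11-population HapMap-style panel with one planted lethal
genotype, then scan it.

SNP index 10 carries a fully lethal minor homozygote (survival 0): no such
individual can appear in any population, although the allele frequencies
predict dozens. The scan should flag exactly that SNP.
"""

from lethalscan import SimConfig, generate_panel, scan_chromosome

config = SimConfig(
    n_snps=500,
    maf=(0.2, 0.5),                     # per-population minor allele freqs
    lethal_snps={10: (2, 0.0)},         # SNP 10: minor homozygote lethal
    missing_rate=0.01,
    seed=7,
)
tables, truth = generate_panel(config)
print(f"simulated {len(tables)} populations, "
      f"{sum(t.n_individuals for t in tables)} individuals, "
      f"{config.n_snps} SNPs")

summary = scan_chromosome(tables, alpha=0.05)
print(f"retained SNPs (k):        {summary.n_tested_snps}")
print(f"hypotheses tested (3k):   {summary.n_hypotheses}")
print(f"Bonferroni threshold:     {summary.threshold:.2E}")
print(f"flagged SNPs:             {summary.n_flagged}")
for r in summary.results:
    print(f"  {r.snp.rsid}  absent genotype {r.genotype}  "
          f"pooled expected count {r.total_expectation:.1f}  "
          f"p-value {r.p_value:.2E}")
print()
print("The flagged SNP is the planted one; the pooled expected count is the")
print("number of minor homozygotes the panel should contain but does not.")
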