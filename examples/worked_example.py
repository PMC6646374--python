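"""The screen's logic on a single hand-sized population.

A population of 1000 individuals is split 500/500 between the two
homozygotes of a bi-allelic SNP and contains no heterozygotes at all.
Random mating says half of the next generation should be heterozygous, so
observing zero of them is astronomically improbable — the signature of a
lethal heterozygote.
"""

import math

from lethalscan import (GenotypeCounts, MultiPopulationCounts, SNPMeta,
                        evaluate_genotype_class, next_gen_distribution)

p = [0.5, 0.0, 0.5]  # observed frequencies of AA, Aa, aa
p_star = next_gen_distribution(p)
print(f"observed genotype frequencies:      {p}")
print(f"next-generation (random mating):    {p_star.round(4).tolist()}")
print(f"expected heterozygote frequency:    {p_star[1]:.2f}")

counts = MultiPopulationCounts(
    snp=SNPMeta("rs_demo", "1", 1000, ("A", "C")),
    per_pop=[GenotypeCounts("DEMO", n0=500, n1=0, n2=500, n_missing=0)],
)
result = evaluate_genotype_class(counts, i=1)
print(f"expected heterozygotes in n=1000:   {result.total_expectation:.0f}")
print(f"log p-value of observing zero:      {result.log_p_value:.1f}"
      f"  (= 1000*ln(0.5) = {1000 * math.log(0.5):.1f})")
print(f"p-value:                            {result.p_value:.2E}")
print()
print("A p-value this small means the heterozygote class cannot be absent")
print("by sampling chance; its carriers are plausibly not surviving to be")
print("sampled.")
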