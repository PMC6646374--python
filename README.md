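# lethalscan

Screen multi-population SNP genotype panels for **potentially lethal
genotypes** — genotype classes that random mating says should be common but
that appear in zero sampled individuals across every population.

If a genotype (say, the minor homozygote `aa` of a bi-allelic SNP) causes
embryonic failure or childhood death, its carriers never reach the adult
cohorts that projects like HapMap sample. The signature is an *abnormal
genotype distribution*: both alleles are clearly segregating, yet one of the
three diploid classes is entirely missing, simultaneously, in every
population. `lethalscan` quantifies how improbable that joint absence is
and flags SNPs whose absent class survives a strict Bonferroni correction.
It is aimed at statistical geneticists triaging candidate lethal variants
from multi-population genotype panels.

## The statistic

For a bi-allelic SNP write the genotype classes g0 = `AA`, g1 = `Aa`,
g2 = `aa` (A = major allele). In population *j*, let
P = [p0, p1, p2] be the observed genotype frequencies among called
individuals. One generation of random mating maps P to

    p0* = (p0 + p1/2)²
    p1* = 2 (p0 + p1/2)(p2 + p1/2)
    p2* = (p2 + p1/2)²

— Hardy–Weinberg proportions at the current allele frequencies. If class
g_i is unobserved in the n_j sampled individuals of population *j*, the
binomial probability of that zero is

    Pr(e_ij) = (1 − p_i*)^(n_j)

and the probability that g_i is absent from **all** J populations at once is

    p_value(eAll) = ∏_j Pr(e_ij)

computed in log space (fully absent common classes underflow doubles).
With k SNPs on a chromosome, 3k class-absence hypotheses are tested, so a
SNP is flagged when its p-value falls below the Bonferroni threshold
**α/(3k)** (α = 0.05 by default, per chromosome).

The package also ships a synthetic panel generator emulating the HapMap
phase-3 structure (11 populations, 1417 individuals), with per-population
allele frequencies, genotype-specific viability selection (lethal classes
with survival probability *s*), and missingness — used to measure the
screen's family-wise error rate and power.

## Worked example

A population of 1000 with 500 `AA`, 500 `aa` and no heterozygotes
(`examples/worked_example.py`):

```
observed genotype frequencies:      [0.5, 0.0, 0.5]
next-generation (random mating):    [0.25, 0.5, 0.25]
expected heterozygote frequency:    0.50
expected heterozygotes in n=1000:   500
log p-value of observing zero:      -693.1  (= 1000*ln(0.5) = -693.1)
p-value:                            9.33E-302
```

Half the next generation should be heterozygous; seeing none of an expected
500 has probability 0.5^1000 — the distribution is abnormal and the
heterozygote class is a lethality candidate.

End to end on a simulated panel (`examples/simulate_and_scan.py`): one SNP
among 500 carries a fully lethal minor homozygote; the scan retains
k = 500 SNPs, tests 1500 hypotheses at threshold 3.33E-05, and flags
exactly the planted SNP:

```
  rs000011  absent genotype GG  pooled expected count 101.3  p-value 1.30E-46
```

`examples/calibration.py` measures the operating characteristics by
simulation (null FWER ≈ 0 at α = 0.05; detection rate 1.0 for a fully
lethal homozygote at minor-allele frequency 0.3).

## Input formats

- **HapMap phase-3 genotype files**: whitespace-delimited; header columns
  `rs# alleles chrom pos strand` + 6 metadata columns + individual IDs; one
  SNP per row; genotypes as two-letter strings, `NN` = missing. One file
  per population per chromosome. X/Y/MT rows are dropped with a warning.
- **TSV matrix**: header `rsid chrom pos alleles strand` + individual IDs;
  empty cells mean missing. Round-trips exactly through
  `write_matrix_tsv`/`read_matrix_tsv`.

## Command line

```sh
lethalscan simulate --config sim.yaml --out panel/
lethalscan scan --input-dir panel/ \
    --populations ASW,CEU,CHB,CHD,GIH,JPT,LWK,MEX,MKK,TSI,YRI \
    --alpha 0.05 --n-source called --correction per-chromosome --out scan/
lethalscan validate --mode fwer --config null.yaml --reps 50 --out val/
```

`scan` writes `results.tsv` (flagged SNPs with per-population expected
counts and p-values in `3.05E-16`-style notation), `qc.tsv` (per-SNP drop
reasons) and `summary.json` (k, thresholds, config echo).

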