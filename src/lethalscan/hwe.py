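"""The zero-observed-genotype screen statistic.

For a bi-allelic SNP with genotype classes g0='AA', g1='Aa', g2='aa'
(A = major, a = minor allele), the observed genotype frequencies
P = [p0, p1, p2] in one population imply, under random mating, the
next-generation distribution

    p0* = (p0 + p1/2)^2
    p1* = 2 (p0 + p1/2) (p2 + p1/2)
    p2* = (p2 + p1/2)^2

i.e. Hardy–Weinberg proportions at the current allele frequencies. If class
g_i is entirely unobserved in a sample of n individuals, the probability of
that zero under a binomial model is (1 - p_i*)^n; evidence is combined
across populations by multiplying these probabilities (the classes being
aligned by the pooled major/minor assignment). A tiny combined probability
for a class that is nevertheless absent everywhere marks the genotype as
potentially lethal.

All products are carried in log space: a fully absent common heterozygote
can drive the combined probability far below double-precision underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .hapmap import SNPMeta
from .harmonize import MultiPopulationCounts

_SIMPLEX_TOL = 1e-9

GENOTYPE_CLASSES = ("major-homozygote", "heterozygote", "minor-homozygote")


def next_gen_distribution(p: Sequence[float]) -> np.ndarray:
    """Random-mating update: genotype distribution of the next generation.

    Maps [p0, p1, p2] to Hardy–Weinberg proportions at the allele
    frequencies implied by p. Idempotent (HWE is reached in one
    generation) and allele-frequency preserving.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or np.any(p < -_SIMPLEX_TOL) or np.any(p > 1 + _SIMPLEX_TOL):
        raise ValueError(f"not a genotype distribution: {p!r}")
    if abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"genotype frequencies must sum to 1, got {p.sum()!r}")
    f_major = p[0] + p[1] / 2.0
    f_minor = p[2] + p[1] / 2.0
    return np.array([f_major * f_major, 2.0 * f_major * f_minor, f_minor * f_minor])


def log_prob_zero_observed(p_star: float, n: int) -> float:
    """log Pr(zero individuals of a class with frequency ``p_star`` in ``n``).

    Computed as n·log1p(−p_star) for numerical stability. Degenerate
    cases: p_star == 1 with n >= 1 gives −inf; n == 0 or p_star == 0
    gives 0 (the zero is certain).
    """
    if not 0.0 <= p_star <= 1.0:
        raise ValueError(f"p_star must be in [0,1], got {p_star}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0 or p_star == 0.0:
        return 0.0
    if p_star == 1.0:
        return -math.inf
    return n * math.log1p(-p_star)


def combine_populations(log_probs: Sequence[float]) -> tuple[float, float]:
    """Multiply per-population zero-observation probabilities (in log space).

    Returns (log_p_value, p_value); p_value is 0 when the sum is below
    double underflow, with the log retained.
    """
    total = 0.0
    for lp in log_probs:
        if lp > 0.0:
            raise ValueError(f"log-probability must be <= 0, got {lp}")
        total += lp
    return total, math.exp(total) if total > -746 else 0.0


def bonferroni_threshold(k: int, alpha: float = 0.05) -> float:
    """Significance threshold alpha/(3k) for k SNPs, three classes each."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / (3.0 * k)


@dataclass
class TestResult:
    """Outcome of testing one genotype class of one SNP for improbable absence.

    ``per_pop_expectation[j]`` is n_j · p*_ij, the expected number of
    class-``genotype_class`` individuals in population j; ``p_value`` is
    the product over populations of (1 − p*_ij)^{n_j}. ``k_tested``,
    ``threshold`` and ``flagged`` are filled in by the chromosome scan.
    """

    __test__ = False  # keep pytest from collecting this as a test class

    snp: SNPMeta
    genotype_class: int
    genotype: str
    populations: list[str]
    per_pop_pstar: list[float]
    per_pop_expectation: list[float]
    per_pop_log_prob: list[float]
    log_p_value: float
    p_value: float
    k_tested: int | None = None
    threshold: float = float("nan")
    flagged: bool | None = None

    @property
    def total_expectation(self) -> float:
        """Expected count of the absent class pooled over all populations."""
        return float(sum(self.per_pop_expectation))


NSource = Literal["called", "panel"]


def evaluate_genotype_class(
    counts: MultiPopulationCounts,
    i: int,
    n_source: NSource = "called",
) -> TestResult | None:
    """Test whether genotype class ``i`` is improbably absent everywhere.

    Returns None unless the class-i count is zero in every population.
    Otherwise, per population: P is estimated from the called genotype
    counts, p* is the class-i component of the random-mating update, and
    the sample size n_j is the called count at this SNP (``n_source=
    "called"``, default) or the full panel size including missing calls
    (``"panel"``).
    """
    if i not in (0, 1, 2):
        raise ValueError(f"genotype class must be 0, 1 or 2, got {i}")
    if any(c.counts[i] > 0 for c in counts.per_pop):
        return None

    pstars: list[float] = []
    expectations: list[float] = []
    log_probs: list[float] = []
    for c in counts.per_pop:
        nc = c.n_called
        if nc == 0:
            raise ValueError(
                f"{counts.snp.rsid}: population {c.population} has no calls "
                "(should be dropped in harmonization)"
            )
        p = np.array(c.counts, dtype=float) / nc
        p_star = float(next_gen_distribution(p)[i])
        n_j = nc if n_source == "called" else c.n_total
        pstars.append(p_star)
        expectations.append(n_j * p_star)
        log_probs.append(log_prob_zero_observed(p_star, n_j))

    log_p, p = combine_populations(log_probs)
    major, minor = counts.snp.alleles
    rendering = (major + major, major + minor, minor + minor)[i]
    return TestResult(
        snp=counts.snp,
        genotype_class=i,
        genotype=rendering,
        populations=counts.populations,
        per_pop_pstar=pstars,
        per_pop_expectation=expectations,
        per_pop_log_prob=log_probs,
        log_p_value=log_p,
        p_value=p,
    )
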