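"""Cross-population SNP harmonization.

Intersects SNPs across population tables, enforces a consistent bi-allelic
encoding (reconciling strand flips by reverse-complement where unambiguous),
assigns major/minor allele roles from pooled counts, and produces the
per-population genotype counts the screen tests.

Allele roles are assigned globally (pooled over all populations), not per
population, so the three genotype classes line up across populations when
their zero-observation probabilities are multiplied.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .hapmap import GenotypeTable, SNPMeta

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
#: allele sets that are their own reverse complement — a strand flip is
#: undetectable for these, so they are never reconciled by guessing
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype-class counts for one SNP in one population.

    n0/n1/n2 count major-homozygotes, heterozygotes and minor-homozygotes;
    any call containing 'N' counts as missing in full.
    """

    population: str
    n0: int
    n1: int
    n2: int
    n_missing: int

    def __post_init__(self) -> None:
        if min(self.n0, self.n1, self.n2, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_called(self) -> int:
        return self.n0 + self.n1 + self.n2

    @property
    def n_total(self) -> int:
        """Panel size: called plus missing individuals."""
        return self.n_called + self.n_missing

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n0, self.n1, self.n2)


@dataclass
class MultiPopulationCounts:
    """Per-population genotype counts for one harmonized SNP.

    ``snp.alleles`` is ordered (major, minor); population order is fixed
    across all SNPs in one run.
    """

    snp: SNPMeta
    per_pop: list[GenotypeCounts]

    @property
    def populations(self) -> list[str]:
        return [c.population for c in self.per_pop]


def assign_allele_roles(pooled_counts: Mapping[str, int]) -> tuple[str, str]:
    """Return (major, minor) from pooled allele counts.

    The major allele has the greater pooled count (homozygotes counted
    twice, heterozygotes once); ties break to the lexicographically smaller
    character.
    """
    if len(pooled_counts) != 2:
        raise ValueError(
            f"expected exactly 2 alleles, got {sorted(pooled_counts)}"
        )
    ordered = sorted(pooled_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[0][0], ordered[1][0]


def count_genotypes(
    calls: Sequence[str], major: str, minor: str, population: str = ""
) -> GenotypeCounts:
    """Tally calls into the three genotype classes plus missing.

    Heterozygotes are counted regardless of character order ("AC" == "CA").
    A call carrying an allele outside {major, minor} raises (tri-allelic
    leak — such SNPs must be filtered upstream).
    """
    tally = Counter(calls)
    n0 = n1 = n2 = n_missing = 0
    hom_major = major + major
    hom_minor = minor + minor
    het = {major + minor, minor + major}
    for call, n in tally.items():
        if "N" in call:
            n_missing += n
        elif call == hom_major:
            n0 += n
        elif call in het:
            n1 += n
        elif call == hom_minor:
            n2 += n
        else:
            raise ValueError(
                f"call {call!r} contains an allele outside {{{major},{minor}}}"
            )
    return GenotypeCounts(population, n0, n1, n2, n_missing)


def complement_calls(calls: Sequence[str]) -> list[str]:
    """Reverse-complement every call (strand reconciliation); involutive."""
    return [_COMPLEMENT[c[0]] + _COMPLEMENT[c[1]] for c in calls]


def _observed_alleles(tally: Counter) -> set[str]:
    alleles: set[str] = set()
    for call in tally:
        if "N" not in call:
            alleles.update(call)
    return alleles


def harmonize_snps(
    tables: Sequence[GenotypeTable],
    min_call_rate: float = 0.0,
    min_maf: float = 0.0,
) -> tuple[list[MultiPopulationCounts], list[tuple[str, str]]]:
    """Intersect SNPs across populations and produce harmonized counts.

    A SNP is retained iff it (a) appears by rsid in every table, (b) has a
    consistent allele set of size <= 2 pooled over populations after any
    reverse-complement reconciliation, (c) is bi-allelic in the pooled
    calls, (d) has at least one called genotype in every population and a
    call rate >= ``min_call_rate`` everywhere. Monomorphic SNPs are kept
    (the screen assigns them p-value 1). ``min_maf`` > 0 additionally
    requires the pooled minor-allele frequency to reach that floor.

    Returns the retained SNPs (in the first table's order) and a QC list of
    (rsid, drop-reason) pairs.
    """
    if len(tables) < 1:
        raise ValueError("harmonization needs at least 1 population")

    index_by_pop: list[dict[str, int]] = []
    for t in tables:
        idx: dict[str, int] = {}
        for k, snp in enumerate(t.snps):
            if snp.rsid in idx:
                raise ValueError(f"duplicate rsid {snp.rsid} in {t.population}")
            idx[snp.rsid] = k
        index_by_pop.append(idx)

    common = set(index_by_pop[0])
    for idx in index_by_pop[1:]:
        common &= set(idx)

    qc: list[tuple[str, str]] = []
    all_rsids = set().union(*index_by_pop)
    for rsid in sorted(all_rsids - common):
        qc.append((rsid, "absent-in-population"))

    kept: list[MultiPopulationCounts] = []
    for snp0 in tables[0].snps:
        rsid = snp0.rsid
        if rsid not in common:
            continue
        pop_calls = [t.calls[index_by_pop[j][rsid]] for j, t in enumerate(tables)]
        pop_meta = [t.snps[index_by_pop[j][rsid]] for j, t in enumerate(tables)]
        tallies = [Counter(c) for c in pop_calls]
        obs_sets = [_observed_alleles(t) for t in tallies]

        if any(sum(n for call, n in t.items() if "N" not in call) == 0
               for t in tallies):
            qc.append((rsid, "no-calls"))
            continue

        pooled = set().union(*obs_sets)
        flipped = [False] * len(tables)
        if len(pooled) > 2:
            # consensus = allele set of the population with the most calls
            ref = max(
                range(len(tables)),
                key=lambda j: (
                    sum(n for c, n in tallies[j].items() if "N" not in c),
                    tables[j].population,
                ),
            )
            consensus = set(obs_sets[ref])
            ok = True
            for j, s in enumerate(obs_sets):
                if s <= consensus:
                    continue
                if frozenset(s) in _PALINDROMIC or frozenset(consensus) in _PALINDROMIC:
                    ok = False
                    break
                comp = {_COMPLEMENT[a] for a in s}
                if comp <= consensus or len(consensus | comp) <= 2:
                    flipped[j] = True
                    consensus |= comp
                else:
                    ok = False
                    break
            if not ok or len(consensus) > 2:
                reason = "strand-ambiguous" if not ok and any(
                    frozenset(s) in _PALINDROMIC for s in obs_sets
                ) else "tri-allelic"
                qc.append((rsid, reason))
                continue
            for j in range(len(tables)):
                if flipped[j]:
                    pop_calls[j] = complement_calls(pop_calls[j])
                    tallies[j] = Counter(pop_calls[j])
                    obs_sets[j] = _observed_alleles(tallies[j])
            pooled = set().union(*obs_sets)
            if len(pooled) > 2:
                qc.append((rsid, "tri-allelic"))
                continue

        # pooled allele counts: homozygotes twice, heterozygotes once
        allele_counts: Counter = Counter()
        for t in tallies:
            for call, n in t.items():
                if "N" not in call:
                    allele_counts[call[0]] += n
                    allele_counts[call[1]] += n

        if len(allele_counts) == 2:
            major, minor = assign_allele_roles(allele_counts)
        else:  # monomorphic: pair the observed allele with the other meta allele
            (major,) = allele_counts
            meta = pop_meta[0].alleles
            if flipped[0]:
                meta = (_COMPLEMENT[meta[0]], _COMPLEMENT[meta[1]])
            minor = meta[1] if meta[0] == major else meta[0]
            if minor == major:
                minor = _COMPLEMENT[major]

        if min_maf > 0 and len(allele_counts) == 2:
            total = sum(allele_counts.values())
            if allele_counts[minor] / total < min_maf:
                qc.append((rsid, "below-min-maf"))
                continue

        per_pop = []
        drop = None
        for j, t in enumerate(tables):
            counts = count_genotypes(pop_calls[j], major, minor, t.population)
            if counts.n_total and counts.n_called / counts.n_total < min_call_rate:
                drop = "below-call-rate"
                break
            per_pop.append(counts)
        if drop:
            qc.append((rsid, drop))
            continue

        meta0 = pop_meta[0]
        kept.append(
            MultiPopulationCounts(
                snp=SNPMeta(rsid, meta0.chrom, meta0.pos, (major, minor),
                            meta0.strand),
                per_pop=per_pop,
            )
        )

    for rsid, reason in qc:
        logger.info("dropped %s: %s", rsid, reason)
    return kept, qc
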