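"""Chromosome and genome scan orchestration.

Harmonizes population tables, tests every retained SNP's three genotype
classes for improbable absence, and flags results below the Bonferroni
threshold alpha/(3k), where k is the number of retained SNPs. The paper
trail for each run is a ScanSummary plus the QC drop list.

Correction is per chromosome by default (k = SNPs retained on the
chromosome under test); genome-wide correction (k = total retained SNPs
over all chromosomes) is available and is strictly more stringent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .hapmap import AUTOSOMES, GenotypeTable
from .harmonize import harmonize_snps
from .hwe import TestResult, bonferroni_threshold, evaluate_genotype_class


@dataclass
class ScanSummary:
    """Outcome of scanning one chromosome.

    ``n_tested_snps`` is k, the retained (post-filter) SNP count; 3k
    hypotheses are tested; ``results`` holds the flagged (SNP, class)
    pairs sorted by ascending p-value; ``n_flagged`` counts distinct
    flagged SNPs.
    """

    chrom: str
    n_input_snps: int
    n_tested_snps: int
    n_hypotheses: int
    threshold: float
    n_flagged: int
    results: list[TestResult] = field(default_factory=list)
    tested: list[TestResult] = field(default_factory=list)
    qc: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_flagged_pairs(self) -> int:
        return len(self.results)


def _sort_key(r: TestResult):
    return (r.p_value, r.log_p_value, int(r.snp.chrom), r.snp.pos, r.snp.rsid,
            r.genotype_class)


def scan_chromosome(
    tables: Sequence[GenotypeTable],
    alpha: float = 0.05,
    n_source: str = "called",
    min_call_rate: float = 0.0,
    min_maf: float = 0.0,
    k_override: int | None = None,
) -> ScanSummary:
    """Scan one autosome's population tables for suspicious genotype classes.

    ``k_override`` substitutes an external hypothesis count for the
    Bonferroni denominator (used by genome-wide correction). With zero
    retained SNPs the threshold is NaN and nothing is flagged.
    """
    chroms = {s.chrom for t in tables for s in t.snps}
    if len(chroms) > 1:
        raise ValueError(f"tables span multiple chromosomes: {sorted(chroms)}")
    if chroms and not chroms <= AUTOSOMES:
        raise ValueError(f"non-autosome chromosome: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else ""

    n_input = len({s.rsid for t in tables for s in t.snps})
    kept, qc = harmonize_snps(tables, min_call_rate=min_call_rate,
                              min_maf=min_maf)
    k = len(kept)
    k_eff = k_override if k_override is not None else k
    if k_eff == 0:
        return ScanSummary(chrom, n_input, 0, 0, float("nan"), 0, [], [], qc)
    threshold = bonferroni_threshold(k_eff, alpha)

    flagged: list[TestResult] = []
    tested: list[TestResult] = []
    for mpc in kept:
        for i in (0, 1, 2):
            r = evaluate_genotype_class(mpc, i, n_source=n_source)
            if r is None:
                continue
            r.k_tested = k_eff
            r.threshold = threshold
            r.flagged = r.p_value < threshold
            tested.append(r)
            if r.flagged:
                flagged.append(r)
    flagged.sort(key=_sort_key)
    return ScanSummary(
        chrom=chrom,
        n_input_snps=n_input,
        n_tested_snps=k,
        n_hypotheses=3 * k,
        threshold=threshold,
        n_flagged=len({r.snp.rsid for r in flagged}),
        results=flagged,
        tested=tested,
        qc=qc,
    )


def scan_genome(
    per_chrom_inputs: Mapping[str, Sequence[GenotypeTable]],
    alpha: float = 0.05,
    n_source: str = "called",
    correction: str = "per-chromosome",
    min_call_rate: float = 0.0,
    min_maf: float = 0.0,
) -> list[ScanSummary]:
    """Scan several autosomes independently.

    With ``correction="per-chromosome"`` (default) each chromosome uses
    its own Bonferroni denominator; ``"genome-wide"`` uses k = total
    retained SNPs across all chromosomes, which can only shrink the
    flagged set.
    """
    for chrom in per_chrom_inputs:
        if chrom not in AUTOSOMES:
            raise ValueError(f"non-autosome chromosome key: {chrom!r}")
    if correction not in ("per-chromosome", "genome-wide"):
        raise ValueError(f"unknown correction {correction!r}")

    order = sorted(per_chrom_inputs, key=int)
    kwargs = dict(alpha=alpha, n_source=n_source,
                  min_call_rate=min_call_rate, min_maf=min_maf)
    if correction == "per-chromosome":
        return [scan_chromosome(per_chrom_inputs[c], **kwargs) for c in order]

    # genome-wide: harmonize first to learn the total k, then rescan
    k_total = 0
    for c in order:
        kept, _ = harmonize_snps(per_chrom_inputs[c],
                                 min_call_rate=min_call_rate, min_maf=min_maf)
        k_total += len(kept)
    if k_total == 0:
        return [scan_chromosome(per_chrom_inputs[c], **kwargs) for c in order]
    return [
        scan_chromosome(per_chrom_inputs[c], k_override=k_total, **kwargs)
        for c in order
    ]
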