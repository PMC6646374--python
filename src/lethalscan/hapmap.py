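"""Reading and writing HapMap phase-3 style genotype files and result tables.

HapMap phase 3 genotype files are whitespace-delimited text: a header line
whose first columns are ``rs# alleles chrom pos strand`` followed by a fixed
number of metadata columns (assembly, center, protLSID, assayLSID, panelLSID,
QCcode) and then one column per individual; each subsequent line is one SNP,
with genotypes as two-letter strings over {A,C,G,T,N} ("NN" = missing).

Only autosomes (1..22) are retained: the heredity of X/Y/MT sites does not
follow the diploid random-mating model the screen assumes, so such rows are
dropped at read time with a logged warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: autosome labels accepted after stripping a leading "chr"
AUTOSOMES = frozenset(str(i) for i in range(1, 23))

#: number of leading non-individual columns in a phase-3 genotype file
#: (rs#, alleles, chrom, pos, strand, assembly#, center, protLSID, assayLSID,
#: panelLSID, QCcode)
HAPMAP_HEADER_COLS = 11

_CALL_RE = re.compile(r"^[ACGTN]{2}$")
_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SNPMeta:
    """Identity and coordinates of one SNP.

    ``alleles`` is an ordered pair; after harmonization the order is
    (major, minor). Coordinates are 1-based, as in HapMap files.
    """

    rsid: str
    chrom: str
    pos: int
    alleles: tuple[str, str]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if len(self.alleles) != 2 or not set(self.alleles) <= _NUCLEOTIDES:
            raise ValueError(f"{self.rsid}: invalid allele pair {self.alleles!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.rsid}: invalid strand {self.strand!r}")


@dataclass
class GenotypeTable:
    """One population's genotype calls for a set of SNPs.

    ``calls[k][m]`` is the two-letter genotype of individual ``m`` at SNP
    ``k``; any call containing 'N' is treated as fully missing downstream.
    """

    population: str
    individuals: list[str]
    snps: list[SNPMeta] = field(default_factory=list)
    calls: list[list[str]] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def validate(self) -> None:
        if len(self.calls) != len(self.snps):
            raise ValueError("calls and snps length mismatch")
        for snp, row in zip(self.snps, self.calls):
            if len(row) != self.n_individuals:
                raise ValueError(
                    f"{snp.rsid}: {len(row)} calls for {self.n_individuals} individuals"
                )
            for call in row:
                if not _CALL_RE.match(call):
                    raise ValueError(f"{snp.rsid}: invalid genotype token {call!r}")


def _parse_allele_field(token: str, rsid: str) -> tuple[str, str]:
    parts = token.split("/")
    if len(parts) != 2 or not all(p in _NUCLEOTIDES for p in parts):
        raise ValueError(f"{rsid}: cannot parse allele field {token!r}")
    return (parts[0], parts[1])


def _normalize_chrom(token: str) -> str:
    return token[3:] if token.lower().startswith("chr") else token


def read_hapmap_genotypes(
    path: str | Path,
    population: str,
    header_cols: int = HAPMAP_HEADER_COLS,
) -> GenotypeTable:
    """Read one population's HapMap phase-3 genotype file.

    Parameters
    ----------
    path
        Whitespace-delimited genotype file (see module docstring).
    population
        Label attached to the returned table (e.g. "CEU").
    header_cols
        Number of leading non-individual columns; phase-3 files have 11 but
        dialects vary.

    Returns
    -------
    GenotypeTable preserving file order. Non-autosomal rows (X/Y/MT) are
    dropped with a warning. Malformed lines, invalid genotype tokens and
    duplicate rsids raise ``ValueError`` naming the line.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) < header_cols:
            raise ValueError(f"{path}: header has fewer than {header_cols} columns")
        individuals = header[header_cols:]
        n_fields = header_cols + len(individuals)

        table = GenotypeTable(population=population, individuals=individuals)
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            rsid = fields[0]
            if rsid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate rsid {rsid}")
            seen.add(rsid)
            chrom = _normalize_chrom(fields[2])
            if chrom not in AUTOSOMES:
                logger.warning(
                    "%s:%d: dropping %s on non-autosome %s", path, lineno, rsid, chrom
                )
                continue
            calls = fields[header_cols:]
            for call in calls:
                if not _CALL_RE.match(call):
                    raise ValueError(
                        f"{path}:{lineno}: invalid genotype token {call!r}"
                    )
            table.snps.append(
                SNPMeta(
                    rsid=rsid,
                    chrom=chrom,
                    pos=int(fields[3]),
                    alleles=_parse_allele_field(fields[1], rsid),
                    strand=fields[4],
                )
            )
            table.calls.append(calls)
    return table


def write_hapmap_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write a GenotypeTable in the phase-3 dialect (metadata columns as '-')."""
    path = Path(path)
    meta_cols = ["assembly#", "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]
    with path.open("w") as fh:
        fh.write(" ".join(["rs#", "alleles", "chrom", "pos", "strand"] + meta_cols
                          + table.individuals) + "\n")
        for snp, row in zip(table.snps, table.calls):
            fh.write(" ".join(
                [snp.rsid, f"{snp.alleles[0]}/{snp.alleles[1]}", snp.chrom,
                 str(snp.pos), snp.strand] + ["-"] * 6 + list(row)) + "\n")


def read_matrix_tsv(path: str | Path) -> GenotypeTable:
    """Read the simple TSV genotype-matrix format.

    Columns: rsid, chrom, pos, alleles ("A/C"), strand, then one genotype
    per individual; header row carries the individual IDs. Empty cells are
    read as "NN".
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["rsid", "chrom", "pos", "alleles", "strand"]:
            raise ValueError(f"{path}: unexpected matrix header {header[:5]}")
        individuals = header[5:]
        population = ""
        table = GenotypeTable(population=population, individuals=individuals)
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5 + len(individuals):
                raise ValueError(
                    f"{path}:{lineno}: expected {5 + len(individuals)} fields, "
                    f"got {len(fields)}"
                )
            rsid = fields[0]
            if rsid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate rsid {rsid}")
            seen.add(rsid)
            chrom = _normalize_chrom(fields[1])
            if chrom not in AUTOSOMES:
                logger.warning(
                    "%s:%d: dropping %s on non-autosome %s", path, lineno, rsid, chrom
                )
                continue
            calls = ["NN" if c == "" else c for c in fields[5:]]
            for call in calls:
                if not _CALL_RE.match(call):
                    raise ValueError(
                        f"{path}:{lineno}: invalid genotype token {call!r}"
                    )
            table.snps.append(
                SNPMeta(rsid, chrom, int(fields[2]),
                        _parse_allele_field(fields[3], rsid), fields[4])
            )
            table.calls.append(calls)
    return table


def write_matrix_tsv(table: GenotypeTable, path: str | Path) -> None:
    """Write the TSV genotype-matrix format (inverse of :func:`read_matrix_tsv`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["rsid", "chrom", "pos", "alleles", "strand"]
                           + table.individuals) + "\n")
        for snp, row in zip(table.snps, table.calls):
            fh.write("\t".join(
                [snp.rsid, snp.chrom, str(snp.pos),
                 f"{snp.alleles[0]}/{snp.alleles[1]}", snp.strand] + list(row)) + "\n")


RESULT_COLUMNS = [
    "chrom", "rsid", "pos", "alleles", "tested_genotype",
    "per_pop_expected", "log10_p_value", "p_value",
    "k_tested", "threshold", "flagged",
]


def _sci(x: float) -> str:
    """Render a probability in 3-significant-digit scientific notation
    (e.g. 3.051e-16 -> "3.05E-16")."""
    return f"{x:.2E}"


def write_results(results: Iterable, path: str | Path) -> None:
    """Write TestResults as a TSV (header always written).

    ``per_pop_expected`` packs the per-population expected counts of the
    tested genotype class as ``POP=count`` pairs joined by ';'.
    """
    import math

    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            exp = ";".join(
                f"{pop}={e:.2f}" for pop, e in zip(r.populations, r.per_pop_expectation)
            )
            log10p = r.log_p_value / math.log(10.0)
            fh.write("\t".join([
                r.snp.chrom, r.snp.rsid, str(r.snp.pos),
                f"{r.snp.alleles[0]}/{r.snp.alleles[1]}", r.genotype,
                exp, f"{log10p:.4f}", _sci(r.p_value),
                str(r.k_tested),
                _sci(r.threshold) if r.threshold == r.threshold else "NaN",
                str(bool(r.flagged)),
            ]) + "\n")


def write_qc(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write per-SNP drop reasons (rsid, reason) as a QC TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("rsid\treason\n")
        for rsid, reason in records:
            fh.write(f"{rsid}\t{reason}\n")
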