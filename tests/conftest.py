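import pytest

HAPMAP_HEADER = ("rs# alleles chrom pos strand assembly# center protLSID "
                 "assayLSID panelLSID QCcode")
META = ["b36", "ctr", "p1", "a1", "pnl", "QC+"]


def hapmap_text(individuals, rows):
    """Build a HapMap phase-3 style file body.

    ``rows`` are (rsid, alleles, chrom, pos, strand, calls) tuples.
    """
    lines = [HAPMAP_HEADER + " " + " ".join(individuals)]
    for rsid, alleles, chrom, pos, strand, calls in rows:
        lines.append(" ".join([rsid, alleles, chrom, str(pos), strand]
                              + META + list(calls)))
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_hapmap(tmp_path):
    def _write(name, individuals, rows):
        path = tmp_path / name
        path.write_text(hapmap_text(individuals, rows))
        return path
    return _write


@pytest.fixture
def two_pop_tables():
    """Two small populations sharing three SNPs (one with a strand flip)."""
    from lethalscan.hapmap import GenotypeTable, SNPMeta

    snps_a = [
        SNPMeta("rs1", "1", 100, ("A", "C")),
        SNPMeta("rs2", "1", 200, ("G", "T")),
        SNPMeta("rs3", "1", 300, ("A", "G")),
    ]
    pop_a = GenotypeTable(
        population="POP1",
        individuals=[f"P1_{i}" for i in range(4)],
        snps=snps_a,
        calls=[
            ["AA", "AC", "CC", "AA"],
            ["GG", "GT", "TT", "NN"],
            ["AA", "AG", "GG", "AA"],
        ],
    )
    # rs3 is recorded on the opposite strand in POP2 (A/G -> T/C)
    snps_b = [
        SNPMeta("rs1", "1", 100, ("A", "C")),
        SNPMeta("rs2", "1", 200, ("G", "T")),
        SNPMeta("rs3", "1", 300, ("T", "C")),
    ]
    pop_b = GenotypeTable(
        population="POP2",
        individuals=[f"P2_{i}" for i in range(3)],
        snps=snps_b,
        calls=[
            ["AA", "AA", "AC"],
            ["GG", "GG", "GT"],
            ["TT", "TC", "CC"],
        ],
    )
    return [pop_a, pop_b]
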