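"""Synthetic multi-population genotype panels with optional lethal selection.

The generator emulates the structure of the HapMap phase-3 panel: 11
populations totalling 1417 individuals (the default sizes below), one
genotype file per population, bi-allelic autosomal SNPs, genotypes drawn at
Hardy–Weinberg proportions from per-population minor-allele frequencies,
optional genotype-specific viability selection, and independent missingness.

Viability selection models the screen's premise that sampled individuals
are living adults: a drawn individual of the lethal class survives with
probability ``s`` and non-survivors are redrawn, so exactly ``size``
survivors are emitted per population (ascertainment by survival, not
thinning). With ``s = 0`` the lethal class is therefore absent from every
emitted sample while the surviving classes keep their conditional
frequencies.

Randomness uses numpy's Generator (PCG64); a SimConfig seed fully
determines the output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .hapmap import GenotypeTable, SNPMeta
from .screen import ScanSummary, scan_chromosome

#: the 11 HapMap phase-3 populations and their panel sizes (1417 in total)
HAPMAP_PANEL: tuple[tuple[str, int], ...] = (
    ("ASW", 87), ("CEU", 174), ("CHB", 139), ("CHD", 109), ("GIH", 101),
    ("JPT", 116), ("LWK", 110), ("MEX", 86), ("MKK", 184), ("TSI", 102),
    ("YRI", 209),
)

_NUCLEOTIDES = np.array(list("ACGT"))
_MAX_REDRAWS = 10_000


@dataclass
class SimConfig:
    """Full specification of a synthetic multi-population panel.

    ``maf`` is either a single minor-allele frequency applied everywhere
    or a (low, high) range sampled independently per population per SNP;
    frequencies are capped at 0.5 so the first allele is the pooled major
    allele in expectation. ``lethal_snps`` maps a SNP index to its lethal
    genotype class (0, 1 or 2) and the survival probability ``s`` of that
    class (s = 0: fully lethal; s = 1: neutral).
    """

    populations: Sequence[tuple[str, int]] = HAPMAP_PANEL
    n_snps: int = 100
    maf: float | tuple[float, float] = (0.05, 0.5)
    lethal_snps: dict[int, tuple[int, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.populations = tuple(
            (str(lab), int(size)) for lab, size in self.populations
        )
        if isinstance(self.maf, list):
            self.maf = tuple(self.maf)

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("at least one population is required")
        labels = [lab for lab, _ in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        for lab, size in self.populations:
            if size < 1:
                raise ValueError(f"population {lab}: size must be >= 1")
        if self.n_snps < 0:
            raise ValueError("n_snps must be >= 0")
        lo, hi = self.maf if isinstance(self.maf, tuple) else (self.maf, self.maf)
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError(f"maf must lie in [0, 0.5], got {self.maf}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        for idx, (cls, s) in self.lethal_snps.items():
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"lethal SNP index {idx} out of range")
            if cls not in (0, 1, 2):
                raise ValueError(f"lethal class must be 0, 1 or 2, got {cls}")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"survival_prob must be in [0, 1], got {s}")

    @property
    def total_individuals(self) -> int:
        return sum(size for _, size in self.populations)

    def to_dict(self) -> dict:
        return {
            "populations": [[lab, int(size)] for lab, size in self.populations],
            "n_snps": int(self.n_snps),
            "maf": list(self.maf) if isinstance(self.maf, tuple) else float(self.maf),
            "lethal_snps": [
                {"snp": int(i), "class": int(c), "survival": float(s)}
                for i, (c, s) in sorted(self.lethal_snps.items())
            ],
            "missing_rate": float(self.missing_rate),
            "seed": int(self.seed),
            "chrom": self.chrom,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        maf = d.get("maf", (0.05, 0.5))
        if isinstance(maf, (list, tuple)):
            maf = tuple(float(x) for x in maf)
        lethal = {
            int(e["snp"]): (int(e["class"]), float(e.get("survival", 0.0)))
            for e in d.get("lethal_snps", [])
        }
        if len(lethal) != len(d.get("lethal_snps", [])):
            raise ValueError("duplicate SNP indices in lethal_snps")
        cfg = cls(
            populations=[tuple(p) for p in d.get("populations", HAPMAP_PANEL)],
            n_snps=int(d.get("n_snps", 100)),
            maf=maf,
            lethal_snps=lethal,
            missing_rate=float(d.get("missing_rate", 0.0)),
            seed=int(d.get("seed", 0)),
            chrom=str(d.get("chrom", "1")),
        )
        cfg.validate()
        return cfg


def _genotype_codes(
    q: np.ndarray, size: int, lethal: dict[int, tuple[int, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (n_snps, size) genotype codes 0/1/2 at HWE proportions with
    per-SNP viability selection by rejection."""
    n_snps = q.shape[0]
    p0 = (1.0 - q) ** 2
    p1 = 2.0 * q * (1.0 - q)
    cum1 = p0 + p1
    u = rng.random((n_snps, size))
    codes = (u >= p0[:, None]).astype(np.int8) + (u >= cum1[:, None])

    for idx, (cls, s) in lethal.items():
        p_cls = (p0[idx], p1[idx], (q[idx] ** 2))[cls]
        p_survive = 1.0 - p_cls * (1.0 - s)
        if p_survive <= 0.0:
            raise ValueError(
                f"SNP {idx}: no surviving genotype (class {cls}, s={s}, "
                f"q={q[idx]})"
            )
        row = codes[idx]
        # each individual faces the survival lottery exactly once per draw
        pending = np.arange(size)
        for _ in range(_MAX_REDRAWS):
            hit = row[pending] == cls
            if s > 0.0 and hit.any():
                hit &= rng.random(pending.size) >= s
            dead = pending[hit]
            if dead.size == 0:
                break
            u2 = rng.random(dead.size)
            row[dead] = (u2 >= p0[idx]).astype(np.int8) + (u2 >= cum1[idx])
            pending = dead
        else:
            raise ValueError(f"SNP {idx}: rejection sampling did not converge")
    return codes


def simulate_population(
    label: str,
    size: int,
    q: np.ndarray,
    snps: Sequence[SNPMeta],
    lethal: dict[int, tuple[int, float]],
    missing_rate: float,
    rng: np.random.Generator,
) -> GenotypeTable:
    """Simulate one population's genotype table.

    ``q[k]`` is the minor-allele frequency of SNP ``k`` in this population;
    genotypes are drawn with probabilities [(1−q)², 2q(1−q), q²] over
    (major-hom, het, minor-hom), lethal classes are rejected to survival,
    and each emitted call is masked to "NN" independently with probability
    ``missing_rate``.
    """
    q = np.asarray(q, dtype=float)
    n_snps = len(snps)
    codes = _genotype_codes(q, size, lethal, rng)
    if missing_rate > 0.0:
        codes[rng.random((n_snps, size)) < missing_rate] = 3

    lut = np.empty((max(n_snps, 1), 4), dtype="<U2")
    for k, snp in enumerate(snps):
        a, b = snp.alleles
        lut[k] = (a + a, a + b, b + b, "NN")
    calls = lut[np.arange(n_snps)[:, None], codes].tolist() if n_snps else []

    return GenotypeTable(
        population=label,
        individuals=[f"{label}{i + 1:04d}" for i in range(size)],
        snps=list(snps),
        calls=calls,
    )


def generate_panel(
    config: SimConfig,
) -> tuple[list[GenotypeTable], pd.DataFrame]:
    """Generate one table per population plus a truth table.

    Deterministic given ``config.seed``. The truth table records, per SNP,
    the simulated per-population minor-allele frequency, the lethal class
    (-1 if none) and its survival probability.
    """
    config.validate()
    master = np.random.default_rng(config.seed)
    n = config.n_snps
    n_pops = len(config.populations)

    allele_idx = np.array(
        [master.choice(4, size=2, replace=False) for _ in range(n)], dtype=int
    ).reshape(n, 2)
    snps = [
        SNPMeta(
            rsid=f"rs{k + 1:06d}",
            chrom=config.chrom,
            pos=1000 * (k + 1),
            alleles=(str(_NUCLEOTIDES[allele_idx[k, 0]]),
                     str(_NUCLEOTIDES[allele_idx[k, 1]])),
        )
        for k in range(n)
    ]

    if isinstance(config.maf, tuple):
        lo, hi = config.maf
        q = master.uniform(lo, hi, size=(n_pops, n))
    else:
        q = np.full((n_pops, n), float(config.maf))

    pop_seeds = master.integers(0, 2**31, size=n_pops)
    tables = []
    for j, (label, size) in enumerate(config.populations):
        rng = np.random.default_rng(pop_seeds[j])
        tables.append(
            simulate_population(label, size, q[j], snps, config.lethal_snps,
                                config.missing_rate, rng)
        )

    truth = pd.DataFrame({
        "rsid": [s.rsid for s in snps],
        "chrom": [s.chrom for s in snps],
        "pos": [s.pos for s in snps],
        "major": [s.alleles[0] for s in snps],
        "minor": [s.alleles[1] for s in snps],
        "lethal_class": [config.lethal_snps.get(k, (-1, 1.0))[0] for k in range(n)],
        "survival_prob": [config.lethal_snps.get(k, (-1, 1.0))[1] for k in range(n)],
    })
    for j, (label, _) in enumerate(config.populations):
        truth[f"q_{label}"] = q[j]
    return tables, truth


def _replicate_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)


def run_null_simulation(
    config: SimConfig, alpha: float = 0.05, reps: int = 50
) -> dict:
    """Empirical family-wise error rate of the screen on null panels.

    Runs the chromosome scan on ``reps`` independently seeded panels with
    no lethal SNPs and reports the fraction of replicates with at least
    one flag (FWER) and the flag rate per (SNP, class) hypothesis.
    """
    config.validate()
    if config.lethal_snps:
        raise ValueError("null simulation requires a config without lethal SNPs")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = [_replicate_seed(config.seed, r) for r in range(reps)]
    flags_per_rep: list[int] = []
    n_hypotheses = 0
    for s in seeds:
        summary = scan_chromosome(generate_panel(replace(config, seed=s))[0],
                                  alpha=alpha)
        flags_per_rep.append(summary.n_flagged_pairs)
        n_hypotheses += summary.n_hypotheses
    return {
        "reps": reps,
        "alpha": alpha,
        "seeds": seeds,
        "flags_per_rep": flags_per_rep,
        "fwer": sum(f > 0 for f in flags_per_rep) / reps,
        "per_test_rate": (sum(flags_per_rep) / n_hypotheses
                          if n_hypotheses else 0.0),
    }


def run_power_simulation(
    config: SimConfig, alpha: float = 0.05, reps: int = 20
) -> dict:
    """Detection rate of planted lethal SNPs over replicate panels.

    Reports, per planted SNP index, the fraction of replicates in which
    (SNP, planted class) is flagged, and the combined p-values of the
    planted class in the replicates where its absence event occurred
    (NaN when the class was observed somewhere).
    """
    config.validate()
    if not config.lethal_snps:
        raise ValueError("power simulation requires at least one lethal SNP")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = [_replicate_seed(config.seed, r) for r in range(reps)]
    planted = {f"rs{idx + 1:06d}": (idx, cls)
               for idx, (cls, _) in config.lethal_snps.items()}
    detected = {rsid: 0 for rsid in planted}
    p_values: dict[str, list[float]] = {rsid: [] for rsid in planted}
    for s in seeds:
        summary = scan_chromosome(generate_panel(replace(config, seed=s))[0],
                                  alpha=alpha)
        tested = {(r.snp.rsid, r.genotype_class): r for r in summary.tested}
        for rsid, (idx, cls) in planted.items():
            r = tested.get((rsid, cls))
            if r is not None and r.flagged:
                detected[rsid] += 1
            p_values[rsid].append(r.p_value if r is not None else float("nan"))
    return {
        "reps": reps,
        "alpha": alpha,
        "seeds": seeds,
        "detection_rate": {rsid: detected[rsid] / reps for rsid in planted},
        "p_values": p_values,
    }
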