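"""Synthetic genotype data with the statistical structure of the study system.

The generator emulates the data a sperm-reserve / paternity survey of
snow crab produces: a three-marker microsatellite panel with a dozen or so
alleles per locus but modest effective allele numbers, females who mated
with zero to four males, seminal-receptacle content pools contaminated by
female tissue (on average ~4.9 of the 6 female alleles visible), null
genotypes, occasional one-repeat-unit miscalls, skewed dual-sire clutches,
and sperm depletion removing a mate's alleles from the reserves. Truth
labels are retained throughout so estimator guarantees (e.g. that minimum
mates never exceeds true mates without genotyping error) are testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    Allele,
    EmbryoRecord,
    FemaleRecord,
    Genotype,
    ReceptacleSample,
    SnpCall,
    ValidationError,
    genotype,
)

__all__ = [
    "SimulationConfig",
    "Population",
    "FemaleTruth",
    "simulate_population",
    "simulate_matings",
    "simulate_clutch",
]


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study; defaults mirror the study conditions."""

    n_loci: int = 3
    alleles_per_locus: int = 13
    #: Dirichlet concentration for allele frequencies; ``inf`` = equifrequent.
    concentration: float = 0.5
    #: acceptable population effective-allele range (rejection sampled)
    neff_range: tuple[float, float] = (3.0, 7.0)
    repeat_unit: int = 2  # bp between adjacent allele ladder rungs
    n_males: int = 400
    n_females: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "primiparous": {"NW": 25, "CEN": 25, "SE": 25},
            "multiparous": {"NW": 25, "CEN": 25, "SE": 25},
        }
    )
    #: distribution of true mate counts per female (support 0..4)
    mates_distribution: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.59, 2: 0.32, 3: 0.035, 4: 0.005}
    )
    repeated_mating_prob: float = 0.10  # one male contributing an extra layer
    #: expected number of the 6 female alleles visible in receptacle pools
    contamination_expected: float = 4.9
    null_rate: float = 0.0  # whole-locus scoring failure probability
    miscall_rate: float = 0.0  # per-allele +/- one repeat unit
    sperm_depletion_prob: float = 0.2  # a mate's sperm fully expended
    two_sample_prob: float = 0.4  # receptacle partitioned into two subsamples
    #: probability a mate is a Tanner crab, by area
    interspecies_rate: Mapping[str, float] = field(
        default_factory=lambda: {"NW": 0.002, "CEN": 0.005, "SE": 0.03}
    )
    snp_error_rate: float = 0.01
    n_embryos: int = 20
    #: Beta(a, b) for the dominant-sire share rescaled to (0.5, 1); the
    #: defaults put the mean dominant share at 0.78.
    skew_beta: tuple[float, float] = (2.8, 2.2)

    def __post_init__(self) -> None:
        if self.alleles_per_locus < 2:
            raise ValidationError("need >= 2 alleles per locus")
        total = sum(self.mates_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("mates distribution must be normalised")
        for p in (
            self.repeated_mating_prob,
            self.null_rate,
            self.miscall_rate,
            self.sperm_depletion_prob,
            self.two_sample_prob,
            self.snp_error_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")

    @property
    def contamination_p(self) -> float:
        return self.contamination_expected / (2 * self.n_loci)


@dataclass
class Population:
    loci: list[str]
    freqs: dict[str, dict[Allele, float]]
    males: list[dict[str, Genotype]]
    male_species: list[str]


@dataclass
class FemaleTruth:
    """A simulated female plus the ground truth behind her record."""

    record: FemaleRecord
    true_mates: list[dict[str, Genotype]]
    mate_species: list[str]
    depleted: list[bool]
    true_n_mates: int


def _draw_frequencies(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    k = cfg.alleles_per_locus
    if np.isinf(cfg.concentration):
        return np.full(k, 1.0 / k)
    lo, hi = cfg.neff_range
    best = None
    for _ in range(200):
        p = rng.dirichlet(np.full(k, cfg.concentration))
        p = np.maximum(p, 1e-6)
        p = p / p.sum()
        neff = 1.0 / float((p**2).sum())
        if lo <= neff <= hi:
            return p
        score = min(abs(neff - lo), abs(neff - hi))
        if best is None or score < best[0]:
            best = (score, p)
    return best[1]  # infeasible target; closest draw


def _hwe_genotype(
    freqs: Mapping[Allele, float], rng: np.random.Generator
) -> tuple[Allele, Allele]:
    labels = list(freqs)
    p = np.array([freqs[a] for a in labels])
    i, j = rng.choice(len(labels), size=2, p=p)
    return genotype(labels[i], labels[j])


def simulate_population(cfg: SimulationConfig, seed: int = 0) -> Population:
    """Marker frequencies and a male pool with Hardy-Weinberg genotypes.

    Allele labels form a fragment-size ladder with rungs one or two repeat
    units apart, so miscall perturbation lands on plausible neighbours.
    """
    rng = np.random.default_rng(seed)
    loci = [f"L{i + 1}" for i in range(cfg.n_loci)]
    freqs: dict[str, dict[Allele, float]] = {}
    for li, locus in enumerate(loci):
        steps = rng.choice([1, 2], size=cfg.alleles_per_locus - 1)
        sizes = 100 + 50 * li + cfg.repeat_unit * np.concatenate(
            [[0], np.cumsum(steps)]
        )
        p = _draw_frequencies(cfg, rng)
        freqs[locus] = {int(a): float(q) for a, q in zip(sizes, p)}
    males = [
        {l: _hwe_genotype(freqs[l], rng) for l in loci} for _ in range(cfg.n_males)
    ]
    return Population(loci, freqs, males, ["snow"] * cfg.n_males)


def _degrade_alleles(
    alleles: set[Allele], cfg: SimulationConfig, rng: np.random.Generator
) -> set[Allele]:
    if cfg.miscall_rate <= 0:
        return alleles
    out = set()
    for a in alleles:
        if rng.random() < cfg.miscall_rate:
            out.add(a + cfg.repeat_unit * int(rng.choice([-1, 1])))
        else:
            out.add(a)
    return out


def simulate_matings(
    population: Population, cfg: SimulationConfig, seed: int = 1
) -> list[FemaleTruth]:
    """Females with true mates, receptacle content samples and layer counts.

    Receptacle pools are the union of the non-depleted mates' alleles plus
    per-allele female contamination, degraded by the null and miscall
    rates. Layer counts equal the number of contributing males plus any
    repeated matings, so layers can exceed mates.
    """
    rng = np.random.default_rng(seed)
    loci = population.loci
    mate_ks = sorted(cfg.mates_distribution)
    mate_ps = np.array([cfg.mates_distribution[k] for k in mate_ks])
    out: list[FemaleTruth] = []
    fid = 0
    for stage, by_area in cfg.n_females.items():
        for area, count in by_area.items():
            for _ in range(count):
                fid += 1
                own = {
                    l: (None if rng.random() < cfg.null_rate
                        else _hwe_genotype(population.freqs[l], rng))
                    for l in loci
                }
                k = int(rng.choice(mate_ks, p=mate_ps))
                idx = rng.choice(len(population.males), size=k, replace=False)
                tanner_p = cfg.interspecies_rate.get(area, 0.0)
                mates, species = [], []
                for i in idx:
                    if rng.random() < tanner_p:
                        # congener mate: distinct allele ladder offset keeps
                        # truth recoverable; ITS species drives detection
                        mates.append(
                            {l: _hwe_genotype(population.freqs[l], rng) for l in loci}
                        )
                        species.append("tanner")
                    else:
                        mates.append(population.males[int(i)])
                        species.append("snow")
                depleted = [bool(rng.random() < cfg.sperm_depletion_prob) for _ in mates]
                contributing = [m for m, d in zip(mates, depleted) if not d]
                contrib_species = [s for s, d in zip(species, depleted) if not d]
                extra_layers = int(
                    sum(rng.random() < cfg.repeated_mating_prob for _ in contributing)
                )
                n_layers = len(contributing) + extra_layers
                n_samples = (
                    2 if (contributing and rng.random() < cfg.two_sample_prob) else 1
                )
                # each contributing male's material lands in >= 1 subsample
                assignment = [
                    set([int(rng.integers(n_samples))])
                    | ({0, 1} if n_samples == 2 and rng.random() < 0.3 else set())
                    for _ in contributing
                ]
                samples = []
                for si in range(n_samples):
                    alleles: dict[str, frozenset[Allele]] = {}
                    males_here = [
                        m for m, a in zip(contributing, assignment) if si in a
                    ]
                    species_here = [
                        s for s, a in zip(contrib_species, assignment) if si in a
                    ]
                    for l in loci:
                        if rng.random() < cfg.null_rate:
                            continue
                        pool: set[Allele] = set()
                        for m in males_here:
                            if m[l] is not None:
                                pool |= set(m[l])
                        if own[l] is not None:
                            for a in own[l]:
                                if rng.random() < cfg.contamination_p:
                                    pool.add(a)
                        if pool:
                            alleles[l] = frozenset(_degrade_alleles(pool, cfg, rng))
                    has_tanner = "tanner" in species_here
                    has_snow = bool(species_here.count("snow")) or True  # female tissue
                    if rng.random() < cfg.snp_error_rate:
                        its = None
                    elif has_tanner and has_snow:
                        its = "C/G"
                    elif has_tanner:
                        its = "C/C"
                    else:
                        its = "G/G"
                    pos = "single" if n_samples == 1 else ("proximal", "distal")[si]
                    samples.append(
                        ReceptacleSample(
                            female_id=f"F{fid:05d}",
                            alleles=alleles,
                            snp=SnpCall(its=its, s16=None),
                            position=pos,
                            layer_age="fresh" if n_layers else "unknown",
                        )
                    )
                rec = FemaleRecord(
                    female_id=f"F{fid:05d}",
                    stage=stage,
                    area=area,
                    year=2016,
                    putative_species="snow",
                    genotype=own,
                    clutch_fullness=int(rng.integers(4, 7)),
                    receptacle_load=float(
                        rng.lognormal(0.0 if stage == "primiparous" else 0.6, 0.5)
                    ),
                    n_layers=n_layers,
                    fresh_ejaculate=n_layers > 0,
                    samples=samples if contributing or n_samples else [],
                )
                out.append(
                    FemaleTruth(
                        record=rec,
                        true_mates=mates,
                        mate_species=species,
                        depleted=depleted,
                        true_n_mates=k,
                    )
                )
    return out


def draw_skew(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Dominant-sire share for a dual clutch, mean set by ``skew_beta``."""
    a, b = cfg.skew_beta
    dom = 0.5 + 0.5 * float(rng.beta(a, b))
    return (dom, 1.0 - dom)


def simulate_clutch(
    mother: Mapping[str, Genotype],
    sires: Sequence[Mapping[str, Genotype]],
    cfg: SimulationConfig,
    seed: int = 2,
    n_embryos: Optional[int] = None,
    skew: Optional[Sequence[float]] = None,
    female_id: str = "F00000",
) -> tuple[list[EmbryoRecord], list[int]]:
    """Mendelian embryos from 1-2 sires; returns records plus true sire index."""
    if not 1 <= len(sires) <= 2:
        raise ValidationError("simulate_clutch supports 1 or 2 sires")
    rng = np.random.default_rng(seed)
    n = n_embryos if n_embryos is not None else cfg.n_embryos
    if skew is None:
        skew = (1.0,) if len(sires) == 1 else draw_skew(cfg, rng)
    phi = np.asarray(skew, dtype=float)
    if len(phi) != len(sires) or abs(phi.sum() - 1.0) > 1e-9:
        raise ValidationError("skew must be a distribution over the sires")
    embryos: list[EmbryoRecord] = []
    truth: list[int] = []
    for i in range(n):
        s = int(rng.choice(len(sires), p=phi))
        truth.append(s)
        geno: dict[str, Genotype] = {}
        for l, mg in mother.items():
            sg = sires[s].get(l)
            if mg is None or sg is None or rng.random() < cfg.null_rate:
                geno[l] = None
                continue
            mat = mg[int(rng.integers(2))]
            pat = sg[int(rng.integers(2))]
            if cfg.miscall_rate > 0:
                if rng.random() < cfg.miscall_rate:
                    mat += cfg.repeat_unit * int(rng.choice([-1, 1]))
                if rng.random() < cfg.miscall_rate:
                    pat += cfg.repeat_unit * int(rng.choice([-1, 1]))
            geno[l] = genotype(mat, pat)
        embryos.append(
            EmbryoRecord(female_id, f"{female_id}-E{i + 1:03d}", geno, its="G/G")
        )
    return embryos, truth
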