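"""Core domain types shared across the analysis modules.

Alleles are integer labels (microsatellite fragment sizes in base pairs).
A diploid genotype is an ordered pair ``(a1, a2)`` with ``a1 <= a2``;
``None`` marks a scoring failure (null genotype). Loci are addressed by
their string name throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

Allele = int
Genotype = Optional[tuple[Allele, Allele]]

#: Three-area / two-domain regional grid used for hybrid maternal-lineage
#: aggregation (areas crossed with the middle and outer shelf domains).
REGIONS = (
    "NW outer",
    "NW middle",
    "CEN outer",
    "CEN middle",
    "SE outer",
    "SE middle",
)

AREAS = ("NW", "CEN", "SE")

STAGES = ("primiparous", "multiparous")


class OpilioError(Exception):
    """Base class for package errors."""


class ValidationError(OpilioError):
    """Malformed input (bad frequencies, unknown region, schema violation)."""


class NoDataError(OpilioError):
    """An operation was asked to run on an empty or all-null input."""


def genotype(a: Allele, b: Allele) -> Genotype:
    """Normalise an allele pair into canonical sorted order."""
    return (a, b) if a <= b else (b, a)


def is_het(g: Genotype) -> bool:
    return g is not None and g[0] != g[1]


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus with an optional fixed allele universe."""

    name: str
    allele_universe: tuple[Allele, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.allele_universe)) != len(self.allele_universe):
            raise ValidationError(f"duplicate allele labels at locus {self.name}")


@dataclass(frozen=True)
class LocusSummary:
    """Per-locus informativeness statistics for a marker panel.

    ``h_exp`` is Nei's unbiased gene diversity (sample-size corrected);
    ``n_eff`` is the effective allele count ``1 / (1 - h_exp)`` computed
    from the corrected value so printed heterozygosities round-trip.
    """

    locus: str
    n: int
    n_alleles: int
    n_eff: float
    freq_max: float
    h_obs: float
    h_exp: float
    f_is: float
    p_excl: float
    monomorphic: bool = False


@dataclass(frozen=True)
class SnpCall:
    """Two-marker SNP call: nuclear ITS diplotype and mitochondrial 16S base.

    ``its`` is one of ``"C/C"``, ``"C/G"``, ``"G/G"`` or ``None``;
    ``s16`` is ``"C"``, ``"T"`` or ``None``.
    """

    its: Optional[str] = None
    s16: Optional[str] = None

    def __post_init__(self) -> None:
        if self.its not in (None, "C/C", "C/G", "G/G"):
            raise ValidationError(f"bad ITS diplotype {self.its!r}")
        if self.s16 not in (None, "C", "T"):
            raise ValidationError(f"bad 16S haplotype {self.s16!r}")


@dataclass(frozen=True)
class SpeciesCall:
    """Species and maternal-lineage determination for one crab."""

    species: str  # snow | tanner | hybrid | unresolved
    maternal_lineage: str  # snow | tanner | n/a
    mito_discordant: bool = False
    genotyping_error: bool = False


@dataclass
class ReceptacleSample:
    """Pooled allele detections from one seminal-receptacle content subsample.

    ``alleles`` maps locus name to the set of allele labels detected; a
    locus absent from the mapping was not scored (null). A pooled sample
    can legitimately show more than two alleles at a locus because it may
    contain ejaculate from several males plus female epithelial tissue.
    """

    female_id: str
    alleles: dict[str, frozenset[Allele]]
    snp: SnpCall = field(default_factory=SnpCall)
    position: str = "single"  # single | proximal | intermediate | distal
    layer_age: str = "unknown"  # fresh | old | fresh+old | unknown

    def __post_init__(self) -> None:
        if self.position not in ("single", "proximal", "intermediate", "distal"):
            raise ValidationError(f"bad sample position {self.position!r}")

    def scored_loci(self) -> set[str]:
        return set(self.alleles)


@dataclass
class EmbryoRecord:
    """One embryo's multi-locus genotype (post- or pre-screening)."""

    female_id: str
    embryo_id: str
    genotype: dict[str, Genotype]
    its: Optional[str] = None


@dataclass
class FemaleRecord:
    """A female crab with metadata, her own genotype and linked samples."""

    female_id: str
    stage: Optional[str] = None  # primiparous | multiparous
    area: Optional[str] = None  # NW | CEN | SE
    year: Optional[int] = None
    putative_species: Optional[str] = None
    species_call: Optional[SpeciesCall] = None
    genotype: dict[str, Genotype] = field(default_factory=dict)
    clutch_fullness: Optional[int] = None  # ordinal 1 (empty) .. 6 (full)
    receptacle_load: Optional[float] = None  # wet weight of contents, g
    n_layers: Optional[int] = None
    layer_ages: tuple[str, ...] = ()
    fresh_ejaculate: Optional[bool] = None
    samples: list[ReceptacleSample] = field(default_factory=list)
    embryos: list[EmbryoRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage is not None and self.stage not in STAGES:
            raise ValidationError(f"bad life-history stage {self.stage!r}")
        if self.clutch_fullness is not None and not 1 <= self.clutch_fullness <= 6:
            raise ValidationError("clutch fullness score must be in 1..6")


@dataclass(frozen=True)
class MateCountEstimate:
    """Minimum-mates estimate from pooled non-female allele counts.

    ``supported`` is the largest non-female allele count corroborated by
    at least two markers (i.e. the second-largest per-locus count) and
    ``min_mates = ceil(supported / 2)``.
    """

    per_locus: Mapping[str, int]
    supported: Optional[int]
    min_mates: Optional[int]
    unsupported: bool = False


@dataclass(frozen=True)
class SireScenario:
    """One candidate sire reconstruction for a clutch.

    ``genotypes`` holds one or two multi-locus sire genotypes as mappings
    locus -> allele pair, where the sentinel allele ``-1`` stands for an
    unobserved ("any other") second allele. ``compat_counts`` gives the
    number of screened embryos genetically compatible with each sire; an
    embryo compatible with both sires counts for both.
    """

    genotypes: tuple[Mapping[str, tuple[Allele, Allele]], ...]
    compat_counts: tuple[int, ...]
    log_likelihood: float


@dataclass
class PaternityResult:
    """Clutch-level paternity determination for one female."""

    female_id: str
    n_embryos_screened: int
    paternal_counts: dict[str, int]
    min_sires: int
    scenarios: list[SireScenario] = field(default_factory=list)
    dominant_contribution: Optional[float] = None
    compat_counts: Optional[tuple[int, ...]] = None
    sire_present: Optional[tuple[bool, ...]] = None
    all_sires_present: Optional[bool] = None
    ambiguous_top: bool = False
    flagged_three_plus: bool = False


def non_null(genotypes: Iterable[Genotype]) -> list[tuple[Allele, Allele]]:
    """Drop null genotypes (listwise per locus)."""
    return [g for g in genotypes if g is not None]


def pooled_alleles(samples: Sequence[ReceptacleSample], locus: str) -> Optional[frozenset[Allele]]:
    """Union of detected alleles at ``locus`` across subsamples.

    Returns ``None`` when no subsample scored the locus.
    """
    found = [s.alleles[locus] for s in samples if locus in s.alleles]
    if not found:
        return None
    out: frozenset[Allele] = frozenset()
    for f in found:
        out |= f
    return out
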