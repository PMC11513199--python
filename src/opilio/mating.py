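"""Minimum-mates estimation from pooled seminal-receptacle alleles.

A female snow crab stores ejaculate from every mating in her paired
seminal receptacles, so the distinct non-female microsatellite alleles in
receptacle contents bound the number of males she has mated with from
below. The estimator assumes males are heterozygous and share no alleles
with each other or the female, so it can only undercount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import (
    FemaleRecord,
    Genotype,
    MateCountEstimate,
    NoDataError,
    ReceptacleSample,
    pooled_alleles,
)
from . import stats as _stats
from .species import classify_receptacle_its, female_interspecies_evidence

__all__ = [
    "screen_females",
    "pool_and_subtract",
    "min_mates",
    "estimate_mates",
    "layers_vs_mates",
    "interspecies_summary",
]


def screen_females(
    females: Sequence[FemaleRecord], min_loci: int = 2
) -> tuple[list[FemaleRecord], dict[str, str]]:
    """Keep females whose every receptacle sample scored >= ``min_loci`` markers.

    Genotypes from each content subsample are determined independently, so
    a single badly scored subsample can distort the pooled allele set; the
    screen therefore requires all of a female's subsamples to be usable.
    Returns the eligible subset and a per-female exclusion-reason log.
    """
    kept: list[FemaleRecord] = []
    excluded: dict[str, str] = {}
    for fem in females:
        if not fem.samples:
            excluded[fem.female_id] = "empty receptacle"
            continue
        bad = [s for s in fem.samples if len(s.scored_loci()) < min_loci]
        if bad:
            excluded[fem.female_id] = (
                f"{len(bad)} sample(s) scored at fewer than {min_loci} markers"
            )
            continue
        kept.append(fem)
    return kept, excluded


@dataclass(frozen=True)
class MatePool:
    """Pooled per-locus allele evidence after female-allele subtraction."""

    detected: Mapping[str, frozenset[int]]
    nonfemale: Mapping[str, Optional[frozenset[int]]]  # None when female genotype unknown
    counts: Mapping[str, int]


def pool_and_subtract(
    samples: Sequence[ReceptacleSample],
    female_genotype: Mapping[str, Genotype],
    loci: Optional[Sequence[str]] = None,
) -> MatePool:
    """Pool subsample detections per locus and remove female contamination.

    Female epithelial tissue lines the receptacle, so her alleles appear in
    most content samples. Where her genotype is known her (at most two)
    allele labels are removed from the pooled set; where unknown, the
    distinct-allele count is reduced by two, floored at zero. Loci scored
    in no subsample are left undefined (absent from ``counts``).
    """
    if loci is None:
        seen: list[str] = []
        for s in samples:
            for l in s.alleles:
                if l not in seen:
                    seen.append(l)
        loci = seen
    detected: dict[str, frozenset[int]] = {}
    nonfemale: dict[str, Optional[frozenset[int]]] = {}
    counts: dict[str, int] = {}
    for locus in loci:
        pool = pooled_alleles(samples, locus)
        if pool is None:
            continue
        detected[locus] = pool
        own = female_genotype.get(locus)
        if own is not None:
            remaining = pool - frozenset(own)
            nonfemale[locus] = remaining
            counts[locus] = len(remaining)
        else:
            nonfemale[locus] = None
            counts[locus] = max(len(pool) - 2, 0)
    return MatePool(detected=detected, nonfemale=nonfemale, counts=counts)


def min_mates(counts: Mapping[str, int]) -> MateCountEstimate:
    """Minimum number of mates from per-locus non-female allele counts.

    The supported count is the largest number of non-female alleles
    corroborated by two or more markers, i.e. the second-largest per-locus
    count, and the estimate is half of it rounded up. With fewer than two
    defined loci the estimate is flagged unsupported.
    """
    vals = sorted(counts.values(), reverse=True)
    if len(vals) < 2:
        return MateCountEstimate(dict(counts), None, None, unsupported=True)
    supported = vals[1]
    return MateCountEstimate(dict(counts), supported, math.ceil(supported / 2))


def estimate_mates(
    female: FemaleRecord, loci: Optional[Sequence[str]] = None
) -> tuple[MateCountEstimate, MatePool]:
    """Convenience wrapper: pool, subtract, and count for one female."""
    if not female.samples:
        raise NoDataError(f"female {female.female_id} has no receptacle samples")
    pool = pool_and_subtract(female.samples, female.genotype, loci)
    return min_mates(pool.counts), pool


# ---------------------------------------------------------------------------
# Ejaculate layers as a proxy for mates

@dataclass(frozen=True)
class LayerComparison:
    crosstab: pd.DataFrame
    concordance: float
    single_layer_excess: float  # P(min_mates > 1 | 1 layer)
    two_layer_deficit: float  # P(min_mates < 2 | 2 layers)
    n_layer_known: int


def layers_vs_mates(records: pd.DataFrame) -> LayerComparison:
    """Cross-tabulate minimum mates against ejaculate-layer counts.

    ``records`` needs integer column ``min_mates`` and nullable column
    ``n_layers`` (layer counts come from the contralateral receptacle and
    are unavailable for some females; those fall in an ``NA`` column and
    are excluded from the concordance denominator).
    """
    df = records.copy()
    layers = df["n_layers"].astype("object").where(df["n_layers"].notna(), "NA")
    layers = layers.map(lambda v: v if v == "NA" else int(v))
    tab = pd.crosstab(df["min_mates"], layers)
    tab.index.name = "min_mates"
    tab.columns.name = "n_layers"
    known = df[df["n_layers"].notna()]
    n_known = len(known)
    if n_known == 0:
        raise NoDataError("no females with known layer counts")
    conc = float((known["min_mates"] == known["n_layers"]).mean())
    one = known[known["n_layers"] == 1]
    two = known[known["n_layers"] == 2]
    excess = float((one["min_mates"] > 1).mean()) if len(one) else float("nan")
    deficit = float((two["min_mates"] < 2).mean()) if len(two) else float("nan")
    return LayerComparison(tab, conc, excess, deficit, n_known)


# ---------------------------------------------------------------------------
# Interspecies mating evidence

@dataclass
class InterspeciesSummary:
    n_females: int
    n_flagged: int
    rate: float
    by_stage: pd.DataFrame
    by_area: pd.DataFrame
    by_fresh: pd.DataFrame
    p_stage: float
    p_area: float
    p_fresh: float
    warnings: list[str] = field(default_factory=list)


def interspecies_evidence(female: FemaleRecord) -> bool:
    """Does any of this female's receptacle samples indicate a congener mate?"""
    calls = [classify_receptacle_its(s.snp.its) for s in female.samples]
    return female_interspecies_evidence(calls)


def interspecies_summary(females: Sequence[FemaleRecord]) -> InterspeciesSummary:
    """Interspecies-mating counts with chi-square tests by stratum.

    Tests the occurrence of interspecies evidence across life-history
    stages, across collection area (southeast versus elsewhere, where
    Tanner crab overlap is concentrated), and by presence of fresh
    ejaculate. Falls back to Fisher's exact test with a warning when an
    expected cell count drops below 1.
    """
    rows = []
    for fem in females:
        calls = [classify_receptacle_its(s.snp.its) for s in fem.samples]
        if all(c == "error" for c in calls):
            continue  # genotyping error across all samples
        rows.append(
            {
                "female_id": fem.female_id,
                "stage": fem.stage,
                "area": fem.area,
                "fresh": fem.fresh_ejaculate,
                "flagged": female_interspecies_evidence(calls),
            }
        )
    if not rows:
        raise NoDataError("no females with scored receptacle SNPs")
    df = pd.DataFrame(rows)
    warnings: list[str] = []

    def crosstab_p(col: str, transform=None) -> tuple[pd.DataFrame, float]:
        sub = df[df[col].notna()]
        labels = sub[col] if transform is None else sub[col].map(transform)
        tab = pd.crosstab(labels, sub["flagged"])
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            return tab, float("nan")
        res = _stats.chi_square_test(tab.to_numpy())
        if res.low_expected:
            warnings.append(f"low expected counts in {col} table; exact test used")
        return tab, res.p_value

    by_stage, p_stage = crosstab_p("stage")
    by_area, p_area = crosstab_p("area", lambda a: "SE" if a == "SE" else "other")
    by_fresh, p_fresh = crosstab_p("fresh")
    return InterspeciesSummary(
        n_females=len(df),
        n_flagged=int(df["flagged"].sum()),
        rate=float(df["flagged"].mean()),
        by_stage=by_stage,
        by_area=by_area,
        by_fresh=by_fresh,
        p_stage=p_stage,
        p_area=p_area,
        p_fresh=p_fresh,
        warnings=warnings,
    )
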