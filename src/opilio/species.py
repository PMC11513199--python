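"""Species, hybrid and maternal-lineage calling from two diagnostic SNPs.

Snow crab and Tanner crab are distinguished by a nuclear SNP in the rRNA
internal transcribed spacer (ITS; biparental, diplotype over C/G) and a
mitochondrial SNP in the 16S rRNA gene (maternal, haplotype over C/T).
ITS G/G indicates snow crab, C/C Tanner crab, and C/G an F1-like hybrid;
16S T indicates a snow crab maternal lineage and C a Tanner crab one.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .core import REGIONS, SnpCall, SpeciesCall, ValidationError

__all__ = [
    "call_species",
    "classify_receptacle_its",
    "regional_lineage_table",
    "concordance_summary",
]

_ITS_SPECIES = {"G/G": "snow", "C/C": "tanner", "C/G": "hybrid"}
_S16_LINEAGE = {"T": "snow", "C": "tanner"}


def call_species(snp: SnpCall) -> SpeciesCall:
    """Call species and maternal lineage for one crab.

    Species comes from the nuclear ITS diplotype. The mitochondrial 16S
    haplotype supplies the maternal lineage (decisive for hybrids, a
    consistency check for the parental species). When ITS is null the
    species is unresolved but the 16S lineage is still recorded. When both
    markers are null the crab is a genotyping-error record, to be excluded
    downstream.
    """
    if snp.its is None and snp.s16 is None:
        return SpeciesCall("unresolved", "n/a", genotyping_error=True)
    lineage = _S16_LINEAGE.get(snp.s16, "n/a") if snp.s16 else "n/a"
    if snp.its is None:
        return SpeciesCall("unresolved", lineage)
    species = _ITS_SPECIES[snp.its]
    # A pure-species ITS call with the other species' mitochondria is
    # reported from ITS with a flag (possible introgression), not an error.
    discordant = (
        species in ("snow", "tanner")
        and lineage != "n/a"
        and lineage != species
    )
    return SpeciesCall(species, lineage, mito_discordant=discordant)


def classify_receptacle_its(
    its: Optional[str], female_species: str = "snow"
) -> str:
    """Interpret the ITS diplotype of a pooled receptacle-content sample.

    For a snow crab female: G/G can only arise from conspecific material
    (her own tissue and/or snow crab mates); C/C requires a Tanner crab
    mate; C/G indicates either a hybrid mate or a mixture that includes a
    Tanner crab mate alongside snow crab material. Returns one of
    ``conspecific_only``, ``tanner_mate``, ``hybrid_or_mixture``, ``error``.
    """
    if female_species != "snow":
        raise ValidationError("receptacle ITS interpretation is defined for snow crab females")
    if its is None:
        return "error"
    return {
        "G/G": "conspecific_only",
        "C/C": "tanner_mate",
        "C/G": "hybrid_or_mixture",
    }[its]


def female_interspecies_evidence(sample_calls: Iterable[str]) -> bool:
    """A female shows interspecies-mating evidence if any sample does."""
    return any(c in ("tanner_mate", "hybrid_or_mixture") for c in sample_calls)


def regional_lineage_table(records: pd.DataFrame) -> pd.DataFrame:
    """Annual regional proportions of hybrids with a snow crab maternal lineage.

    ``records`` needs columns ``station``, ``region``, ``year``,
    ``n_hybrids``, ``prop_snow_lineage``. Station estimates are averaged
    unweighted within each region-by-year cell; cells with no sampled
    stations come out as missing (NaN), never as zero.
    """
    required = {"station", "region", "year", "n_hybrids", "prop_snow_lineage"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"lineage records missing columns: {sorted(missing)}")
    bad = set(records["region"]) - set(REGIONS)
    if bad:
        raise ValidationError(f"unknown regions: {sorted(bad)}")
    if ((records["prop_snow_lineage"] < 0) | (records["prop_snow_lineage"] > 1)).any():
        raise ValidationError("station proportions must be in [0, 1]")
    if (records["n_hybrids"] < 1).any():
        raise ValidationError("each station estimate needs >= 1 hybrid")
    table = (
        records.groupby(["region", "year"])["prop_snow_lineage"]
        .mean()
        .unstack("year")
        .reindex(list(REGIONS))
    )
    table.index.name = "region"
    return table


def regional_lineage_average(records: pd.DataFrame) -> pd.Series:
    """Multi-year regional averages: mean of the annual regional values."""
    return regional_lineage_table(records).mean(axis=1, skipna=True)


def concordance_summary(
    putative: Sequence[str], genetic: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Confusion matrix and misidentification rate of field species calls.

    Both label vectors must be aligned per crab; crabs without a successful
    genetic call should be excluded by the caller. Returns the confusion
    matrix (putative rows, genetic columns) and the discordant fraction.
    """
    if len(putative) != len(genetic):
        raise ValidationError("label vectors differ in length")
    if not putative:
        raise ValidationError("no crabs to compare")
    df = pd.DataFrame({"putative": putative, "genetic": genetic})
    matrix = pd.crosstab(df["putative"], df["genetic"])
    rate = float((df["putative"] != df["genetic"]).mean())
    return matrix, rate
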