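"""Long-format TSV readers/writers and GenePop export.

All tabular interchange uses tab-separated text with one fact per row:
genotypes as ``individual_id, locus, allele1, allele2`` (blank = null),
receptacle detections as one row per detected allele, embryos like
genotypes plus an ITS call. pandas does the parsing; this module only
fixes the schemas and assembles the in-memory records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    EmbryoRecord,
    FemaleRecord,
    Genotype,
    ReceptacleSample,
    SnpCall,
    ValidationError,
    genotype,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_receptacle_samples",
    "write_receptacle_samples",
    "read_embryos",
    "read_snp_calls",
    "read_metadata",
    "assemble_females",
    "to_genepop",
]


def _require(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValidationError(f"{what} table missing columns: {sorted(missing)}")


def read_genotypes(path: str | Path) -> dict[str, dict[str, Genotype]]:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "locus": str})
    _require(df, ["individual_id", "locus", "allele1", "allele2"], "genotype")
    out: dict[str, dict[str, Genotype]] = {}
    for row in df.itertuples(index=False):
        g: Genotype
        if pd.isna(row.allele1) or pd.isna(row.allele2):
            g = None
        else:
            g = genotype(int(row.allele1), int(row.allele2))
        out.setdefault(row.individual_id, {})[row.locus] = g
    return out


def write_genotypes(
    genotypes: Mapping[str, Mapping[str, Genotype]], path: str | Path
) -> None:
    rows = []
    for ind, per_locus in genotypes.items():
        for locus, g in per_locus.items():
            rows.append(
                {
                    "individual_id": ind,
                    "locus": locus,
                    "allele1": "" if g is None else g[0],
                    "allele2": "" if g is None else g[1],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_receptacle_samples(path: str | Path) -> dict[str, list[ReceptacleSample]]:
    df = pd.read_csv(path, sep="\t", dtype={"female_id": str, "locus": str})
    _require(
        df,
        ["female_id", "sample_position", "layer_age", "locus", "allele", "its_call"],
        "receptacle sample",
    )
    out: dict[str, list[ReceptacleSample]] = {}
    keys = ["female_id", "sample_position", "layer_age"]
    for (fid, pos, age), grp in df.groupby(keys, sort=False):
        alleles: dict[str, frozenset[int]] = {}
        for locus, sub in grp.groupby("locus", sort=False):
            found = frozenset(int(a) for a in sub["allele"].dropna())
            if found:
                alleles[locus] = found
        its = grp["its_call"].dropna().unique()
        snp = SnpCall(its=its[0] if len(its) else None)
        out.setdefault(fid, []).append(
            ReceptacleSample(
                female_id=fid,
                alleles=alleles,
                snp=snp,
                position=pos,
                layer_age=age,
            )
        )
    return out


def write_receptacle_samples(
    females: Sequence[FemaleRecord], path: str | Path
) -> None:
    rows = []
    for fem in females:
        for s in fem.samples:
            loci = sorted(s.alleles) or [""]
            for locus in loci:
                alleles = sorted(s.alleles.get(locus, ())) or [None]
                for a in alleles:
                    rows.append(
                        {
                            "female_id": fem.female_id,
                            "sample_position": s.position,
                            "layer_age": s.layer_age,
                            "locus": locus,
                            "allele": "" if a is None else a,
                            "its_call": s.snp.its or "",
                        }
                    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_embryos(path: str | Path) -> dict[str, list[EmbryoRecord]]:
    df = pd.read_csv(
        path, sep="\t", dtype={"female_id": str, "embryo_id": str, "locus": str}
    )
    _require(
        df, ["female_id", "embryo_id", "locus", "allele1", "allele2"], "embryo"
    )
    out: dict[str, list[EmbryoRecord]] = {}
    for (fid, eid), grp in df.groupby(["female_id", "embryo_id"], sort=False):
        geno: dict[str, Genotype] = {}
        for row in grp.itertuples(index=False):
            if pd.isna(row.allele1) or pd.isna(row.allele2):
                geno[row.locus] = None
            else:
                geno[row.locus] = genotype(int(row.allele1), int(row.allele2))
        its = None
        if "its_call" in grp.columns:
            vals = grp["its_call"].dropna().unique()
            its = vals[0] if len(vals) else None
        out.setdefault(fid, []).append(EmbryoRecord(fid, eid, geno, its))
    return out


def read_snp_calls(path: str | Path) -> dict[str, SnpCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require(df, ["individual_id", "its_call", "s16_call"], "SNP")
    out = {}
    for row in df.itertuples(index=False):
        its = None if pd.isna(row.its_call) else row.its_call
        s16 = None if pd.isna(row.s16_call) else row.s16_call
        out[row.individual_id] = SnpCall(its=its, s16=s16)
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"female_id": str})
    _require(df, ["female_id"], "metadata")
    return df


def assemble_females(
    metadata: pd.DataFrame,
    genotypes: Optional[Mapping[str, Mapping[str, Genotype]]] = None,
    samples: Optional[Mapping[str, list[ReceptacleSample]]] = None,
    embryos: Optional[Mapping[str, list[EmbryoRecord]]] = None,
) -> list[FemaleRecord]:
    """Join the long tables into FemaleRecords keyed by female_id."""
    out = []
    for row in metadata.itertuples(index=False):
        d = row._asdict()
        fid = d["female_id"]

        def get(key, cast=None):
            v = d.get(key)
            if v is None or (isinstance(v, float) and pd.isna(v)):
                return None
            return cast(v) if cast else v

        out.append(
            FemaleRecord(
                female_id=fid,
                stage=get("stage"),
                area=get("area"),
                year=get("year", int),
                putative_species=get("putative_species"),
                genotype=dict((genotypes or {}).get(fid, {})),
                clutch_fullness=get("clutch_fullness", int),
                receptacle_load=get("receptacle_load", float),
                n_layers=get("n_layers", int),
                fresh_ejaculate=get("fresh_ejaculate", bool),
                samples=list((samples or {}).get(fid, [])),
                embryos=list((embryos or {}).get(fid, [])),
            )
        )
    return out


def to_genepop(
    genotypes: Mapping[str, Mapping[str, Genotype]],
    loci: Sequence[str],
    path: str | Path,
    title: str = "opilio export",
    digits: int = 3,
) -> None:
    """GenePop flat file (one population, 2- or 3-digit allele codes).

    Microsatellite fragment sizes are used directly as allele codes, so
    they must fit the requested digit width; ``000`` encodes a null.
    """
    if digits not in (2, 3):
        raise ValidationError("GenePop allele codes are 2 or 3 digits")
    lines = [title]
    lines.extend(loci)
    lines.append("POP")
    for ind, per_locus in genotypes.items():
        fields = []
        for locus in loci:
            g = per_locus.get(locus)
            if g is None:
                fields.append("0" * digits * 2)
            else:
                for a in g:
                    if a >= 10**digits:
                        raise ValidationError(
                            f"allele {a} at {locus} does not fit {digits} digits"
                        )
                fields.append(f"{g[0]:0{digits}d}{g[1]:0{digits}d}")
        lines.append(f"{ind}, " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")
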