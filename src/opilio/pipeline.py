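"""Study-level orchestration: run every stage and emit table-style reports.

``analyze_mating_study`` and ``analyze_paternity_study`` take assembled
female records and produce the per-female result frames the summary
tables are built from; ``run_pipeline`` wires TSV inputs through both and
writes the report bundle (TSV tables, a machine-readable JSON, and an
exclusion log).
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as oio
from .core import Allele, FemaleRecord, NoDataError, ValidationError
from .markers import allele_frequencies, combined_exclusion, locus_summary
from .mating import (
    estimate_mates,
    interspecies_summary,
    layers_vs_mates,
    screen_females,
)
from .paternity import analyze_clutch, paternity_summary

__all__ = ["RunConfig", "analyze_mating_study", "analyze_paternity_study", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str
    genotypes: Optional[str] = None
    receptacle_samples: Optional[str] = None
    embryos: Optional[str] = None
    metadata: Optional[str] = None
    loci: Sequence[str] = ("L1", "L2", "L3")
    min_markers: int = 2
    min_embryos: int = 7
    presence_min_loci: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_markers, self.min_embryos, self.presence_min_loci) < 1:
            raise ValidationError("thresholds must be positive")


def analyze_mating_study(
    females: Sequence[FemaleRecord], min_markers: int = 2
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Minimum mates per eligible female, plus the exclusion log."""
    eligible, excluded = screen_females(females, min_markers)
    rows = []
    for fem in eligible:
        est, _pool = estimate_mates(fem)
        rows.append(
            {
                "female_id": fem.female_id,
                "stage": fem.stage,
                "area": fem.area,
                "year": fem.year,
                "min_mates": est.min_mates,
                "supported": est.supported,
                "n_layers": fem.n_layers,
                "unsupported": est.unsupported,
            }
        )
    return pd.DataFrame(rows), excluded


def analyze_paternity_study(
    females: Sequence[FemaleRecord],
    freqs: Mapping[str, Mapping[Allele, float]],
    min_embryos: int = 7,
    min_markers: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Clutch paternity and reserve status per female.

    Females with an empty seminal receptacle are kept with zero mates and
    sires recorded absent (no reserves to hold them); females whose
    receptacle samples fail the marker screen get missing mates/presence
    but still contribute their clutch's sire count.
    """
    rows = []
    details = {}
    for fem in females:
        try:
            res = analyze_clutch(fem, freqs, min_embryos=min_embryos, min_loci=min_markers)
        except NoDataError:
            continue
        details[fem.female_id] = res
        if not fem.samples:
            mates: Optional[int] = 0
            all_sires: Optional[bool] = False
        else:
            ok, _ = screen_females([fem], min_markers)
            if not ok:
                mates = None
                all_sires = None
            else:
                mates = estimate_mates(fem)[0].min_mates
                all_sires = res.all_sires_present
        rows.append(
            {
                "female_id": fem.female_id,
                "stage": fem.stage,
                "min_sires": res.min_sires,
                "min_mates": mates,
                "all_sires": all_sires,
                "n_embryos": res.n_embryos_screened,
                "dominant_contribution": res.dominant_contribution,
                "compat_1": res.compat_counts[0] if res.compat_counts else None,
                "compat_2": (
                    res.compat_counts[1]
                    if res.compat_counts and len(res.compat_counts) > 1
                    else None
                ),
                "receptacle_load": fem.receptacle_load,
                "clutch_fullness": fem.clutch_fullness,
            }
        )
    df = pd.DataFrame(rows)
    return df, details


def dual_paternity_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-clutch compatibility splits for the dual-paternity clutches."""
    dual = records[records["min_sires"] == 2].copy()
    out = dual[["female_id", "n_embryos", "compat_1", "compat_2", "dominant_contribution"]]
    return out.reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute species -> mating -> paternity and write the report bundle.

    Emits TSV tables plus ``results.json``; partial outputs are removed on
    failure so a bundle is either complete or absent. Idempotent given the
    same inputs and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"config": {"seed": config.seed, "loci": list(config.loci)}}
    try:
        genotypes = oio.read_genotypes(config.genotypes) if config.genotypes else {}
        samples = (
            oio.read_receptacle_samples(config.receptacle_samples)
            if config.receptacle_samples
            else {}
        )
        embryos = oio.read_embryos(config.embryos) if config.embryos else {}
        if not config.metadata:
            raise ValidationError("pipeline needs a metadata table")
        metadata = oio.read_metadata(config.metadata)
        if metadata.empty:
            raise ValidationError("metadata table is empty")
        females = oio.assemble_females(metadata, genotypes, samples, embryos)

        # marker panel summary from the female genotypes
        panel_rows = []
        freqs: dict[str, dict[int, float]] = {}
        for locus in config.loci:
            gs = [f.genotype.get(locus) for f in females if f.genotype]
            gs = [g for g in gs if g is not None]
            if len(gs) >= 2:
                s = locus_summary(gs, locus)
                freqs[locus] = allele_frequencies(gs, locus)
                panel_rows.append(s.__dict__)
        if panel_rows:
            panel = pd.DataFrame(panel_rows)
            p = out / "marker_summary.tsv"
            panel.to_csv(p, sep="\t", index=False)
            written.append(p)
            results["combined_exclusion"] = combined_exclusion(panel["p_excl"])

        with_samples = [f for f in females if f.samples or f.embryos]
        mates_df, excluded = analyze_mating_study(with_samples, config.min_markers)
        if not mates_df.empty:
            p = out / "min_mates.tsv"
            mates_df.to_csv(p, sep="\t", index=False)
            written.append(p)
            results["n_females_mates"] = int(len(mates_df))
            results["mates_distribution"] = (
                mates_df["min_mates"].value_counts().sort_index().to_dict()
            )
            layered = mates_df[mates_df["n_layers"].notna() | True]
            comp = layers_vs_mates(mates_df) if mates_df["n_layers"].notna().any() else None
            if comp is not None:
                p = out / "layers_vs_mates.tsv"
                comp.crosstab.to_csv(p, sep="\t")
                written.append(p)
                results["layer_concordance"] = comp.concordance
        inter = None
        if any(f.samples for f in females):
            inter = interspecies_summary([f for f in females if f.samples])
            results["interspecies_rate"] = inter.rate
            results["interspecies_n"] = inter.n_flagged
        results["exclusions"] = excluded

        if embryos and freqs:
            pat_df, _details = analyze_paternity_study(
                females, freqs, config.min_embryos, config.min_markers
            )
            if not pat_df.empty:
                p = out / "paternity.tsv"
                pat_df.to_csv(p, sep="\t", index=False)
                written.append(p)
                summary = paternity_summary(pat_df)
                p = out / "paternity_summary.tsv"
                summary.table.to_csv(p, sep="\t", index=False)
                written.append(p)
                p = out / "dual_paternity.tsv"
                dual_paternity_table(pat_df).to_csv(p, sep="\t", index=False)
                written.append(p)
                results["single_paternity_share"] = summary.single_paternity_share

        p = out / "results.json"
        with open(p, "w") as fh:
            json.dump(results, fh, indent=2, default=_jsonable)
        written.append(p)
    except Exception:
        for p in written:
            if p.exists():
                p.unlink()
        raise
    return results


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
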