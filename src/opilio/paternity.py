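"""Clutch paternity: embryo screening, minimum sires, sire reconstruction.

Each embryo carries one maternal and one paternal allele per locus, so
after accounting for the (known) maternal genotype the distinct paternal
alleles pooled over a clutch bound the number of sires from below:
``min_sires = ceil(max per-locus paternal count / 2)``, assuming sires are
heterozygous. For one- and two-sire clutches an exhaustive search over
candidate sire genotypes (built from the observed paternal alleles plus
"any unobserved second allele" wildcards) ranks reconstruction scenarios
by a Mendelian-transmission likelihood with Hardy-Weinberg genotype
priors, and reports per-sire embryo-compatibility counts.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    Allele,
    EmbryoRecord,
    FemaleRecord,
    Genotype,
    NoDataError,
    PaternityResult,
    SireScenario,
    ValidationError,
)
from .mating import pool_and_subtract

__all__ = [
    "OTHER_ALLELE",
    "screen_embryos",
    "assign_paternal_alleles",
    "min_sires",
    "reconstruct_sires",
    "dominant_contribution",
    "sires_in_reserves",
    "analyze_clutch",
]

#: Sentinel for a sire allele never observed among the embryos ("any other").
OTHER_ALLELE: Allele = -1


# ---------------------------------------------------------------------------
# Screening

def screen_embryos(
    embryos: Sequence[EmbryoRecord],
    mother: Mapping[str, Genotype],
    min_loci: int = 2,
) -> tuple[list[EmbryoRecord], list[tuple[str, str]]]:
    """Apply the embryo quality screen against the maternal genotype.

    Stage 1 nulls any embryo locus whose genotype shares no allele with the
    mother (treated as a scoring failure). Stage 2 keeps embryos that are
    non-null at >= ``min_loci`` markers, share a maternal allele at
    >= ``min_loci`` markers, and show at least one non-maternal allele
    overall. Returns screened copies plus an exclusion log of
    ``(embryo_id, reason)`` pairs.
    """
    known = {l for l, g in mother.items() if g is not None}
    if len(known) < min_loci:
        raise NoDataError("maternal genotype too incomplete; clutch excluded")
    kept: list[EmbryoRecord] = []
    log: list[tuple[str, str]] = []
    for emb in embryos:
        cleaned: dict[str, Genotype] = {}
        for locus, g in emb.genotype.items():
            if g is None:
                cleaned[locus] = None
                continue
            mg = mother.get(locus)
            if mg is not None and not (set(g) & set(mg)):
                cleaned[locus] = None  # maternally incompatible -> scoring failure
            else:
                cleaned[locus] = g
        nonnull = [l for l, g in cleaned.items() if g is not None]
        if len(nonnull) < min_loci:
            log.append((emb.embryo_id, "non-null at fewer than two markers"))
            continue
        shares = [
            l
            for l in nonnull
            if mother.get(l) is not None and set(cleaned[l]) & set(mother[l])
        ]
        if len(shares) < min_loci:
            log.append((emb.embryo_id, "shares a maternal allele at fewer than two markers"))
            continue
        has_nonmaternal = any(
            mother.get(l) is not None and (set(cleaned[l]) - set(mother[l]))
            for l in nonnull
        )
        if not has_nonmaternal:
            log.append((emb.embryo_id, "no non-maternal allele"))
            continue
        kept.append(
            EmbryoRecord(emb.female_id, emb.embryo_id, cleaned, emb.its)
        )
    return kept, log


# ---------------------------------------------------------------------------
# Paternal allele assignment

def assign_paternal_alleles(
    embryos: Sequence[EmbryoRecord], mother: Mapping[str, Genotype]
) -> dict[str, dict[str, Allele]]:
    """Designate one paternal allele per non-null locus for each embryo.

    A non-maternal allele is paternal; a maternal homozygote's allele is
    paternal even though it matches the mother. When the embryo equals the
    heterozygous maternal genotype either allele could be paternal; the
    ambiguity is resolved clutch-wide to minimise the distinct paternal
    allele set per locus (preserving the "minimum" semantics), breaking
    ties toward the smaller allele label.
    """
    forced: dict[str, set[Allele]] = {}
    ambiguous: dict[str, list[str]] = {}
    out: dict[str, dict[str, Allele]] = {e.embryo_id: {} for e in embryos}
    for emb in embryos:
        for locus, g in emb.genotype.items():
            if g is None:
                continue
            mg = mother.get(locus)
            if mg is None:
                continue
            mset = set(mg)
            nonmat = [a for a in g if a not in mset]
            if nonmat:
                pat = nonmat[0]
            elif g[0] == g[1]:
                pat = g[0]  # homozygous for a maternal allele
            else:
                # embryo genotype == heterozygous maternal genotype
                ambiguous.setdefault(locus, []).append(emb.embryo_id)
                continue
            out[emb.embryo_id][locus] = pat
            forced.setdefault(locus, set()).add(pat)
    for locus, emb_ids in ambiguous.items():
        choices = set(mother[locus])
        hit = sorted(choices & forced.get(locus, set()))
        pick = hit[0] if hit else min(choices)
        for eid in emb_ids:
            out[eid][locus] = pick
    return out


def paternal_allele_sets(
    assignments: Mapping[str, Mapping[str, Allele]]
) -> dict[str, set[Allele]]:
    """Distinct paternal alleles per locus, pooled across the clutch."""
    sets: dict[str, set[Allele]] = {}
    for per_locus in assignments.values():
        for locus, allele in per_locus.items():
            sets.setdefault(locus, set()).add(allele)
    return sets


def min_sires(paternal_counts: Mapping[str, int]) -> int:
    """``ceil(max per-locus distinct paternal allele count / 2)``, at least 1."""
    if not paternal_counts:
        raise NoDataError("no paternal allele counts; clutch undefined")
    return max(1, math.ceil(max(paternal_counts.values()) / 2))


# ---------------------------------------------------------------------------
# Sire genotype reconstruction (exhaustive over a candidate grammar)

def _locus_candidates(
    observed: Sequence[Allele], freqs: Mapping[Allele, float]
) -> tuple[list[tuple[Allele, Allele]], dict[Allele, float]]:
    """Candidate sire genotypes at one locus and effective allele frequencies.

    Candidates are unordered pairs over the observed paternal alleles plus
    the wildcard; a genotype of two wildcards is excluded (such a sire
    would be invisible at the locus). The wildcard's frequency is the
    residual mass not taken by the observed paternal alleles.
    """
    symbols = sorted(observed) + [OTHER_ALLELE]
    eff = {a: max(freqs.get(a, 1e-9), 1e-9) for a in observed}
    eff[OTHER_ALLELE] = max(1.0 - sum(eff.values()), 1e-9)
    cands = [
        (a, b)
        for i, a in enumerate(symbols)
        for b in symbols[i:]
        if not (a == OTHER_ALLELE and b == OTHER_ALLELE)
    ]
    return cands, eff


def _transmission(g: tuple[Allele, Allele], allele: Allele) -> float:
    if g[0] == g[1]:
        return 1.0 if g[0] == allele else 0.0
    return 0.5 if allele in g else 0.0


def reconstruct_sires(
    embryo_paternal: Mapping[str, Mapping[str, Allele]],
    freqs: Mapping[str, Mapping[Allele, float]],
    n_sires: int,
    loci: Optional[Sequence[str]] = None,
) -> list[SireScenario]:
    """Exhaustive sire-genotype search for one- or two-sire clutches.

    ``embryo_paternal`` maps embryo id -> locus -> assigned paternal allele
    (loci null for an embryo are simply absent). Every scenario must make
    each embryo compatible with at least one sire at all of its non-null
    loci, and each sire compatible with at least one embryo. Scenarios are
    scored by ``sum_e log(mean_s t_s(e)) + sum_s log HWE-prior(s)`` where
    ``t_s(e)`` is the product over the embryo's loci of the Mendelian
    transmission probability of its paternal allele, and returned sorted by
    likelihood (descending). An empty list means no scenario with
    ``n_sires`` sires exists (three or more sires required).
    """
    if n_sires not in (1, 2):
        raise ValidationError("reconstruction supports 1 or 2 sires")
    emb_ids = sorted(embryo_paternal)
    if not emb_ids:
        raise NoDataError("no embryos to reconstruct from")
    if loci is None:
        loci = sorted({l for per in embryo_paternal.values() for l in per})
    loci = [l for l in loci if any(l in embryo_paternal[e] for e in emb_ids)]
    if len(loci) > 3:
        raise ValidationError("reconstruction supports at most 3 loci")
    n_emb = len(emb_ids)

    per_locus_cands: list[list[tuple[Allele, Allele]]] = []
    per_locus_trans: list[np.ndarray] = []  # (n_cands, n_emb)
    per_locus_logprior: list[np.ndarray] = []
    observed_sets: list[set[Allele]] = []
    for locus in loci:
        observed = sorted({
            embryo_paternal[e][locus] for e in emb_ids if locus in embryo_paternal[e]
        })
        observed_sets.append(set(observed))
        cands, eff = _locus_candidates(observed, freqs.get(locus, {}))
        trans = np.ones((len(cands), n_emb))
        for ci, g in enumerate(cands):
            for ei, e in enumerate(emb_ids):
                allele = embryo_paternal[e].get(locus)
                if allele is not None:
                    trans[ci, ei] = _transmission(g, allele)
        logprior = np.array([
            math.log(eff[g[0]] ** 2 if g[0] == g[1] else 2 * eff[g[0]] * eff[g[1]])
            for g in cands
        ])
        per_locus_cands.append(cands)
        per_locus_trans.append(trans)
        per_locus_logprior.append(logprior)

    scenarios: list[SireScenario] = []
    if n_sires == 1:
        # the single sire must carry every observed paternal allele
        choices = []
        for cands, obs in zip(per_locus_cands, observed_sets):
            ok = [i for i, g in enumerate(cands) if obs <= set(g)]
            if not ok:
                return []
            choices.append(ok)
        for combo in itertools.product(*choices):
            t = np.ones(n_emb)
            logp = 0.0
            for li, ci in enumerate(combo):
                t = t * per_locus_trans[li][ci]
                logp += per_locus_logprior[li][ci]
            if (t <= 0).any():
                continue
            geno = {loci[li]: per_locus_cands[li][ci] for li, ci in enumerate(combo)}
            ll = float(np.log(t).sum() + logp)
            scenarios.append(SireScenario((geno,), (n_emb,), ll))
    else:
        # ordered pairs per locus must jointly carry every observed allele
        pair_choices = []
        for cands, obs in zip(per_locus_cands, observed_sets):
            pairs = [
                (i, j)
                for i in range(len(cands))
                for j in range(len(cands))
                if obs <= set(cands[i]) | set(cands[j])
            ]
            if not pairs:
                return []
            pair_choices.append(pairs)
        seen: set[tuple] = set()
        for combo in itertools.product(*pair_choices):
            t1 = np.ones(n_emb)
            t2 = np.ones(n_emb)
            logp = 0.0
            for li, (ci, cj) in enumerate(combo):
                t1 = t1 * per_locus_trans[li][ci]
                t2 = t2 * per_locus_trans[li][cj]
                logp += per_locus_logprior[li][ci] + per_locus_logprior[li][cj]
            c1 = t1 > 0
            c2 = t2 > 0
            if not (c1 | c2).all() or not c1.any() or not c2.any():
                continue
            g1 = tuple(per_locus_cands[li][ci] for li, (ci, _) in enumerate(combo))
            g2 = tuple(per_locus_cands[li][cj] for li, (_, cj) in enumerate(combo))
            key = tuple(sorted((g1, g2)))
            if key in seen:
                continue
            seen.add(key)
            mix = np.log(0.5 * t1 + 0.5 * t2)
            ll = float(mix.sum() + logp)
            geno1 = {loci[li]: g1[li] for li in range(len(loci))}
            geno2 = {loci[li]: g2[li] for li in range(len(loci))}
            n1, n2 = int(c1.sum()), int(c2.sum())
            if n1 >= n2:
                scenarios.append(SireScenario((geno1, geno2), (n1, n2), ll))
            else:
                scenarios.append(SireScenario((geno2, geno1), (n2, n1), ll))
    scenarios.sort(key=lambda s: s.log_likelihood, reverse=True)
    return scenarios


def dominant_contribution(n1: int, n2: int) -> float:
    """Share of embryos attributed to the dominant sire, 2-decimal reporting.

    With ``n2 == 0`` the clutch is effectively single-paternity and 1.0 is
    returned by convention.
    """
    if n1 < n2 or n1 < 1 or n2 < 0:
        raise ValidationError("need n1 >= n2 >= 0 with n1 >= 1")
    if n2 == 0:
        return 1.0
    return round(n1 / (n1 + n2), 2)


# ---------------------------------------------------------------------------
# Presence of sires in the female's sperm reserves

def sires_in_reserves(
    sires: Sequence[Mapping[str, tuple[Allele, Allele]]],
    nonfemale_pool: Mapping[str, Optional[frozenset[Allele]]],
    min_loci: int = 2,
    require_both: bool = True,
) -> tuple[tuple[bool, ...], bool]:
    """Check whether each reconstructed sire is still in the sperm reserves.

    A sire is present when, at >= ``min_loci`` markers, his alleles appear
    among the pooled non-female receptacle alleles. ``require_both``
    demands both alleles at a marker (one if homozygous; the stricter
    reading); wildcard second alleles can never be confirmed and fail the
    marker under the strict rule. Loci where the female genotype is unknown
    (no attributable non-female allele set) are not evaluable.
    """
    flags: list[bool] = []
    for sire in sires:
        hits = 0
        for locus, g in sire.items():
            pool = nonfemale_pool.get(locus)
            if pool is None:
                continue
            alleles = set(g)
            if require_both:
                ok = all(a in pool for a in alleles)
            else:
                ok = any(a in pool for a in alleles if a != OTHER_ALLELE)
            if ok:
                hits += 1
        flags.append(hits >= min_loci)
    return tuple(flags), all(flags) if flags else False


# ---------------------------------------------------------------------------
# Clutch-level orchestration

def analyze_clutch(
    female: FemaleRecord,
    freqs: Mapping[str, Mapping[Allele, float]],
    min_embryos: int = 7,
    min_loci: int = 2,
    require_both: bool = True,
) -> PaternityResult:
    """Run the full paternity determination for one female's clutch."""
    screened, _log = screen_embryos(female.embryos, female.genotype, min_loci)
    if len(screened) < min_embryos:
        raise NoDataError(
            f"female {female.female_id}: {len(screened)} screened embryos "
            f"(minimum {min_embryos}); clutch excluded"
        )
    assignments = assign_paternal_alleles(screened, female.genotype)
    sets = paternal_allele_sets(assignments)
    counts = {l: len(s) for l, s in sets.items()}
    k = min_sires(counts)
    result = PaternityResult(
        female_id=female.female_id,
        n_embryos_screened=len(screened),
        paternal_counts=counts,
        min_sires=k,
    )
    if k <= 2:
        scenarios = reconstruct_sires(assignments, freqs, k)
        if not scenarios:
            result.flagged_three_plus = True
            return result
        result.scenarios = scenarios[:50]
        top = scenarios[0]
        result.ambiguous_top = (
            len(scenarios) > 1
            and scenarios[1].log_likelihood > top.log_likelihood - 1e-9
        )
        result.compat_counts = top.compat_counts
        if k == 2:
            n1, n2 = top.compat_counts
            result.dominant_contribution = dominant_contribution(n1, n2)
        if female.samples:
            pool = pool_and_subtract(female.samples, female.genotype)
            present, all_present = sires_in_reserves(
                top.genotypes, pool.nonfemale, min_loci, require_both
            )
            result.sire_present = present
            result.all_sires_present = all_present
        else:
            result.sire_present = tuple(False for _ in top.genotypes)
            result.all_sires_present = False  # no reserves
    else:
        result.flagged_three_plus = True
    return result


# ---------------------------------------------------------------------------
# Study-level summary

def paternity_summary(records: "pd.DataFrame") -> "PaternitySummary":
    """Stage-by-sires crosstab of mates and reserve status, with group tests.

    ``records`` has one row per female with columns ``stage``,
    ``min_sires``, ``min_mates`` (nullable: females excluded by the
    receptacle screen carry NA), ``all_sires`` (nullable boolean),
    ``receptacle_load`` and ``clutch_fullness``. Females with empty
    receptacles enter with ``min_mates = 0`` and ``all_sires = False``.
    """
    import pandas as pd

    from . import stats as _stats

    df = records.copy()
    rows = []
    mate_levels = sorted({int(v) for v in df["min_mates"].dropna()})
    for stage in ("primiparous", "multiparous"):
        for k in sorted(df["min_sires"].unique()):
            sub = df[(df["stage"] == stage) & (df["min_sires"] == k)]
            if sub.empty:
                continue
            row = {"stage": stage, "min_sires": int(k), "n": len(sub)}
            for m in mate_levels:
                row[f"mates_{m}"] = int((sub["min_mates"] == m).sum())
            row["all_sires_true"] = int((sub["all_sires"] == True).sum())  # noqa: E712
            row["all_sires_false"] = int((sub["all_sires"] == False).sum())  # noqa: E712
            rows.append(row)
    table = pd.DataFrame(rows)

    single = df[df["min_sires"] == 1]
    multiple = df[df["min_sires"] >= 2]
    known_mates = df[df["min_mates"].notna()]
    known_pres = df[df["all_sires"].notna()]

    def _share(x, n):
        return float(x) / n if n else float("nan")

    single_share = _share(len(single), len(df))
    one_mate_share = _share((known_mates["min_mates"] == 1).sum(), len(known_mates))
    absent_share = _share((known_pres["all_sires"] == False).sum(), len(known_pres))  # noqa: E712
    pres_single = single[single["all_sires"].notna()]
    pres_multi = multiple[multiple["all_sires"].notna()]
    all_present_single = _share((pres_single["all_sires"] == True).sum(), len(pres_single))  # noqa: E712
    all_present_multi = _share((pres_multi["all_sires"] == True).sum(), len(pres_multi))  # noqa: E712
    by_stage_multi = {
        s: _share((df[df["stage"] == s]["min_sires"] >= 2).sum(), (df["stage"] == s).sum())
        for s in ("primiparous", "multiparous")
    }

    tests: dict[str, float] = {}
    prim = df[df["stage"] == "primiparous"]
    mult = df[df["stage"] == "multiparous"]
    if len(prim) and len(mult):
        tests["multiple_paternity_by_stage"] = _stats.prop_test(
            int((prim["min_sires"] >= 2).sum()), len(prim),
            int((mult["min_sires"] >= 2).sum()), len(mult),
        ).p_value
    if len(pres_single) and len(pres_multi):
        tests["all_present_single_vs_multiple"] = _stats.prop_test(
            int((pres_single["all_sires"] == True).sum()), len(pres_single),  # noqa: E712
            int((pres_multi["all_sires"] == True).sum()), len(pres_multi),  # noqa: E712
        ).p_value
    prim_p = prim[prim["all_sires"].notna()]
    mult_p = mult[mult["all_sires"].notna()]
    if len(prim_p) and len(mult_p):
        tests["all_present_by_stage"] = _stats.prop_test(
            int((prim_p["all_sires"] == True).sum()), len(prim_p),  # noqa: E712
            int((mult_p["all_sires"] == True).sum()), len(mult_p),  # noqa: E712
        ).p_value
    # minimum mates by stage, pooling sparse high counts (2 with 3+)
    km = known_mates
    if len(km):
        def mate_counts(sub):
            raw = [int((sub["min_mates"] == m).sum()) for m in mate_levels]
            return _stats.pool_tail(raw, 2)
        tab = [mate_counts(km[km["stage"] == s]) for s in ("primiparous", "multiparous")]
        try:
            tests["mates_by_stage"] = _stats.chi_square_test(tab).p_value
        except Exception:
            pass
    if df["receptacle_load"].notna().sum():
        a = prim["receptacle_load"].dropna()
        b = mult["receptacle_load"].dropna()
        if len(a) > 1 and len(b) > 1:
            tests["load_by_stage"] = _stats.t_test(a, b).p_value
    for stage, sub in (("primiparous", prim), ("multiparous", mult)):
        w = sub[sub["all_sires"].notna() & sub["clutch_fullness"].notna()]
        a = w[w["all_sires"] == True]["clutch_fullness"]  # noqa: E712
        b = w[w["all_sires"] == False]["clutch_fullness"]  # noqa: E712
        if len(a) and len(b):
            tests[f"fullness_by_presence_{stage}"] = _stats.wilcoxon_test(a, b).p_value

    return PaternitySummary(
        table=table,
        n_females=len(df),
        single_paternity_share=single_share,
        one_mate_share=one_mate_share,
        any_sire_absent_share=absent_share,
        all_present_given_single=all_present_single,
        all_present_given_multiple=all_present_multi,
        multiple_paternity_by_stage=by_stage_multi,
        tests=tests,
    )


from dataclasses import dataclass as _dataclass, field as _field


@_dataclass
class PaternitySummary:
    """Aggregate paternity/reserve outcomes across a study's females."""

    table: "object"
    n_females: int
    single_paternity_share: float
    one_mate_share: float
    any_sire_absent_share: float
    all_present_given_single: float
    all_present_given_multiple: float
    multiple_paternity_by_stage: dict
    tests: dict = _field(default_factory=dict)
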