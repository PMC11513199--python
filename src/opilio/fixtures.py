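"""Constructed reference datasets for end-to-end checks.

These are deterministic, hand-built genotype datasets whose pipeline
outputs reproduce the study-scale marginal counts (the mates-by-layers
cross-tab, the stage-by-sires paternity table, the 16 dual-paternity
compatibility splits, the interspecies-mating tally and the regional
hybrid counts). They are synthetic test scaffolding engineered to hit
those margins — not a reconstruction of any real crab's genotype.
"""

from __future__ import annotations

import itertools
from typing import Optional

import pandas as pd

from .core import (
    Allele,
    EmbryoRecord,
    FemaleRecord,
    ReceptacleSample,
    SnpCall,
)

LOCI = ("L1", "L2", "L3")
MOM = (100, 102)
SIRE1 = (120, 122)
SIRE2 = (140, 142)
SIRE2_SHARED = (120, 140)  # overlap design: shares an allele with SIRE1
EXTRA_MATES = [(160, 162), (180, 182), (200, 202)]

#: allele frequencies used for reconstruction priors; mass is concentrated
#: on the common paternal alleles so rare-allele homozygotes and unobserved
#: second alleles are properly disfavoured
_FREQ_TABLE = {
    120: 0.55, 122: 0.068, 140: 0.20, 142: 0.10,
    100: 0.01025, 102: 0.01025, 160: 0.01025, 162: 0.01025,
    180: 0.01025, 182: 0.01025, 200: 0.01025, 202: 0.01025,
}
FIXTURE_ALLELES = tuple(sorted(_FREQ_TABLE))
FIXTURE_FREQS = {locus: dict(_FREQ_TABLE) for locus in LOCI}


def _sample(fid: str, per_locus: dict[str, frozenset[Allele]], its: Optional[str] = "G/G",
            position: str = "single", layer_age: str = "fresh") -> ReceptacleSample:
    return ReceptacleSample(
        female_id=fid,
        alleles=per_locus,
        snp=SnpCall(its=its, s16=None),
        position=position,
        layer_age=layer_age,
    )


def _pool_sample(fid: str, male_alleles, its: str = "G/G") -> ReceptacleSample:
    """One receptacle sample: female contamination plus given male alleles.

    ``male_alleles`` is either a single iterable applied to every locus or
    a mapping locus -> iterable.
    """
    per_locus: dict[str, frozenset[Allele]] = {}
    for locus in LOCI:
        if isinstance(male_alleles, dict):
            males = male_alleles.get(locus, ())
        else:
            males = male_alleles
        per_locus[locus] = frozenset(MOM) | frozenset(males)
    return _sample(fid, per_locus, its)


# ---------------------------------------------------------------------------
# Mates-by-layers cross-tab fixture

#: cell counts: (min_mates, n_layers or None) -> number of females
LAYER_TABLE: dict[tuple[int, Optional[int]], int] = {
    (0, 0): 0, (0, 1): 35, (0, 2): 7, (0, 3): 0, (0, None): 5,
    (1, 0): 4, (1, 1): 387, (1, 2): 151, (1, 3): 3, (1, None): 42,
    (2, 0): 1, (2, 1): 142, (2, 2): 150, (2, 3): 9, (2, None): 15,
    (3, 0): 0, (3, 1): 5, (3, 2): 26, (3, 3): 4, (3, None): 2,
    (4, 0): 0, (4, 1): 0, (4, 2): 1, (4, 3): 1, (4, None): 1,
}

_MATE_BLOCKS = [SIRE1, SIRE2] + EXTRA_MATES


def layer_fixture() -> list[FemaleRecord]:
    """Females whose pooled receptacle alleles give a fixed mates/layers grid."""
    out: list[FemaleRecord] = []
    i = 0
    for (m, layers), count in LAYER_TABLE.items():
        for _ in range(count):
            i += 1
            fid = f"LM-{i:04d}"
            males = frozenset(itertools.chain.from_iterable(_MATE_BLOCKS[:m]))
            rec = FemaleRecord(
                female_id=fid,
                stage="multiparous" if i % 2 else "primiparous",
                area=("NW", "CEN", "SE")[i % 3],
                genotype={l: MOM for l in LOCI},
                n_layers=layers,
                samples=[_pool_sample(fid, males)],
            )
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Interspecies-mating fixture (receptacle SNP evidence)

#: the 17 flagged females: (stage, area, layer_age, sample calls with positions)
_FLAGGED = [
    ("primiparous", "CEN", "fresh", [("single", "C/G")]),
    ("primiparous", "SE", "fresh", [("single", "C/G")]),
    ("primiparous", "SE", "fresh", [("single", "C/G")]),
    ("multiparous", "NW", "fresh", [("single", "C/G")]),
    ("multiparous", "CEN", "fresh+old", [("proximal", "C/G"), ("distal", "C/C")]),
    ("multiparous", "SE", "fresh+old", [("proximal", "G/G"), ("distal", "C/G")]),
    ("multiparous", "SE", "fresh", [("single", "C/C")]),
    ("multiparous", "SE", "fresh", [("single", "C/G")]),
    ("multiparous", "SE", "fresh", [("single", "C/G")]),
    ("multiparous", "SE", "fresh", [("single", "C/G")]),
    ("multiparous", "SE", "fresh", [("single", "C/G")]),
    ("multiparous", "SE", "fresh", [("proximal", "G/G"), ("distal", "C/G")]),
    ("multiparous", "SE", "fresh", [("proximal", None), ("distal", "C/C")]),
    ("multiparous", "SE", "fresh", [("proximal", "C/G"), ("distal", "G/G")]),
    ("multiparous", "SE", "unknown", [("proximal", "G/G"), ("distal", "C/G")]),
    ("multiparous", "SE", "unknown", [("proximal", "C/G"), ("distal", "C/C")]),
    ("multiparous", "SE", "fresh", [("proximal", "G/G"), ("intermediate", "C/G"), ("distal", "C/G")]),
]

#: background (conspecific-only) females by stage and area, totalling 912
_BACKGROUND = {
    ("primiparous", "NW"): 200,
    ("primiparous", "CEN"): 150,
    ("primiparous", "SE"): 100,
    ("multiparous", "NW"): 200,
    ("multiparous", "CEN"): 162,
    ("multiparous", "SE"): 100,
}

_N_SNP_ERROR = 20  # females with genotyping error across all samples


def interspecies_fixture() -> list[FemaleRecord]:
    """929 SNP-typed snow crab females, 17 with congener-mate evidence."""
    out: list[FemaleRecord] = []
    i = 0

    def add(stage, area, layer_age, calls):
        nonlocal i
        i += 1
        fid = f"IS-{i:04d}"
        samples = [
            _sample(
                fid,
                {l: frozenset(MOM) | frozenset(SIRE1) for l in LOCI},
                its=call,
                position=pos,
                layer_age=layer_age,
            )
            for pos, call in calls
        ]
        out.append(
            FemaleRecord(
                female_id=fid,
                stage=stage,
                area=area,
                putative_species="snow",
                genotype={l: MOM for l in LOCI},
                fresh_ejaculate="fresh" in layer_age,
                samples=samples,
            )
        )

    for stage, area, layer_age, calls in _FLAGGED:
        add(stage, area, layer_age, calls)
    for (stage, area), n in _BACKGROUND.items():
        for j in range(n):
            add(stage, area, "fresh" if j % 4 else "old", [("single", "G/G")])
    for _ in range(_N_SNP_ERROR):
        add("primiparous", "NW", "unknown", [("single", None)])
    return out


# ---------------------------------------------------------------------------
# Regional hybrid maternal-lineage fixture

#: (region, year) -> (n stations, n hybrids), matching the survey margins
_STATION_CELLS = {
    ("NW outer", 2009): (1, 1), ("NW outer", 2010): (2, 10), ("NW outer", 2011): (2, 19),
    ("NW outer", 2012): (3, 27), ("NW outer", 2013): (1, 15), ("NW outer", 2016): (1, 12),
    ("NW middle", 2011): (1, 2), ("NW middle", 2013): (1, 7),
    ("CEN outer", 2009): (3, 8), ("CEN outer", 2010): (3, 13), ("CEN outer", 2015): (1, 3),
    ("CEN middle", 2009): (8, 23), ("CEN middle", 2010): (1, 2), ("CEN middle", 2011): (1, 3),
    ("CEN middle", 2012): (4, 14), ("CEN middle", 2013): (3, 9), ("CEN middle", 2014): (1, 2),
    ("CEN middle", 2015): (1, 1),
    ("SE outer", 2011): (1, 4), ("SE outer", 2012): (1, 14), ("SE outer", 2015): (2, 7),
    ("SE outer", 2016): (1, 1),
    ("SE middle", 2009): (8, 47), ("SE middle", 2010): (1, 1), ("SE middle", 2011): (6, 10),
    ("SE middle", 2012): (1, 4), ("SE middle", 2013): (6, 11), ("SE middle", 2015): (2, 21),
}

_REGION_LINEAGE = {
    "NW outer": 0.9,
    "NW middle": 0.5,
    "CEN outer": 0.2,
    "CEN middle": 0.5,
    "SE outer": 0.1,
    "SE middle": 0.1,
}


def lineage_fixture() -> pd.DataFrame:
    """Station-level hybrid lineage records (67 stations, 291 hybrids)."""
    rows = []
    sid = 0
    for (region, year), (n_st, n_hyb) in _STATION_CELLS.items():
        base, rem = divmod(n_hyb, n_st)
        for s in range(n_st):
            sid += 1
            n = base + (1 if s < rem else 0)
            prop = min(1.0, max(0.0, _REGION_LINEAGE[region] + (0.05 if s % 2 else -0.05)))
            rows.append(
                {
                    "station": f"S{sid:03d}",
                    "region": region,
                    "year": year,
                    "n_hybrids": n,
                    "prop_snow_lineage": prop,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Morphology-vs-genetics concordance fixture

def concordance_fixture() -> tuple[list[str], list[str]]:
    """1479 putative/genetic species pairs with 19 hybrid-related misidentifications."""
    putative, genetic = [], []
    for species, n in (("snow", 900), ("tanner", 283), ("hybrid", 277)):
        putative += [species] * n
        genetic += [species] * n
    putative += ["hybrid"] * 12 + ["hybrid"] * 2 + ["snow"] * 5
    genetic += ["snow"] * 12 + ["tanner"] * 2 + ["hybrid"] * 5
    return putative, genetic


# ---------------------------------------------------------------------------
# Paternity fixture (stage x sires x mates x reserves, dual-sire splits)

#: the 16 dual-paternity clutches: (n embryos, sire1-compatible, sire2-compatible)
DUAL_SPLITS = [
    (20, 12, 8), (20, 18, 2), (20, 19, 3), (20, 19, 3),
    (19, 13, 6), (19, 17, 2), (19, 15, 4), (19, 17, 5),
    (19, 16, 3), (19, 18, 2), (18, 16, 2), (18, 17, 5),
    (18, 13, 5), (14, 8, 6), (8, 7, 3), (7, 5, 2),
]

# Per (stage, min_sires) receptacle designs: lists of (min_mates, all_present,
# count). ``None`` mates marks the female whose samples fail the screen;
# ``"empty"`` marks an empty seminal receptacle (mates 0, sires absent).
_PATERNITY_DESIGN = {
    ("primiparous", 1): [
        ("empty", False, 2), (0, False, 2), (1, True, 16), (1, False, 8),
        (2, True, 6), (2, False, 2), (3, True, 1), (None, None, 1),
    ],
    ("primiparous", 2): [
        ("empty", False, 1), (1, True, 1), (1, False, 3),
    ],
    ("multiparous", 1): [
        (0, False, 4), (1, True, 17), (1, False, 3), (2, True, 10), (2, False, 1),
    ],
    ("multiparous", 2): [
        (0, False, 1), (1, True, 2), (1, False, 4), (2, True, 4),
    ],
}


def _cycle_patterns(a: Allele, b: Allele, n: int, force_b: bool) -> list[tuple[Allele, ...]]:
    """n 3-locus paternal patterns over {a, b}; each contains b if forced."""
    base = [
        (b, a, a), (a, b, a), (a, a, b), (b, b, a), (a, b, b), (b, a, b), (b, b, b),
    ] if force_b else [
        (a, b, a), (b, a, b), (a, a, b), (b, b, a), (a, b, b), (b, a, a), (a, a, a),
    ]
    return [base[i % len(base)] for i in range(n)]


def _make_embryos(fid: str, patterns: list[tuple[Allele, ...]]) -> list[EmbryoRecord]:
    embryos = []
    for i, pat in enumerate(patterns):
        mat = MOM[i % 2]
        geno = {
            locus: tuple(sorted((mat, pat[li]))) for li, locus in enumerate(LOCI)
        }
        embryos.append(EmbryoRecord(fid, f"{fid}-E{i + 1:03d}", geno, its="G/G"))
    return embryos


def _single_sire_embryos(fid: str, n: int) -> list[EmbryoRecord]:
    pats = _cycle_patterns(SIRE1[0], SIRE1[1], n, force_b=False)
    # guarantee both sire alleles appear at every locus
    pats[0] = (SIRE1[0], SIRE1[0], SIRE1[0])
    pats[1] = (SIRE1[1], SIRE1[1], SIRE1[1])
    return _make_embryos(fid, pats)


def _dual_sire_embryos(
    fid: str, n: int, n1: int, n2: int
) -> tuple[list[EmbryoRecord], tuple, tuple]:
    """Embryos realising a (n1, n2) compatibility split; returns sire genotypes."""
    overlap = n1 + n2 - n
    if overlap == 0:
        s2 = SIRE2
        k1, k2 = n1, n2
        pats = _cycle_patterns(*SIRE1, k1, force_b=False)
        pats += _cycle_patterns(*SIRE2, k2, force_b=False)
        if k1 >= 2:
            pats[0] = (SIRE1[0], SIRE1[1], SIRE1[0])
            pats[1] = (SIRE1[1], SIRE1[0], SIRE1[1])
        if k2 >= 2:
            pats[k1] = (SIRE2[0], SIRE2[1], SIRE2[0])
            pats[k1 + 1] = (SIRE2[1], SIRE2[0], SIRE2[1])
    else:
        # shared-allele design: "both"-compatible embryos carry the shared
        # allele at all loci
        s2 = SIRE2_SHARED
        shared = SIRE1[0]
        k1 = n1 - overlap  # sire1-only embryos (must show the 122 allele)
        k2 = n2 - overlap  # sire2-only embryos (must show the 140 allele)
        pats = [(shared, shared, shared)] * overlap
        pats += _cycle_patterns(shared, SIRE1[1], k1, force_b=True)
        # sire2's private allele must be seen at every locus, so its
        # embryos lean heavily on it
        b = SIRE2_SHARED[1]
        dense = [(b, b, b), (b, b, shared), (shared, b, b), (b, shared, b)]
        pats += [dense[j % len(dense)] for j in range(k2)]
    assert len(pats) == n
    return _make_embryos(fid, pats), tuple({l: SIRE1 for l in LOCI}.items()), s2


def _reserve_pool(min_sires: int, mates, present: Optional[bool], overlap: bool):
    """Per-locus male-allele sets for the receptacle sample."""
    if mates == "empty":
        return None  # no samples at all
    if mates is None:
        return "screenfail"
    sires = [SIRE1, SIRE2_SHARED if overlap else SIRE2][: min_sires]
    sire_alleles = set(itertools.chain.from_iterable(sires))
    if mates == 0:
        return {l: frozenset() for l in LOCI}
    if not present:
        blocks = EXTRA_MATES[:mates]
        return {l: frozenset(itertools.chain.from_iterable(blocks)) for l in LOCI}
    # all sires present
    if min_sires == 1:
        blocks = [SIRE1] + EXTRA_MATES[: mates - 1]
        return {l: frozenset(itertools.chain.from_iterable(blocks)) for l in LOCI}
    # dual paternity with both sires in reserves
    if mates == 2:
        extra = frozenset()
        return {l: frozenset(sire_alleles) | extra for l in LOCI}
    # mates == 1 with both sires present: different loci lost different
    # alleles, so the corroborated count stays at two
    assert not overlap
    return {
        "L1": frozenset(SIRE1) | frozenset(SIRE2),
        "L2": frozenset(SIRE1),
        "L3": frozenset(SIRE2),
    }


def paternity_fixture() -> list[FemaleRecord]:
    """89 brooding females realising the stage/sires/mates/reserves margins."""
    # allocate dual-clutch splits: overlap rows cannot take the
    # mates-1-all-present pool design
    overlap_rows = [i for i, (n, n1, n2) in enumerate(DUAL_SPLITS) if n1 + n2 > n]
    plain_rows = [i for i in range(len(DUAL_SPLITS)) if i not in overlap_rows]
    dual_iter = {"needs_plain": list(plain_rows), "rest": list(overlap_rows)}

    def next_dual(needs_plain: bool) -> tuple[int, int, int]:
        src = dual_iter["needs_plain"] if needs_plain or not dual_iter["rest"] else dual_iter["rest"]
        return DUAL_SPLITS[src.pop(0)]

    out: list[FemaleRecord] = []
    single_sizes = iter([19] * 53 + [18] * 20)
    i = 0
    for (stage, k), cells in _PATERNITY_DESIGN.items():
        for mates, present, count in cells:
            for _ in range(count):
                i += 1
                fid = f"PT-{i:03d}"
                if k == 1:
                    embryos = _single_sire_embryos(fid, next(single_sizes))
                    overlap = False
                else:
                    n, n1, n2 = next_dual(needs_plain=(mates == 1 and present is True))
                    embryos, _, s2 = _dual_sire_embryos(fid, n, n1, n2)
                    overlap = s2 == SIRE2_SHARED
                pool = _reserve_pool(k, mates, present, overlap)
                if pool is None:
                    samples = []
                elif pool == "screenfail":
                    samples = [
                        _sample(fid, {"L1": frozenset(MOM) | frozenset(SIRE1)})
                    ]
                else:
                    samples = [
                        _sample(fid, {l: frozenset(MOM) | pool[l] for l in LOCI})
                    ]
                out.append(
                    FemaleRecord(
                        female_id=fid,
                        stage=stage,
                        area="NW" if i % 2 else "CEN",
                        year=2017 + (i % 2),
                        putative_species="snow",
                        genotype={l: MOM for l in LOCI},
                        clutch_fullness=4 + (i % 2) if stage == "primiparous" else 5 + (i % 2),
                        receptacle_load=round(0.8 + 0.05 * (i % 5), 2)
                        if stage == "primiparous"
                        else round(1.8 + 0.07 * (i % 5), 2),
                        samples=samples,
                        embryos=embryos,
                    )
                )
    assert i == 89
    return out
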