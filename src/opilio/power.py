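"""Probability of detecting multiple paternity (PrDM-style power analysis).

Detection power for a marker panel is the probability that a clutch sired
by several males is recognised as such from ``n`` genotyped embryos. It
rises with marker polymorphism and embryo count and falls with paternal
skew. The default detection criterion is the pipeline's own estimator
(embryo screening, paternal-allele assignment, then
``min_sires >= 2``), keeping the power model internally consistent with
the analysis it plans for; a simpler distinct-non-maternal-allele rule is
available as a toggle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import Allele, Genotype, ValidationError

__all__ = ["PrdmResult", "prdm", "prdm_exact", "plan_sample_size", "detect_multiple_paternity"]


@dataclass(frozen=True)
class PrdmResult:
    estimate: float
    ci_low: float
    ci_high: float
    reps: int

    def __float__(self) -> float:  # allow use in comparisons
        return self.estimate


def _validate_contributions(contributions: Sequence[float]) -> np.ndarray:
    c = np.asarray(contributions, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValidationError("contributions must be a non-empty vector")
    if (c <= 0).any():
        raise ValidationError("contributions must be strictly positive")
    if abs(c.sum() - 1.0) > 1e-9:
        raise ValidationError("contributions must sum to 1")
    return c


def _freq_arrays(
    freqs: Mapping[str, Mapping[Allele, float]]
) -> tuple[list[str], list[np.ndarray], list[list[Allele]]]:
    loci = list(freqs)
    ps, labels = [], []
    for l in loci:
        items = sorted(freqs[l].items())
        p = np.array([v for _, v in items], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValidationError(f"allele frequencies at {l} must be a distribution")
        ps.append(p)
        labels.append([a for a, _ in items])
    return loci, ps, labels


# ---------------------------------------------------------------------------
# Scalar detection rule (shared by Monte Carlo, exact oracle and tests)

def detect_multiple_paternity(
    embryo_genotypes: Sequence[Mapping[str, Genotype]],
    mother: Mapping[str, Genotype],
    rule: str = "paternal_alleles",
) -> bool:
    """Would the clutch estimator call >= 2 sires on these embryos?

    Applies the same screen and paternal-allele assignment as the paternity
    module, with the marker-count thresholds adapted to the panel size (a
    single-locus panel cannot demand two non-null markers). ``rule="naive"``
    instead counts distinct non-maternal alleles at any locus with no
    screening, for comparison with simpler published detection criteria.
    """
    from .core import EmbryoRecord
    from .paternity import assign_paternal_alleles, min_sires, paternal_allele_sets, screen_embryos

    loci = list(mother)
    if rule == "naive":
        per_locus: dict[str, set[Allele]] = {}
        for g in embryo_genotypes:
            for l in loci:
                gt = g.get(l)
                if gt is None:
                    continue
                mset = set(mother[l]) if mother[l] else set()
                per_locus.setdefault(l, set()).update(set(gt) - mset)
        return any(len(s) >= 3 for s in per_locus.values())
    if rule != "paternal_alleles":
        raise ValidationError(f"unknown detection rule {rule!r}")
    min_loci = min(2, len(loci))
    embryos = [
        EmbryoRecord("f", f"e{i}", dict(g)) for i, g in enumerate(embryo_genotypes)
    ]
    kept, _ = screen_embryos(embryos, mother, min_loci=min_loci)
    if not kept:
        return False
    assignments = assign_paternal_alleles(kept, mother)
    sets = paternal_allele_sets(assignments)
    if not sets:
        return False
    return min_sires({l: len(s) for l, s in sets.items()}) >= 2


# ---------------------------------------------------------------------------
# Monte Carlo estimator

def prdm(
    freqs: Mapping[str, Mapping[Allele, float]],
    n_embryos: int,
    contributions: Sequence[float],
    reps: int = 10_000,
    seed: int = 0,
    rule: str = "paternal_alleles",
    mother: Optional[Mapping[str, Genotype]] = None,
    sires: Optional[Sequence[Mapping[str, Genotype]]] = None,
) -> PrdmResult:
    """Monte Carlo probability of detecting multiple paternity.

    Parents are drawn from Hardy-Weinberg proportions at the given allele
    frequencies (or fixed via ``mother`` / ``sires``), each embryo's sire
    follows ``contributions``, alleles transmit Mendelianly, and the
    detection criterion of ``rule`` is applied. Returns the detected
    proportion with a binomial (Wald) 95% interval; deterministic given
    ``seed``. A single contribution of 1.0 returns 0 exactly.
    """
    c = _validate_contributions(contributions)
    if n_embryos < 1:
        raise ValidationError("need n_embryos >= 1")
    if len(c) == 1:
        return PrdmResult(0.0, 0.0, 0.0, 0)
    loci, ps, labels = _freq_arrays(freqs)
    n_sires = len(c)
    rng = np.random.default_rng(seed)
    R, n, L = reps, n_embryos, len(loci)

    idx_of = [{a: i for i, a in enumerate(lab)} for lab in labels]
    if mother is not None:
        mother_al = np.empty((R, L, 2), dtype=np.int64)
        for li, l in enumerate(loci):
            g = mother[l]
            mother_al[:, li, 0] = idx_of[li][g[0]]
            mother_al[:, li, 1] = idx_of[li][g[1]]
    else:
        mother_al = np.stack(
            [rng.choice(len(p), size=(R, 2), p=p) for p in ps], axis=1
        )
    if sires is not None:
        if len(sires) != n_sires:
            raise ValidationError("sires length must match contributions")
        sire_al = np.empty((R, n_sires, L, 2), dtype=np.int64)
        for si, s in enumerate(sires):
            for li, l in enumerate(loci):
                g = s[l]
                sire_al[:, si, li, 0] = idx_of[li][g[0]]
                sire_al[:, si, li, 1] = idx_of[li][g[1]]
    else:
        sire_al = np.stack(
            [rng.choice(len(p), size=(R, n_sires, 2), p=p) for p in ps], axis=2
        )

    which_sire = rng.choice(n_sires, size=(R, n), p=c)
    mat_pick = rng.integers(0, 2, size=(R, n, L))
    pat_pick = rng.integers(0, 2, size=(R, n, L))
    rr = np.arange(R)[:, None, None]
    ll = np.arange(L)[None, None, :]
    mat = mother_al[rr, ll, mat_pick]
    pat = sire_al[rr, which_sire[:, :, None], ll, pat_pick]

    m0 = mother_al[:, None, :, 0]
    m1 = mother_al[:, None, :, 1]
    pat_nonmat = (pat != m0) & (pat != m1)

    if rule == "naive":
        detected = np.zeros(R, dtype=bool)
        for li in range(L):
            k = len(ps[li])
            present = np.zeros((R, k), dtype=bool)
            vals = pat[:, :, li]
            mask = pat_nonmat[:, :, li]
            rows = np.repeat(np.arange(R), n)
            np.logical_or.at(present, (rows, vals.ravel()), mask.ravel())
            detected |= present.sum(axis=1) >= 3
    elif rule == "paternal_alleles":
        kept = pat_nonmat.any(axis=2)  # embryo shows >= 1 non-maternal allele
        detected = np.zeros(R, dtype=bool)
        mother_het = mother_al[:, :, 0] != mother_al[:, :, 1]
        for li in range(L):
            k = len(ps[li])
            vals = pat[:, :, li]
            unamb = kept & (pat_nonmat[:, :, li] | (vals == mat[:, :, li]))
            ambiguous = kept & ~unamb  # embryo equals the het maternal genotype
            present = np.zeros((R, k), dtype=bool)
            rows = np.repeat(np.arange(R), n)
            np.logical_or.at(present, (rows, vals.ravel()), unamb.ravel())
            count = present.sum(axis=1)
            amb_any = ambiguous.any(axis=1)
            a0 = mother_al[:, li, 0]
            a1 = mother_al[:, li, 1]
            covered = present[np.arange(R), a0] | present[np.arange(R), a1]
            count = count + (amb_any & ~covered & mother_het[:, li]).astype(int)
            detected |= count >= 3
    else:
        raise ValidationError(f"unknown detection rule {rule!r}")

    p_hat = float(detected.mean())
    half = 1.96 * math.sqrt(max(p_hat * (1 - p_hat), 0.0) / R)
    return PrdmResult(p_hat, max(0.0, p_hat - half), min(1.0, p_hat + half), R)


# ---------------------------------------------------------------------------
# Exact single-locus oracle

def _genotype_space(labels: Sequence[Allele], p: np.ndarray):
    gs = []
    for i, a in enumerate(labels):
        for j in range(i, len(labels)):
            b = labels[j]
            w = p[i] ** 2 if i == j else 2 * p[i] * p[j]
            gs.append(((a, b), w))
    return gs


def prdm_exact(
    freqs: Mapping[str, Mapping[Allele, float]],
    n_embryos: int,
    contributions: Sequence[float],
    mother: Optional[Mapping[str, Genotype]] = None,
    sires: Optional[Sequence[Mapping[str, Genotype]]] = None,
    rule: str = "paternal_alleles",
) -> float:
    """Exact detection probability for a single-locus panel with two sires.

    Enumerates parental genotype draws (under Hardy-Weinberg unless fixed)
    and all multisets of observable embryo genotypes with their multinomial
    probabilities, then applies the same scalar detection rule as the
    estimator. Intended as an independent oracle at modest allele counts.
    """
    c = _validate_contributions(contributions)
    if len(c) == 1:
        return 0.0
    if len(c) != 2:
        raise ValidationError("exact oracle supports exactly 2 sires")
    loci, ps, labels = _freq_arrays(freqs)
    if len(loci) != 1:
        raise ValidationError("exact oracle supports a single locus")
    locus = loci[0]
    lab, p = labels[0], ps[0]
    if len(lab) > 8:
        raise ValidationError("exact oracle limited to <= 8 alleles")

    mothers = (
        [(mother[locus], 1.0)] if mother is not None else _genotype_space(lab, p)
    )
    if sires is not None:
        sire_pairs = [((sires[0][locus], sires[1][locus]), 1.0)]
    else:
        space = _genotype_space(lab, p)
        sire_pairs = [((g1, g2), w1 * w2) for g1, w1 in space for g2, w2 in space]

    total = 0.0
    for mg, wm in mothers:
        for (s1, s2), ws in sire_pairs:
            w = wm * ws
            if w == 0:
                continue
            # per-embryo distribution over observable (unordered) genotypes
            dist: dict[tuple[Allele, Allele], float] = {}
            for mi in mg:
                for si, phi in ((s1, c[0]), (s2, c[1])):
                    for pa in si:
                        g = (mi, pa) if mi <= pa else (pa, mi)
                        dist[g] = dist.get(g, 0.0) + 0.5 * phi * 0.5
            outcomes = [(g, q) for g, q in dist.items() if q > 0]
            prob_detect = 0.0
            for combo in itertools.combinations_with_replacement(
                range(len(outcomes)), n_embryos
            ):
                counts: dict[int, int] = {}
                for o in combo:
                    counts[o] = counts.get(o, 0) + 1
                logw = math.lgamma(n_embryos + 1)
                for o, k in counts.items():
                    logw += k * math.log(outcomes[o][1]) - math.lgamma(k + 1)
                genos = [
                    {locus: outcomes[o][0]} for o, k in counts.items() for _ in range(k)
                ]
                if detect_multiple_paternity(genos, {locus: mg}, rule=rule):
                    prob_detect += math.exp(logw)
            total += w * prob_detect
    return total


# ---------------------------------------------------------------------------
# Sample-size planning

def plan_sample_size(
    freqs: Mapping[str, Mapping[Allele, float]],
    contributions: Sequence[float],
    power_target: float,
    reps: int = 10_000,
    seed: int = 0,
    n_max: int = 200,
    rule: str = "paternal_alleles",
) -> Optional[int]:
    """Smallest embryo count whose detection power reaches ``power_target``.

    Monotone bisection over ``n`` with a fixed seed per evaluation; returns
    ``None`` when the target is unreachable by ``n_max`` (e.g. a single
    contributor, which can never be detected as multiple).
    """
    if not 0.0 <= power_target < 1.0:
        raise ValidationError("power_target must be in [0, 1)")
    c = _validate_contributions(contributions)
    if power_target == 0.0:
        return 1
    if len(c) == 1:
        return None

    def power_at(n: int) -> float:
        return prdm(freqs, n, contributions, reps=reps, seed=seed, rule=rule).estimate

    if power_at(n_max) < power_target:
        return None
    lo, hi = 1, n_max  # invariant: power(hi) >= target
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= power_target:
            hi = mid
        else:
            lo = mid + 1
    return hi
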