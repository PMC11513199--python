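"""Microsatellite marker informativeness statistics.

Implements the panel-validation layer: allele frequencies, observed and
unbiased expected heterozygosity, effective allele counts, the inbreeding
coefficient, Monte Carlo exact tests for Hardy-Weinberg and linkage
equilibrium, and the one-known-parent paternity exclusion probability.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .core import (
    Allele,
    Genotype,
    LocusSummary,
    NoDataError,
    ValidationError,
    is_het,
    non_null,
)

__all__ = [
    "allele_frequencies",
    "locus_summary",
    "effective_allele_count",
    "hwe_test",
    "linkage_test",
    "exclusion_probability",
    "combined_exclusion",
]


def allele_frequencies(
    genotypes: Iterable[Genotype], locus: Optional[str] = None
) -> dict[Allele, float]:
    """Sample allele frequencies from diploid genotypes.

    Each non-null individual contributes two allele counts; null genotypes
    are excluded listwise. Raises :class:`NoDataError` when every genotype
    is null.
    """
    counts: Counter[Allele] = Counter()
    for g in non_null(genotypes):
        counts[g[0]] += 1
        counts[g[1]] += 1
    if not counts:
        where = f" at locus {locus}" if locus else ""
        raise NoDataError(f"no data{where}: all genotypes are null")
    total = sum(counts.values())
    return {a: c / total for a, c in sorted(counts.items())}


def _validate_freqs(freqs: Mapping[Allele, float]) -> None:
    if not freqs:
        raise ValidationError("empty frequency set")
    if any(p < 0 for p in freqs.values()):
        raise ValidationError("negative allele frequency")
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValidationError(f"allele frequencies sum to {sum(freqs.values())}, not 1")


def effective_allele_count(h_exp: float) -> float:
    """Effective number of alleles ``(1 - H_E)^-1`` from expected heterozygosity."""
    if not 0.0 <= h_exp < 1.0:
        raise ValidationError("H_E must be in [0, 1)")
    return 1.0 / (1.0 - h_exp)


def locus_summary(genotypes: Sequence[Genotype], locus: str = "") -> LocusSummary:
    """Per-locus summary statistics (N, N_A, N_eff, Freq_max, H_O, H_E, F_IS, p_excl).

    H_E is Nei's unbiased gene diversity ``(2N / (2N - 1)) (1 - sum p_i^2)``
    and N_eff is computed from that corrected value. F_IS is the
    single-population Nei form ``1 - H_O / H_E`` (0 for a monomorphic
    locus, which is flagged).
    """
    gs = non_null(genotypes)
    if len(gs) < 2:
        raise NoDataError(f"need >= 2 non-null genotypes at locus {locus or '?'}")
    n = len(gs)
    freqs = allele_frequencies(gs, locus)
    sum_p2 = sum(p * p for p in freqs.values())
    h_obs = sum(1 for g in gs if is_het(g)) / n
    h_exp = (2 * n / (2 * n - 1)) * (1.0 - sum_p2)
    mono = len(freqs) == 1
    n_eff = 1.0 if mono else effective_allele_count(h_exp)
    f_is = 0.0 if h_exp <= 0 else 1.0 - h_obs / h_exp
    return LocusSummary(
        locus=locus,
        n=n,
        n_alleles=len(freqs),
        n_eff=n_eff,
        freq_max=max(freqs.values()),
        h_obs=h_obs,
        h_exp=0.0 if mono else h_exp,
        f_is=0.0 if mono else f_is,
        p_excl=exclusion_probability(freqs),
        monomorphic=mono,
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte Carlo permutation of alleles)

def _genotype_table_logprob(pairs: np.ndarray, n_symbols: int) -> np.ndarray:
    """Table-dependent part of the conditional genotype-table probability.

    ``pairs`` has shape (reps, N, 2) with sorted integer-coded alleles. The
    conditional probability of a genotype table given the allele counts is
    proportional to ``2^h / prod n_ab!`` where h is the heterozygote count,
    so only that part is computed (per replicate).
    """
    reps, n, _ = pairs.shape
    het = (pairs[:, :, 0] != pairs[:, :, 1]).sum(axis=1)
    code = pairs[:, :, 0] * n_symbols + pairs[:, :, 1]
    ncell = n_symbols * n_symbols
    tab = np.zeros((reps, ncell), dtype=np.int64)
    rows = np.repeat(np.arange(reps), n)
    np.add.at(tab, (rows, code.ravel()), 1)
    return het * math.log(2.0) - gammaln(tab + 1).sum(axis=1)


def hwe_test(
    genotypes: Sequence[Genotype],
    locus: str = "",
    reps: int = 10_000,
    seed: int = 0,
    method: str = "mc",
) -> float:
    """Exact test for Hardy-Weinberg equilibrium via allele permutation.

    Monte Carlo version of the multi-allele exact test: the 2N observed
    alleles are repeatedly shuffled and re-paired, and the p-value is the
    proportion of arrangements whose conditional genotype-table probability
    is at most that of the observed table (with the +1 continuity of a
    permutation test). ``method="chisq"`` gives the classic goodness-of-fit
    approximation for speed.
    """
    gs = non_null(genotypes)
    if len(gs) < 5:
        raise NoDataError("need >= 5 non-null genotypes for the HWE test")
    freqs = allele_frequencies(gs)
    if len(freqs) == 1:
        return 1.0
    symbols = sorted(freqs)
    idx = {a: i for i, a in enumerate(symbols)}
    k = len(symbols)
    obs = np.array([[idx[g[0]], idx[g[1]]] for g in gs], dtype=np.int64)
    if method == "chisq":
        return _hwe_chisq(obs, k)
    if method != "mc":
        raise ValidationError(f"unknown HWE method {method!r}")
    if reps < 1000:
        raise ValidationError("Monte Carlo HWE test needs reps >= 1000")
    n = len(gs)
    obs_stat = _genotype_table_logprob(np.sort(obs, axis=1)[None, :, :], k)[0]
    rng = np.random.default_rng(seed)
    alleles = obs.ravel()
    perms = np.argsort(rng.random((reps, alleles.size)), axis=1)
    shuffled = alleles[perms].reshape(reps, n, 2)
    stats = _genotype_table_logprob(np.sort(shuffled, axis=2), k)
    hits = int((stats <= obs_stat + 1e-12).sum())
    return (hits + 1) / (reps + 1)


def _hwe_chisq(obs: np.ndarray, k: int) -> float:
    n = obs.shape[0]
    counts = np.bincount(obs.ravel(), minlength=k)
    p = counts / counts.sum()
    exp = np.empty((k, k))
    got = np.zeros((k, k))
    for a, b in obs:
        got[min(a, b), max(a, b)] += 1
    stat = 0.0
    for i in range(k):
        for j in range(i, k):
            e = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if e > 0:
                stat += (got[i, j] - e) ** 2 / e
    df = k * (k - 1) / 2
    return float(chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# Linkage (genotypic independence) permutation test

def linkage_test(
    genotypes_a: Sequence[Genotype],
    genotypes_b: Sequence[Genotype],
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation test of genotypic association between two loci.

    Individuals null at either locus are dropped. The statistic is the
    chi-square of the genotype-by-genotype contingency table; the null
    distribution is generated by shuffling one locus's genotypes across
    individuals. Returns 1.0 when either locus is monomorphic.
    """
    paired = [
        (a, b)
        for a, b in zip(genotypes_a, genotypes_b, strict=True)
        if a is not None and b is not None
    ]
    if len(paired) < 5:
        raise NoDataError("need >= 5 individuals non-null at both loci")
    ga = [a for a, _ in paired]
    gb = [b for _, b in paired]
    if len(set(ga)) == 1 or len(set(gb)) == 1:
        return 1.0
    codes_a = {g: i for i, g in enumerate(sorted(set(ga)))}
    codes_b = {g: i for i, g in enumerate(sorted(set(gb)))}
    xa = np.array([codes_a[g] for g in ga])
    xb = np.array([codes_b[g] for g in gb])
    ka, kb = len(codes_a), len(codes_b)

    def stat(b_vec: np.ndarray) -> float:
        tab = np.zeros((ka, kb))
        np.add.at(tab, (xa, b_vec), 1)
        rows = tab.sum(axis=1, keepdims=True)
        cols = tab.sum(axis=0, keepdims=True)
        exp = rows * cols / tab.sum()
        mask = exp > 0
        return float(((tab - exp)[mask] ** 2 / exp[mask]).sum())

    obs = stat(xb)
    rng = np.random.default_rng(seed)
    hits = 0
    work = xb.copy()
    for _ in range(reps):
        rng.shuffle(work)
        if stat(work) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# Paternity exclusion with one known parent

def exclusion_probability(freqs: Mapping[Allele, float]) -> float:
    """Average probability of excluding a random non-father, mother known.

    Closed form in power sums ``a_k = sum_i p_i^k`` for the one-known-parent
    exclusion probability (true mother, father and offspring drawn under
    Mendelian inheritance at the given frequencies; the candidate male is an
    unrelated random genotype):

        Q = 1 - 2 a2 + a3 + 3 (a2 a3 - a5) - 2 (a2^2 - a4)
    """
    _validate_freqs(freqs)
    p = np.array(list(freqs.values()))
    a2 = float((p**2).sum())
    a3 = float((p**3).sum())
    a4 = float((p**4).sum())
    a5 = float((p**5).sum())
    q = 1 - 2 * a2 + a3 + 3 * (a2 * a3 - a5) - 2 * (a2 * a2 - a4)
    return min(max(q, 0.0), 1.0)


def combined_exclusion(p_excl: Iterable[float]) -> float:
    """Combined multi-locus exclusion probability ``1 - prod(1 - q_l)``."""
    out = 1.0
    seen = False
    for q in p_excl:
        if not 0.0 <= q <= 1.0:
            raise ValidationError("per-locus exclusion probabilities must be in [0, 1]")
        out *= 1.0 - q
        seen = True
    if not seen:
        raise ValidationError("no per-locus exclusion probabilities given")
    return 1.0 - out
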