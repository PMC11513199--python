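"""Minimum-mates estimation from pooled receptacle alleles."""

import numpy as np
import pandas as pd
import pytest

from opilio.core import FemaleRecord, ReceptacleSample, SnpCall, genotype
from opilio.mating import (
    interspecies_summary,
    layers_vs_mates,
    min_mates,
    pool_and_subtract,
    screen_females,
)
from opilio.simulate import SimulationConfig, simulate_matings, simulate_population

G = genotype
LOCI = ("L1", "L2", "L3")


def sample(alleles, its="G/G", fid="F1", position="single"):
    return ReceptacleSample(
        female_id=fid,
        alleles={l: frozenset(a) for l, a in alleles.items()},
        snp=SnpCall(its=its),
        position=position,
    )


def female(samples, fid="F1", stage="multiparous", area="NW", **kw):
    return FemaleRecord(
        female_id=fid, stage=stage, area=area,
        genotype={l: G(1, 2) for l in LOCI}, samples=samples, **kw,
    )


# ---------------------------------------------------------------------------
# screening

def test_screen_keeps_fully_scored_females():
    fem = female([sample({"L1": {3}, "L2": {4}}), sample({"L2": {5}, "L3": {6}})])
    kept, excl = screen_females([fem])
    assert kept == [fem] and not excl


def test_screen_drops_female_with_one_bad_sample():
    fem = female([sample({"L1": {3}, "L2": {4}}), sample({"L1": {3}})])
    kept, excl = screen_females([fem])
    assert not kept and "F1" in excl


def test_screen_logs_empty_receptacle():
    kept, excl = screen_females([female([])])
    assert not kept and excl["F1"] == "empty receptacle"


# ---------------------------------------------------------------------------
# pooling and female-allele subtraction

def test_subtraction_with_known_genotype():
    pool = pool_and_subtract([sample({"L1": {1, 2, 3, 4}})], {"L1": G(1, 2)})
    assert pool.counts["L1"] == 2
    assert pool.nonfemale["L1"] == frozenset({3, 4})


def test_reduction_by_two_when_genotype_unknown():
    pool = pool_and_subtract([sample({"L1": {1, 2, 3}})], {"L1": None})
    assert pool.counts["L1"] == 1
    assert pool.nonfemale["L1"] is None
    # floored at zero
    assert pool_and_subtract([sample({"L1": {1}})], {"L1": None}).counts["L1"] == 0


def test_unscored_locus_left_undefined():
    pool = pool_and_subtract([sample({"L1": {3, 4}})], {l: G(1, 2) for l in LOCI})
    assert "L2" not in pool.counts and "L3" not in pool.counts


def test_pooling_invariant_to_subsample_partition():
    """Pooling all content at once equals unioning per-subsample detections."""
    whole = [sample({"L1": {1, 3, 4}, "L2": {5, 6}, "L3": {7}})]
    split = [
        sample({"L1": {1, 3}, "L2": {5}}, position="proximal"),
        sample({"L1": {4}, "L2": {5, 6}, "L3": {7}}, position="distal"),
    ]
    fg = {l: G(1, 2) for l in LOCI}
    a = pool_and_subtract(whole, fg)
    b = pool_and_subtract(split, fg)
    assert a.counts == b.counts and a.nonfemale == b.nonfemale


# ---------------------------------------------------------------------------
# the minimum-mates rule

@pytest.mark.parametrize(
    "counts, supported, mates",
    [
        ({"L1": 4, "L2": 3, "L3": 2}, 3, 2),
        ({"L1": 2, "L2": 2, "L3": 2}, 2, 1),
        ({"L1": 0, "L2": 0, "L3": 0}, 0, 0),
        ({"L1": 5, "L2": 3}, 3, 2),
        ({"L1": 7, "L2": 1, "L3": 0}, 1, 1),
    ],
)
def test_min_mates_second_largest_count(counts, supported, mates):
    est = min_mates(counts)
    assert est.supported == supported
    assert est.min_mates == mates
    assert not est.unsupported


def test_min_mates_needs_two_defined_loci():
    est = min_mates({"L1": 4})
    assert est.unsupported and est.min_mates is None


# ---------------------------------------------------------------------------
# layers vs mates

def test_layers_vs_mates_identity_is_fully_concordant():
    df = pd.DataFrame({"min_mates": [1, 2, 1, 2], "n_layers": [1, 2, 1, 2]})
    comp = layers_vs_mates(df)
    assert comp.concordance == 1.0
    assert comp.single_layer_excess == 0.0
    assert comp.two_layer_deficit == 0.0


def test_layers_vs_mates_na_column_excluded_from_concordance():
    df = pd.DataFrame(
        {"min_mates": [1, 2, 3], "n_layers": [1.0, 1.0, None]}
    )
    comp = layers_vs_mates(df)
    assert comp.n_layer_known == 2
    assert comp.concordance == pytest.approx(0.5)
    assert comp.single_layer_excess == pytest.approx(0.5)
    assert "NA" in comp.crosstab.columns


# ---------------------------------------------------------------------------
# interspecies summary

def test_interspecies_counts_and_trivial_chi_square():
    females = []
    for i in range(50):
        females.append(
            female([sample({"L1": {3}, "L2": {4}}, its="G/G")], fid=f"A{i}",
                   stage="primiparous" if i % 2 else "multiparous",
                   area="NW", fresh_ejaculate=True)
        )
    for i in range(4):
        females.append(
            female([sample({"L1": {3}, "L2": {4}}, its="C/C")], fid=f"B{i}",
                   stage="multiparous", area="SE", fresh_ejaculate=True)
        )
    s = interspecies_summary(females)
    assert s.n_females == 54 and s.n_flagged == 4
    assert s.rate == pytest.approx(4 / 54)
    assert s.p_area < 0.05  # all flagged females in the southeast


def test_interspecies_excludes_all_error_females():
    females = [
        female([sample({"L1": {3}, "L2": {4}}, its="G/G")], fid="A"),
        female([sample({"L1": {3}, "L2": {4}}, its=None)], fid="B"),
    ]
    s = interspecies_summary(females)
    assert s.n_females == 1


# ---------------------------------------------------------------------------
# estimator guarantees on simulated truth

def _small_cfg(**kw):
    defaults = dict(
        n_females={"primiparous": {"NW": 150}, "multiparous": {"NW": 150}},
        null_rate=0.0,
        miscall_rate=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_min_mates_never_exceeds_truth_without_error():
    cfg = _small_cfg()
    pop = simulate_population(cfg, seed=11)
    truths = simulate_matings(pop, cfg, seed=12)
    from opilio.mating import estimate_mates

    kept, _ = screen_females([t.record for t in truths])
    by_id = {t.record.female_id: t for t in truths}
    checked = 0
    for rec in kept:
        est, _ = estimate_mates(rec)
        assert est.min_mates <= by_id[rec.female_id].true_n_mates
        checked += 1
    assert checked > 200


def test_min_mates_exact_when_mates_disjoint_heterozygous():
    """Disjoint heterozygous mates at >= 2 loci are counted exactly."""
    fg = {l: G(1, 2) for l in LOCI}
    mates = [{l: G(10 + 10 * m, 11 + 10 * m) for l in LOCI} for m in range(3)]
    pool = {l: set() for l in LOCI}
    for m in mates:
        for l in LOCI:
            pool[l] |= set(m[l])
    fem = female([sample({l: pool[l] | {1, 2} for l in LOCI})])
    from opilio.mating import estimate_mates

    est, _ = estimate_mates(fem)
    assert est.min_mates == 3
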