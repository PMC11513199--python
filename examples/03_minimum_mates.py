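"""Estimate the minimum number of mates from stored sperm.

Pooled seminal-receptacle contents mix female tissue with ejaculate from
every stored mating. After subtracting the female's own alleles, the
largest non-female allele count corroborated by two markers, halved and
rounded up, bounds the number of mates from below.
"""

from opilio.core import FemaleRecord, ReceptacleSample, SnpCall, genotype
from opilio.mating import estimate_mates, layers_vs_mates
from opilio.fixtures import layer_fixture
from opilio.pipeline import analyze_mating_study

female = FemaleRecord(
    female_id="demo",
    genotype={l: genotype(100, 102) for l in ("L1", "L2", "L3")},
    samples=[
        ReceptacleSample(
            female_id="demo",
            alleles={
                "L1": frozenset({100, 102, 120, 122, 140, 142}),
                "L2": frozenset({100, 120, 122, 140}),
                "L3": frozenset({102, 120, 140}),
            },
            snp=SnpCall(its="G/G"),
        )
    ],
)
est, pool = estimate_mates(female)
print("non-female allele counts per locus:", dict(est.per_locus))
print(f"supported count (>=2 markers): {est.supported}  ->  "
      f"minimum mates = {est.min_mates}")
print("Three non-female alleles corroborated by a second marker imply at")
print("least two males (an odd allele count rounds up to the next mate).\n")

df, _ = analyze_mating_study(layer_fixture())
comp = layers_vs_mates(df)
print(f"across {comp.n_layer_known} females with layer counts:")
print(f"  layer count equals minimum mates for {100*comp.concordance:.0f}%")
print(f"  single-layer females exceed one mate in {100*comp.single_layer_excess:.0f}%")
print(f"  two-layer females fall below two mates in {100*comp.two_layer_deficit:.0f}%")
print("so visually counted ejaculate layers are a poor proxy for mates.")
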