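"""Call species and hybrid maternal lineage from the two diagnostic SNPs.

The nuclear ITS diplotype separates snow crab (G/G), Tanner crab (C/C)
and hybrids (C/G); the mitochondrial 16S base gives the maternal lineage
(T = snow, C = Tanner). Station-level hybrid lineages are then averaged
into annual regional proportions.
"""

from opilio.core import SnpCall
from opilio.fixtures import lineage_fixture
from opilio.species import call_species, regional_lineage_average

for its, s16 in [("G/G", "T"), ("C/C", "C"), ("C/G", "T"), ("C/G", "C"),
                 ("G/G", "C"), (None, "T")]:
    c = call_species(SnpCall(its=its, s16=s16))
    flag = " (mito-discordant)" if c.mito_discordant else ""
    print(f"ITS={its or '--':4} 16S={s16 or '-'}: {c.species:10} "
          f"maternal lineage={c.maternal_lineage}{flag}")

stations = lineage_fixture()
print(f"\n{len(stations)} stations, {stations.n_hybrids.sum()} hybrids")
print("\nmean proportion of hybrids with a snow crab maternal lineage:")
for region, prop in regional_lineage_average(stations).items():
    print(f"  {region:11} {prop:.2f}")
print("\nA high proportion means hybrids there mostly descend from snow crab")
print("mothers mating with Tanner crab males rather than the reverse cross.")
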