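# Methods

This note records the models, rules and design choices behind the
package, in the order the pipeline applies them.

## Study system and data model

Female snow crab mate during a brief window (primiparous females at the
maturity moult, multiparous females as hard-shelled adults with more mate
choice) and store ejaculate in paired seminal receptacles as layered
deposits. A receptacle content sample is therefore a *pool*: one or more
male genotypes plus contaminating female epithelial tissue, so a locus
can legitimately show more than two alleles. Embryo clutches carry one
maternal and one paternal allele per locus. The package represents
alleles as integer fragment sizes, genotypes as sorted pairs (None for a
scoring failure), receptacle samples as per-locus allele *sets*, and
females as records linking metadata, own genotype, samples and embryos.

## Marker statistics

Expected heterozygosity uses Nei's unbiased estimator
H_E = (2N / (2N − 1)) (1 − Σ pᵢ²), and the effective allele count
N_eff = (1 − H_E)⁻¹ is computed from that corrected value so that
heterozygosities printed at three decimals round-trip to the printed
N_eff. With the correction, N_eff can marginally exceed the observed
allele count for near-equifrequent samples; the classical bound
N_eff ≤ N_A holds for the uncorrected quantity 1/Σpᵢ², which is what the
property tests check. F_IS is the single-population Nei form
1 − H_O/H_E (zero, flagged, for monomorphic loci); the Weir–Cockerham
estimator is deliberately out of scope.

The Hardy–Weinberg test is a Monte Carlo exact test: the 2N observed
alleles are re-paired at random and the conditional genotype-table
probability (∝ 2^h / Π n_ab!) compared against the observed table, with
the (hits + 1)/(reps + 1) permutation convention. The linkage test
shuffles one locus's genotypes across individuals with a genotypic
contingency chi-square statistic. Both are seeded and calibrated: over
1000 null simulations (n = 50, four alleles) the empirical type-I error
at α = 0.05 sits within ±0.02 of nominal.

The one-known-parent exclusion probability uses the closed form in power
sums a_k = Σ pᵢᵏ,

Q = 1 − 2a₂ + a₃ + 3(a₂a₃ − a₅) − 2(a₂² − a₄),

verified against a brute-force enumeration of mother × father ×
offspring × candidate-male genotype draws to 1e-12. Whether sample or
bias-corrected frequencies feed this formula is the caller's choice; the
package uses sample frequencies.

## Species and maternal lineage

Species is read from the nuclear ITS diplotype; the mitochondrial 16S
base supplies maternal lineage. A pure-species ITS call with the other
species' mitochondria is reported as the ITS species with a
`mito_discordant` flag rather than an error, since introgressed
mitochondria are biologically plausible and the nuclear marker is the
species determinant. Both markers null is a genotyping-error record.
For pooled receptacle samples from a snow crab female, C/C demands a
Tanner crab mate while C/G is ambiguous between a hybrid mate and a
mixed pool; a female is flagged for interspecies mating if *any* sample
shows either. Station proportions of snow-lineage hybrids are averaged
unweighted within region × year (empty cells stay missing), and
multi-year regional values average the annual means.

## Minimum mates

Per female: union the detected alleles across her content subsamples at
each locus (so the estimate is invariant to how the contents were
partitioned), remove her own alleles where her genotype is known and
otherwise subtract two from the count (floored at zero), then take the
largest count corroborated by at least two markers — implemented as the
second-largest per-locus count, reading "detected at two or more
markers" as "a count k is corroborated by any locus showing ≥ k
non-female alleles". A literal equal-counts-at-two-markers reading
yields no estimate for most real pools; this interpretation is the one
deliberate reading in the package and is isolated in `min_mates` should
a different one be wanted. The estimate is ⌈supported/2⌉: a lower bound,
since it assumes heterozygous males sharing no alleles. Females are
screened first: every subsample must be scored at ≥ 2 of the 3 markers,
otherwise the female is excluded with a logged reason.

## Paternity

Embryo screening: first, any embryo locus sharing no allele with the
mother is nulled (treated as a scoring failure); then embryos must be
non-null at ≥ 2 markers, share a maternal allele at ≥ 2 markers, and
show at least one non-maternal allele. Clutches need ≥ 7 screened
embryos (configurable) to be analysed.

Paternal-allele assignment gives each embryo exactly one paternal allele
per non-null locus: a non-maternal allele if present; the shared allele
if the embryo is homozygous for a maternal allele; and when the embryo
equals the heterozygous maternal genotype, the ambiguity is resolved
clutch-wide to minimise the distinct paternal set per locus (ties to the
smaller label). The greedy per-locus resolution is provably minimal here
because all ambiguous embryos at a locus share the same two candidate
alleles; a brute-force assignment search in the tests confirms it.
Minimum sires is ⌈max per-locus distinct paternal count / 2⌉.

Sire reconstruction (1–2 sires, ≤ 3 loci) enumerates candidate per-locus
genotypes built from the observed paternal alleles plus a wildcard
"unobserved second allele" whose frequency is the residual mass; pairs
must jointly carry every observed paternal allele at every locus, every
embryo must be compatible with at least one sire at all its non-null
loci, and each sire with at least one embryo. Scenarios are scored by

log L = Σ_embryos log(½ t₁ + ½ t₂) + Σ_sires log HWE-prior,

t_s being the product over the embryo's loci of the Mendelian
transmission probability of its assigned paternal allele (1 homozygous
match, ½ heterozygous match, 0 otherwise). This equal-mixture likelihood
is an approximation — the reference programs' internal scoring is not
published — so conclusions rest on the compatibility counts, not the
likelihood values. An embryo compatible with both sires counts for both,
which is why attributed embryos can sum to more than the sample size.
Dominant contribution is n₁/(n₁+n₂) over compatibility counts (1.0 by
convention when n₂ = 0). No scenario with ≤ 2 sires flags the clutch as
≥ 3 sires, counted by the minimum-sires rule only.

Sire presence in reserves: a sire is present if at ≥ 2 markers *both* of
his alleles (one if homozygous) appear among the pooled non-female
receptacle alleles; `require_both=False` relaxes this to one allele per
marker. Wildcard alleles can never be confirmed and fail the strict
rule. Loci where the female's genotype is unknown have no attributable
non-female set and are not evaluable. Females with empty receptacles are
reported with zero mates and sires absent ("no reserves"); females whose
receptacle samples fail the marker screen keep their sire count but have
mates/presence recorded as missing.

## Detection power

`prdm` draws mother and sires from Hardy–Weinberg at the panel's
frequencies (or holds them fixed), assigns each embryo a sire by the
contribution vector, transmits alleles Mendelianly, and applies the
package's own screening + assignment + minimum-sires rule; detection is
min sires ≥ 2. Reusing the pipeline's estimator keeps the power model
consistent with the analysis it plans for; a simpler
distinct-non-maternal-alleles rule is available as a toggle for
comparison with published power software. Defaults: 10,000 replicates
(binomial CI half-width ≈ 0.01 near 0.8), Wald 95% interval, fully
seeded. A single-locus exact oracle enumerates parental draws and embryo
genotype multisets and applies the same detection function; the Monte
Carlo estimate agrees with it within 0.01 at 100,000 replicates. The
sample-size planner bisects over n with a fixed seed per evaluation.
Power at a single modest locus plateaus well below 1 (detection needs
three distinct non-maternal paternal alleles), which is why multi-locus
panels matter.

## Synthetic data

The generator emulates the study conditions rather than idealised data:
three loci with 13-allele ladders spaced one or two repeat units apart,
Dirichlet(0.5) frequencies rejection-sampled until the population
effective allele count lands in 3–7; mates per female distributed
{0: 5%, 1: 59%, 2: 32%, 3: 3.5%, 4: 0.5%}; per-allele female
contamination calibrated so ≈ 4.9 of the 6 female alleles are visible in
a pool; a 20% chance a mate's sperm is fully depleted (absent from
reserves); a 10% repeated-mating chance so layer counts can exceed mate
counts; dual-clutch skew 0.5 + 0.5·Beta(2.8, 2.2), mean dominant share
0.78; 20 embryos per clutch; area-dependent Tanner-mate probabilities
concentrated in the southeast; optional null-genotype and ±1-repeat
miscall rates (zero by default, injected by tests that quantify their
effect). Everything is reproducible from (config, seed).

What the simulator does *not* model: real allele-frequency structure of
the survey populations, spatial station structure, embryo stratification
within clutches (sampling is uniform), null-allele inheritance, and
linkage between loci. Passing tests on synthetic data therefore
demonstrate the estimators' logical guarantees (e.g. mates and sires are
never overcounted absent genotyping error) and calibration, not field
accuracy.

The `fixtures` module is different in kind: deterministic, hand-built
datasets engineered so the pipeline's outputs reproduce study-scale
marginal tables exactly (the 991-female mates-by-layers grid, the
89-clutch stage-by-sires table with reserve status, the sixteen
dual-paternity compatibility splits averaging 0.78, the 17-of-929
interspecies tally, 291 hybrids across 67 stations). They are test
scaffolding: the genotypes are invented, only the margins are real. Two
construction details matter. Where attributed embryos exceed the sample
size, the two sires share an allele and "both"-compatible embryos carry
it at all loci, with the sire-specific allele present at every locus so
the likelihood search pins both genotypes; and the fixture allele
frequencies are deliberately skewed (common shared allele, rarer private
ones) so the top-likelihood scenario is the intended pair rather than a
rare-allele homozygote or wildcard variant. The stage assignment of the
sixteen dual clutches and the background stage/area marginals of the
interspecies tally are not determined by the published margins; they are
fixed, documented choices in the fixture source.

## Numerical conventions and edge cases

Monomorphic loci: H_E = 0, N_eff = 1, F_IS = 0 with a degenerate flag;
HWE and linkage p-values are 1. Frequencies must sum to 1 within 1e-9.
Permutation p-values use (hits + 1)/(reps + 1) and never return 0.
Reconstruction caps at 2 sires and 3 loci (the search is exhaustive
within that envelope); ties in scenario likelihood are surfaced via an
`ambiguous_top` flag with presence evaluated for the first-ranked
scenario. Percentages in reports are rounded to integers; underlying
proportions are kept at full precision in the JSON bundle. Problem
sizes in the test suite (e.g. 10,000 simulated females and clutches for
the no-overcount guarantee, 100,000 replicates for the Monte Carlo
versus exact comparison, 400 simulated clutches against the power
prediction) were chosen to make the checks sharp at desk scale.

## Known limitations

- The reconstruction likelihood is an approximation with equal sire
  mixture weights; it is not a reimplementation of any published
  program's internal scoring.
- The minimum-mates corroboration rule is an interpretation (see above).
- Power values for the real study panel depend on its unpublished
  allele frequencies; the package reproduces the monotone shape of the
  published grid on synthetic panels but makes no claim to its exact
  values.
- F2/backcross hybrids cannot be distinguished by the two-SNP panel and
  are not modelled.
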