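"""Validate a microsatellite marker panel.

Simulates a study-like population, then prints per-locus informativeness
statistics, Hardy-Weinberg test p-values and paternity exclusion
probabilities — the checks run before trusting a panel for parentage.
"""

from opilio.markers import combined_exclusion, hwe_test, linkage_test, locus_summary
from opilio.simulate import SimulationConfig, simulate_population

cfg = SimulationConfig()
pop = simulate_population(cfg, seed=42)

print(f"{'locus':6} {'N':>4} {'N_A':>4} {'N_eff':>6} {'H_O':>6} {'H_E':>6} "
      f"{'F_IS':>7} {'p_excl':>7} {'HWE p':>7}")
p_excl = []
for locus in pop.loci:
    gs = [m[locus] for m in pop.males]
    s = locus_summary(gs, locus)
    p = hwe_test(gs, reps=2000, seed=1)
    p_excl.append(s.p_excl)
    print(f"{locus:6} {s.n:>4} {s.n_alleles:>4} {s.n_eff:>6.1f} {s.h_obs:>6.3f} "
          f"{s.h_exp:>6.3f} {s.f_is:>7.3f} {s.p_excl:>7.3f} {p:>7.3f}")

pair_p = linkage_test(
    [m[pop.loci[0]] for m in pop.males],
    [m[pop.loci[1]] for m in pop.males],
    reps=2000, seed=2,
)
print(f"\nlinkage test {pop.loci[0]}/{pop.loci[1]}: p = {pair_p:.3f}")
print(f"combined exclusion probability: {combined_exclusion(p_excl):.3f}")
print("\nN_eff is the effective allele count (1 - H_E)^-1; the combined")
print("exclusion probability is the chance a random non-father is excluded")
print("given the mother's genotype, pooled across the panel.")
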