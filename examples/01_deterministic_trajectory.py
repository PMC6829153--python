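"""Deterministic dynamics of one sexually antagonistic locus.

Iterates the two-sex viability-selection recursion (10% male cost, equal
female cost, additive effects, random mating) from a low starting frequency
to its polymorphic equilibrium, then prints the divergence and load that
equilibrium buys.
"""

from sexantag import (
    FitnessScheme,
    GenotypeFrequencies,
    iterate,
    load,
    male_female_fst,
    post_selection_freqs,
)
from sexantag.stats import fis

scheme = FitnessScheme(s=0.1, alpha=1.0, hf=0.5, hm=0.5)
traj = iterate(GenotypeFrequencies.hardy_weinberg(0.05), scheme, steps=5000)

print("generation      pA1        pf        pm")
for t in (0, 10, 100, 1000, 5000):
    print(f"{t:10d} {traj.p_a1[t]:9.5f} {traj.pf[t]:9.5f} {traj.pm[t]:9.5f}")

p_eq = traj.final()
sexfreqs = post_selection_freqs(p_eq, scheme)
print(f"\nequilibrium male-female FST : {male_female_fst(p_eq, sexfreqs):.6f}")
print(f"equilibrium genetic load    : {load(p_eq, scheme):.4f}")
print(f"equilibrium FIS             : {fis(p_eq):.6f}")
print(
    "\nA 10% viability cost per sex maintains the polymorphism at pA1=0.5"
    "\nbut produces divergence of only ~7e-4 while costing 5% of mean"
    "\nfitness; the heterozygote excess (positive FIS) is equally tiny."
)
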