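"""Genome-wide antagonistic selection vs a matched neutral control.

Runs a reduced copy of the genome scenario (2,000 diploids, 400 steps,
per-capita mutation supply matched to the full scenario) in both
antagonistic and neutral flavors and prints the divergence, polymorphism, and load
summaries.  The full study scale (10,000 diploids, 100 Mb) runs the same
way in a few minutes via scripts/acceptance.py.
"""

import numpy as np

from sexantag import GenomeSimConfig, run_genome_sim

common = dict(
    carrying_capacity=2_000,
    genome_length=2e7,  # 20 Mb; mutation rate raised so the per-capita
    mutation_rate=2.5e-9,  # mutation supply matches the full scenario
    steps=400,
    replicates=2,
)

for label, neutral, seed in (("antagonistic", False, 1), ("neutral", True, 2)):
    res = run_genome_sim(GenomeSimConfig(neutral=neutral, seed=seed, **common))
    worst = max(
        np.nanmax(r.per_locus["fst_eq4"].to_numpy()) for r in res.replicates
    )
    print(f"\n== {label} ==")
    print(f"segregating SNPs (mean)     : {res.mean_segregating():.0f}")
    print(f"whole-pop mean male-female FST: {res.mean_fst():.2e}")
    print(f"largest per-locus FST       : {worst:.2e}")
    print(f"SNPs above 10% frequency    : {res.pooled_common_snps(0.10)}")
    print(f"mean genetic load           : {res.mean_load():.3f}")

print(
    "\nAntagonistic selection maintains intermediate-frequency balanced"
    "\npolymorphisms (and pays a load for them), yet whole-population"
    "\nmale-female FST stays far below anything detectable in samples."
)
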