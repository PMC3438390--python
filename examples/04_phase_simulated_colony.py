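"""Segregation phasing: simulate a colony, phase it back, audit the result.

Generates a 4-generation colony with known truth (no noise), infers every
animal's diplotype from its unphased genotype plus the pedigree, and
compares against the simulated truth.
"""

from mhckit import SimConfig, find_homozygotes, phase_pedigree, simulate_colony

cfg = SimConfig(
    n_founders=14, n_generations=4, mean_offspring=2.0,
    recomb_rate_per_meiosis=0.0, dropout_rate_per_locus=0.0,
    str_dropout_rate=0.0, seed=2024,
)
truth, records = simulate_colony(cfg)
cohort = phase_pedigree(records, truth.pedigree, truth.working_pool)

n = len(cohort.animals)
resolved = cohort.by_status("resolved")
wrong = sum(
    1 for a in resolved if a.diplotype.pair != truth.diplotypes[a.animal_id].pair
)
print(f"{n} animals simulated; {len(resolved)} resolved "
      f"({100 * cohort.resolution_rate():.1f}% of genotyped), {wrong} wrong")
# With full typing and no recombination, every pool pair has a unique
# union-genotype signature, so phasing is exact: 100% resolved, 0 wrong.

homo = find_homozygotes(cohort)
print("MHC-homozygous animals:", [f"{a} ({h},{h})" for a, h in homo] or "none")
# Homozygotes arise whenever both parents transmit the same haplotype; they
# are the most valuable animals for MHC-matched experiments.

first = resolved[0]
print(f"example: animal {first.animal_id} resolved as {first.diplotype} "
      f"(truth {truth.diplotypes[first.animal_id]})")
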