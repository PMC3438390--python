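"""Microsatellite fast typing: call offspring without sequencing.

Builds the STR association maps from the pool, types a normal offspring from
its fragment-length profile alone, and shows the escalation flag raised by a
recombinant offspring.
"""

from mhckit import Diplotype, build_str_maps, fast_type_offspring, fixture_pool
from mhckit.regions import Interval
from mhckit.simulate import make_chimera

pool = fixture_pool()
a_map, drb_map = build_str_maps(pool)
print(f"{len(a_map.forward)} A-block signatures; "
      f"{len(a_map.collisions)} pattern collision(s); "
      f"{len(drb_map.conflicts)} DRB allele(s) with conflicting lengths")
# The collision (haplotypes differing only in a Mafa-A1 allele but printing
# identical patterns) and the length conflicts are data caveats the maps
# surface instead of hiding.

sire, dam = Diplotype(("1", "2")), Diplotype(("5", "9"))
h1, h5 = pool.get("1"), pool.get("5")
profile = {"D6S2854": h1.d6s2854.lengths | h5.d6s2854.lengths,
           "D6S2859": h1.d6s2859.lengths | h5.d6s2859.lengths}
drb_obs = h1.d6s2878_certain() | h5.d6s2878_certain()
res = fast_type_offspring(profile, drb_obs, sire, dam, pool)
print(f"offspring of (1,2) x (5,9): {res.status} {res.call}")
# The observed fragment unions match exactly one of the four transmissible
# diplotypes, so the animal is typed without sequencing.

recomb = make_chimera(pool.get("21"), pool.get("26"), Interval.A_B, "rec")
other = pool.get("3")
profile = {"D6S2854": recomb.d6s2854.lengths | other.d6s2854.lengths,
           "D6S2859": recomb.d6s2859.lengths | other.d6s2859.lengths}
drb_obs = recomb.d6s2878_certain() | other.d6s2878_certain()
res = fast_type_offspring(profile, drb_obs,
                          Diplotype(("21", "5")), Diplotype(("26", "3")), pool)
print(f"recombinant offspring: {res.status} -- {res.note}")
# No transmissible diplotype fits a crossover product, so the workflow
# escalates the animal to sequencing.
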