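"""Recombinant haplotypes: pool-wide chimera scan and crossover explanation.

Scans the bundled pool for haplotypes that are block-wise combinations of two
others, then explains a transmitted haplotype as a parental crossover.
"""

from mhckit import Diplotype, explain_crossover, find_chimeras, fixture_pool

pool = fixture_pool()

for call in find_chimeras(pool, max_breakpoints=2):
    intervals = ", ".join(str(iv) for iv in call.breakpoint_intervals())
    print(f"haplotype {call.child_id}: blocks "
          f"{'/'.join(call.block_assignment)} "
          f"(donors {call.donor_pair[0]} and {call.donor_pair[1]}; "
          f"breakpoints at {intervals})")
# Two of the 32 haplotypes are chimeras of others: 4 carries haplotype 3's
# class I and DQ/DP blocks around haplotype 21's DR block, and 22 is a single
# A|B crossover product of 21 and 26.

expl = explain_crossover(pool.get("22"), Diplotype(("21", "26")), pool)
print(f"\nhaplotype 22 from a (21,26) parent: {expl.n_breakpoints} breakpoint, "
      f"interval(s) {', '.join(str(iv) for iv in expl.all_single_intervals())}")
# Given the parent diplotype, the crossover is localized to the interval
# between the A and B blocks -- exactly what an offspring-screening workflow
# needs before deciding to sequence.
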