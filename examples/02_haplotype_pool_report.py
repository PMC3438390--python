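"""Haplotype-pool bookkeeping: frequencies, drift, DRB region configurations.

Loads the bundled 32-haplotype colony pool and prints the cohort statistics
a colony manager tracks.
"""

from mhckit import (
    compare_cohorts,
    drb_region_summary,
    fixture_pool,
    haplotype_frequencies,
)

pool = fixture_pool()
orig = haplotype_frequencies(pool, "original")
bprc = haplotype_frequencies(pool, "bprc")
print(f"{len(pool)} haplotypes; {orig.attrs['total']} occurrences in the "
      f"original colony, {bprc.attrs['total']} in the current cohort")
print("five most frequent (current cohort):")
print(bprc.sort_values("count", ascending=False).head())
# Percentages are 100*count/total rounded half-up to one decimal; counts are
# haplotype occurrences (two per animal).

comp = compare_cohorts(pool)
print("\nno longer present in the current cohort:", ", ".join(comp.absent_from_bprc))
print("largest percentage reduction: haplotype", comp.largest_reduction,
      f"({comp.table.loc[comp.largest_reduction, 'original_pct']}% -> "
      f"{comp.table.loc[comp.largest_reduction, 'bprc_pct']}%)")
# Low-frequency haplotypes drop out of a closed colony by drift; anything
# larger would hint at selection or management effects.

drb = drb_region_summary(pool)
print(f"\nDRB region configurations: {drb.min_loci}-{drb.max_loci} DRB genes "
      "per haplotype")
print("haplotype groups sharing an identical DRB allele set:")
for alleles, ids in drb.shared_combinations:
    print("  haplotypes", "/".join(ids))
# Shared DRB sets are why DRB typing alone cannot identify a haplotype; the
# DRA allele, STR lengths and the flanking blocks disambiguate.
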