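# Methods

## Region-block model

The macaque MHC is modelled as five ordered region blocks on one chromosome,
telomeric to centromeric: **A** (the duplicated *Mafa-A1/-A2/-A4/-A5* loci,
with the D6S2854 and D6S2859 microsatellites), **B** (*Mafa-B* loci plus the
oligomorphic *Mafa-I*, which co-segregates with B — no A/I–B recombinant has
been observed in the colony, so I is stored inside the B block), **DR**
(*Mafa-DRA* plus 2–5 *DRB* loci; D6S2878 lies in DRB intron 2), **DQ**
(*DQA1*, *DQB1*) and **DP** (*DPA1*, *DPB1*). Locus order *within* a block
is unknown, so recombination is resolved only to the four inter-block
intervals (A|B, B|DR, DR|DQ, DQ|DP); duplicated loci (*Mafa-B*, *DRB*) are
treated as unordered sets.

Three observation states are distinguished everywhere: a non-empty set
(alleles or fragment lengths detected), an **empty set** as a determinate
negative (a locus the haplotype lacks, or a reproducible null STR pattern —
informative and usable as evidence), and **not determined** (assay failed or
not run — a wildcard for all matching). In the bundled pool, two haplotypes
have null D6S2859 patterns, one has an undetermined D6S2859, one lacks
DQB1/DPA1 determinations, and one carries unconfirmed DP alleles that are
stored but treated as not determined.

## Genotype semantics and decomposition

Typing reports presence, not dosage, so an animal's observed genotype is the
per-locus **set-union** of its two haplotypes' alleles (shared alleles
collapse) and the per-marker union of its STR patterns. Decomposition
inverts this exactly: every unordered pool pair (self-pairs included — MHC
homozygotes are real) is a candidate iff, at each typed locus/marker, the
pair's union equals the observation; where one side is not determined, a
superset test replaces equality. The pool has ~32 haplotypes, so the ≤ 528
pairs are enumerated exhaustively — no heuristics, and correctness of the
generating pair being among the candidates is structural. D6S2878 lengths
flagged uncertain in the source table are excluded from hard matching and
soft-match within 2 bp.

The genotype TSV therefore distinguishes `-` (determinate absence) from `ND`
(not typed); without that distinction absence could not be used as evidence.

## Pedigree phasing

Candidate sets are pruned to a fixpoint with the transmission constraint: a
child's candidate pair must split into one haplotype present in some
surviving sire candidate and one in some surviving dam candidate. Missing
parents impose no constraint; animals in the pedigree without genotypes keep
all pool pairs and merely relay constraints; a parent whose own candidate
set is empty (inconsistent) is treated as unconstraining so its conflict
does not cascade. Pruning is monotone, so the fixpoint is unique and
independent of processing order (the implementation iterates in topological
order only for speed). Animals end as resolved (one candidate), ambiguous
(several — never broken by frequency; an optional ranking orders but never
filters), inconsistent (none — handed to recombination analysis) or untyped.

Founder haplotypes can be reconstructed without the pool by co-transmission:
enumerate assignments of genotyped offspring to the two transmitted
chromosomes; within an assignment, an allele present in the offspring but
absent from its other typed parent sits on the transmitted side, an allele
missing from a typed offspring locus sits off it, and two alleles at a
single-copy locus (A1, DRA, DQA1, DQB1, DPA1, DPB1) occupy opposite sides.
Placement is **parsimonious**: an allele is put on both chromosomes only
when evidence forces it, so a founder homozygous for an allele that no
offspring configuration can side is reported with that allele on one side.
All consistent bipartitions are returned; one means resolved, none flags
possible recombination.

## Recombinant detection

A haplotype is chimeric when its five blocks can be tiled from two donor
haplotypes with 1..`max_breakpoints` switches along the block order.
`max_breakpoints` defaults to 2 because one of the two recombinants in the
bundled pool (haplotype 4: class I and DQ/DP from haplotype 3, DR from 21)
requires two breakpoints; the two-breakpoint reading is an interpretation of
its composition, not an asserted history. Block equality is per-locus allele
set equality; the A block additionally compares both STR patterns, and DR
equality requires the same DRA allele and the same named-DRB set (D6S2878
lengths are allele-linked, hence redundant). A not-determined block on the
*candidate child* matches anything and taints the call with a
`wildcard_supported` caveat; a not-determined **donor** block is never
accepted as positive evidence — a chimera claim needs affirmative matches,
and without this asymmetry haplotypes sharing a DRB set with
DRA-undetermined haplotypes would be spuriously flagged.

`explain_crossover` restricts donors to one parent's diplotype and returns
the minimal-breakpoint explanation. When the parental haplotypes share the
blocks adjacent to the true breakpoint, several single-breakpoint placements
are observationally equivalent; all are reported rather than one guessed. A
crossover between haplotypes identical across the breakpoint produces a
transmitted haplotype equal to a parental one — such events are inherently
unobservable and are correctly reported as non-recombinant.

## STR typing

`build_str_maps` associates each A-block signature (its set of A-region
allele names) with its (D6S2854, D6S2859) pattern pair, and each DRB allele
with its observed D6S2878 lengths. Patterns are attached to whole A-block
signatures, never to individual A loci, because the repeats' physical
position among the A loci is unknown. Two caveats are surfaced rather than
hidden:

* distinct signatures sharing a fully determined pattern pair are recorded
  as **collisions** (the bundled pool contains exactly one — see
  Limitations);
* a DRB allele observed with different firm lengths on different haplotypes
  is recorded under **conflicts** (the bundled table contains several such
  alleles, e.g. one allele printed with lengths 204/208/218 on three
  haplotypes). The default map keeps all observations; `strict=True` turns a
  conflict into an error. Typing predictions therefore use the
  per-haplotype lengths stored in each haplotype's DR block, not the global
  allele map.

Offspring fast typing enumerates the ≤ 4 transmissible diplotypes of two
phased parents and keeps those whose predicted fragment unions match the
observed profile. Lengths are compared exactly by default; a `tolerance`
parameter (bp) absorbs inter-run drift, and uncertain lengths soft-match
within max(tolerance, 2) bp. One survivor is a call (Mendelian-consistent by
construction), several an explicit ambiguity, zero the crossover flag that
recommends sequencing.

## Frequencies and summaries

Counts are haplotype occurrences (two per animal). Percentages are
100·count/total rounded **half-up** to one decimal so that printed tables
reproduce exactly; the drift report lists per-haplotype percentage deltas,
haplotypes absent from the current cohort, and the largest reduction.

## Colony simulator

The simulator emulates the documented colony structure and is the source of
ground truth for the recovery studies. Defaults: 30 founders (half female,
seeding 12 matrilines cyclically), up to 7 generations, mean 2 offspring per
female per generation (chosen to hold a self-sustaining colony of order 10²
animals), founder haplotypes drawn independently with probabilities
proportional to original-colony counts (zero-count haplotypes get weight 1),
dams drawn from the previous generation's females, sires from all males born
so far (matrilines propagate through dams only; imported males were
unrelated). Each meiosis transmits one parental haplotype uniformly, or,
with probability `recomb_rate_per_meiosis` (default 0.01 — an order of
magnitude placeholder, the true rate is unknown for this system), a
single-breakpoint chimera with the interval drawn from `breakpoint_weights`
and coin-flip orientation; chimeras block-identical to a parental haplotype
are recorded as unobservable crossovers. Observations are the union
genotypes of the true diplotypes with independent per-locus and per-marker
dropout (default 0.05 each, representing occasional amplification failure).
A single seeded `numpy` generator drives every choice, so runs are
byte-reproducible.

What the simulator does **not** model: STR or sequence mutation, PCR
chimeras, haplotype-specific amplification bias (the dropout is uniform),
overlapping-generation demography, and inbreeding avoidance. Passing
recovery tests on simulated colonies therefore demonstrates the
combinatorial correctness of decomposition/phasing/crossover logic under the
stated observation model, not robustness to artefacts the model excludes.

## Validation studies and problem sizes

The acceptance script and test suite use: 200 random diplotypes for
decomposition recovery; 20 simulated pedigrees (14 founders, 4 generations,
mean 2 offspring — ≈ 50–60 animals each) with no recombination or dropout
for phasing recovery (expected: zero incorrect resolved calls, ≥ 95%
resolution; observed resolution is 100% because every pool pair has a unique
union signature); and 500 forced single-crossover meioses for breakpoint
localization (observable chimeras must be localized to a minimal-explanation
interval set containing the true interval; unobservable ones must be called
non-recombinant). These sizes keep the full validation comfortably under a
minute while estimating the all-or-nothing recovery properties exactly.

## Known limitations and data caveats

* The bundled haplotype table contains one **pattern collision**: two
  haplotypes differing only in their *Mafa-A1* allele (031:01a vs 031:02,
  same *A2*) print identical D6S2854/D6S2859 patterns. This contradicts the
  accompanying uniqueness claim for A-region patterns; the fixture
  transcribes the table as printed, the collision is reported by
  `build_str_maps`, and the corresponding uniqueness check in the acceptance
  suite documents the discrepancy (it fails by design rather than hiding
  it). For typing, the collision means these two A-blocks are
  indistinguishable by STR alone and require sequencing or pedigree context.
* Several DRB alleles carry different printed D6S2878 lengths on different
  haplotypes (see STR typing above); the one-allele-one-length expectation
  holds only per haplotype.
* One haplotype's DRB copy is known only from its D6S2878 product and is
  stored unnamed; DR-block equality uses named alleles only.
* Catalog entries ship without nucleotide sequences (accessions are opaque
  identifiers), so the extension-contains-fragment invariant is enforced
  only for sequence-bearing catalogs such as those constructed in tests.
* The per-animal typing data behind the colony pool are not distributed;
  animal-level claims are validated by simulation, and two count statements
  in the source disagree (the prose "12 and 4 individuals" for haplotypes
  19/20 vs table counts 12 and 6); the fixture keeps the table counts, which
  sum to the stated totals (242/390).
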