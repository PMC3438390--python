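"""Diplotype inference by candidate decomposition and pedigree segregation.

Each animal's unphased genotype is first decomposed exhaustively against the
haplotype pool: an unordered pair of pool haplotypes (self-pairs included,
homozygotes are real) is a candidate iff, at every typed locus and STR marker,
the set-union of the pair's content reproduces the observation exactly
(not-determined haplotype content acts as a wildcard via a superset rule).
The pool is small (tens of haplotypes), so the search over all unordered
pairs is exact and cheap -- no heuristics.

Candidate sets are then pruned to a fixpoint with the transmission
constraint: a child's candidate pair must be splittable into one haplotype
carried by some surviving sire candidate and one carried by some surviving
dam candidate.  Missing parents impose no constraint.  Pruning is monotone
(sets only shrink), so the fixpoint is unique and independent of the order in
which animals are visited.

Animals whose candidate set empties out are reported ``inconsistent`` and are
the natural input for recombination analysis; an inconsistent parent is
treated as unconstraining so that its own conflict does not cascade into its
descendants' classifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Diplotype,
    GenotypeRecord,
    Haplotype,
    HaplotypePool,
    PedigreeGraph,
    block_match,
    genotype_from_diplotype,
)
from .regions import GENOTYPE_LOCI, RegionBlock, allele_locus

__all__ = [
    "CandidateSet",
    "AnimalPhase",
    "PhasedCohort",
    "MendelianResult",
    "diplotype_matches_record",
    "decompose_genotype",
    "phase_pedigree",
    "check_mendelian",
    "FounderInference",
    "infer_founder_haplotypes",
]

# Loci at which a single haplotype carries at most one allele; two observed
# alleles at such a locus must sit on different chromosomes.
SINGLE_COPY_LOCI = ("A1", "DRA", "DQA1", "DQB1", "DPA1", "DPB1")


# ---------------------------------------------------------------------------
# Candidate decomposition
# ---------------------------------------------------------------------------

def _sets_match(observed: frozenset, s1: Optional[frozenset],
                s2: Optional[frozenset]) -> bool:
    """Union-match with not-determined (None) wildcards.

    Both sides determined: the union must equal the observation exactly
    (absence is evidence).  One side undetermined: it may account for any
    surplus, so the observation must merely contain the determined side.
    """
    if s1 is None and s2 is None:
        return True
    if s1 is None:
        return observed >= s2
    if s2 is None:
        return observed >= s1
    return observed == (s1 | s2)


def _d6s2878_match(observed: frozenset[int], h1: Haplotype, h2: Haplotype) -> bool:
    certain = h1.d6s2878_certain() | h2.d6s2878_certain()
    if not certain <= observed:
        return False
    soft = h1.d6s2878_uncertain() | h2.d6s2878_uncertain()
    extra = observed - certain
    return all(any(abs(x - u) <= 2 for u in soft) for x in extra)


def diplotype_matches_record(
    d: Diplotype, record: GenotypeRecord, pool: HaplotypePool
) -> bool:
    """Whether a haplotype pair reproduces an observed genotype.

    Loci/markers absent from the record or flagged missing are wildcards.
    """
    h1, h2 = (pool.get(i) for i in d.pair)
    for locus in GENOTYPE_LOCI:
        if locus in record.missing or locus not in record.locus_alleles:
            continue
        s1 = None if h1.is_nd(locus) else h1.alleles_at(locus)
        s2 = None if h2.is_nd(locus) else h2.alleles_at(locus)
        if not _sets_match(record.locus_alleles[locus], s1, s2):
            return False
    for marker in ("D6S2854", "D6S2859"):
        if marker in record.missing or marker not in record.str_profile:
            continue
        if not _sets_match(record.str_profile[marker],
                           h1.marker_pattern(marker),
                           h2.marker_pattern(marker)):
            return False
    if "D6S2878" in record.str_profile and "D6S2878" not in record.missing:
        if not _d6s2878_match(record.str_profile["D6S2878"], h1, h2):
            return False
    return True


@dataclass
class CandidateSet:
    animal_id: str
    candidates: frozenset[Diplotype]

    def ranked(self, pool: HaplotypePool, cohort: str = "original") -> list[Diplotype]:
        """Candidates ordered (never filtered) by pool frequency, then id."""
        attr = "bprc_count" if cohort == "bprc" else "original_count"

        def weight(d: Diplotype) -> int:
            return sum(getattr(pool.get(i), attr) for i in d.pair)

        return sorted(self.candidates, key=lambda d: (-weight(d), d.pair))


def decompose_genotype(g: GenotypeRecord, pool: HaplotypePool) -> CandidateSet:
    """Exhaustive decomposition of a genotype into unordered pool pairs.

    Zero surviving candidates is not an error: the empty set flags the animal
    for recombination / novel-haplotype analysis.
    """
    if len(pool) == 0:
        raise ValueError("empty haplotype pool")
    cands = frozenset(
        Diplotype(pair)
        for pair in pool.unordered_pairs(include_self=True)
        if diplotype_matches_record(Diplotype(pair), g, pool)
    )
    return CandidateSet(animal_id=g.animal_id, candidates=cands)


# ---------------------------------------------------------------------------
# Pedigree propagation
# ---------------------------------------------------------------------------

@dataclass
class AnimalPhase:
    animal_id: str
    status: str  # resolved | ambiguous | inconsistent | untyped
    candidates: tuple[Diplotype, ...]
    typed_fraction: float
    notes: str = ""

    @property
    def diplotype(self) -> Optional[Diplotype]:
        return self.candidates[0] if self.status == "resolved" else None


@dataclass
class PhasedCohort:
    animals: dict[str, AnimalPhase]
    mendelian_errors: list[tuple[str, str, str]] = field(default_factory=list)

    def by_status(self, status: str) -> list[AnimalPhase]:
        return [a for a in self.animals.values() if a.status == status]

    def resolution_rate(self) -> float:
        """Resolved fraction among genotyped animals."""
        typed = [a for a in self.animals.values() if a.status != "untyped"]
        if not typed:
            return 0.0
        return sum(1 for a in typed if a.status == "resolved") / len(typed)


def _transmissible(pair: tuple[str, str],
                   sire_haps: Optional[frozenset[str]],
                   dam_haps: Optional[frozenset[str]]) -> bool:
    a, b = pair
    if sire_haps is None and dam_haps is None:
        return True
    if sire_haps is None:
        return a in dam_haps or b in dam_haps
    if dam_haps is None:
        return a in sire_haps or b in sire_haps
    return (a in sire_haps and b in dam_haps) or (b in sire_haps and a in dam_haps)


def phase_pedigree(
    genotypes: Mapping[str, GenotypeRecord],
    pedigree: PedigreeGraph,
    pool: HaplotypePool,
) -> PhasedCohort:
    """Phase a cohort by candidate decomposition plus transmission pruning.

    Animals present in the pedigree but not in ``genotypes`` are untyped
    carriers: they start with every pool pair as a candidate, so they relay
    constraints between their relatives without contributing observations.
    """
    for animal_id in genotypes:
        if animal_id not in pedigree:
            raise ValueError(f"genotyped animal {animal_id} absent from pedigree")

    all_pairs = frozenset(Diplotype(p) for p in pool.unordered_pairs())
    cands: dict[str, frozenset[Diplotype]] = {}
    typed: dict[str, bool] = {}
    for rec in pedigree:
        g = genotypes.get(rec.animal_id)
        typed[rec.animal_id] = g is not None
        cands[rec.animal_id] = (
            decompose_genotype(g, pool).candidates if g is not None else all_pairs
        )

    order = pedigree.topological_ids()
    changed = True
    while changed:
        changed = False
        for animal_id in order:
            rec = pedigree.get(animal_id)
            if rec.sire_id is None and rec.dam_id is None:
                continue

            def parent_haps(pid: Optional[str]) -> Optional[frozenset[str]]:
                if pid is None:
                    return None
                pc = cands[pid]
                if not pc:  # inconsistent parent: unconstraining
                    return None
                return frozenset(h for d in pc for h in d.pair)

            sire_haps = parent_haps(rec.sire_id)
            dam_haps = parent_haps(rec.dam_id)
            pruned = frozenset(
                d for d in cands[animal_id]
                if _transmissible(d.pair, sire_haps, dam_haps)
            )
            if pruned != cands[animal_id]:
                cands[animal_id] = pruned
                changed = True

    animals: dict[str, AnimalPhase] = {}
    for rec in pedigree:
        aid = rec.animal_id
        cset = sorted(cands[aid], key=lambda d: d.pair)
        if not typed[aid]:
            status, notes = "untyped", "no genotype record; constraint carrier"
        elif len(cset) == 1:
            status, notes = "resolved", ""
        elif len(cset) == 0:
            status = "inconsistent"
            notes = "no pool pair fits; candidate for recombination analysis"
        else:
            status, notes = "ambiguous", f"{len(cset)} candidate diplotypes"
        tf = genotypes[aid].typed_fraction() if typed[aid] else 0.0
        animals[aid] = AnimalPhase(aid, status, tuple(cset), tf, notes)

    cohort = PhasedCohort(animals=animals)
    for rec in pedigree:
        child = animals[rec.animal_id]
        if child.status != "resolved" or rec.sire_id is None or rec.dam_id is None:
            continue
        sire, dam = animals[rec.sire_id], animals[rec.dam_id]
        if sire.status != "resolved" or dam.status != "resolved":
            continue
        res = check_mendelian(child.diplotype, sire.diplotype, dam.diplotype, pool)
        if not res.consistent:
            cohort.mendelian_errors.append(
                (rec.animal_id, ",".join(str(b) for b in res.violating_blocks),
                 res.detail)
            )
    return cohort


# ---------------------------------------------------------------------------
# Mendelian check
# ---------------------------------------------------------------------------

@dataclass
class MendelianResult:
    consistent: bool
    violating_blocks: tuple[RegionBlock, ...] = ()
    # child haplotype id -> block -> parental haplotype ids whose block matches
    block_report: dict[str, dict[RegionBlock, tuple[str, ...]]] = field(
        default_factory=dict
    )
    detail: str = ""


def check_mendelian(
    child: Diplotype, sire: Diplotype, dam: Diplotype, pool: HaplotypePool
) -> MendelianResult:
    """Check a trio for Mendelian consistency at haplotype resolution.

    Consistent iff the child's pair can be ordered so the first haplotype is
    carried by the sire and the second by the dam.  On violation, the report
    lists, for each child haplotype, which parental haplotype matches each
    region block -- the starting point for a crossover explanation.
    """
    a, b = child.pair
    s, d = set(sire.pair), set(dam.pair)
    if (a in s and b in d) or (b in s and a in d):
        return MendelianResult(consistent=True)

    parent_ids = list(dict.fromkeys([*sire.pair, *dam.pair]))
    report: dict[str, dict[RegionBlock, tuple[str, ...]]] = {}
    violating: set[RegionBlock] = set()
    for hap_id in dict.fromkeys(child.pair):
        if hap_id in s or hap_id in d:
            continue  # this haplotype itself is transmissible
        hap = pool.get(hap_id)
        per_block: dict[RegionBlock, tuple[str, ...]] = {}
        for block in RegionBlock:
            matches = tuple(
                pid for pid in parent_ids
                if block_match(hap, pool.get(pid), block, donor_wildcards=True)[0]
            )
            per_block[block] = matches
            if not matches:
                violating.add(block)
        report[hap_id] = per_block
    if not report:
        # every child haplotype is carried by a parent, but not split one per
        # parent (e.g. a homozygote whose haplotype only one parent carries)
        detail = (
            f"child {child} not splittable one haplotype per parent "
            f"(sire {sire}, dam {dam})"
        )
        return MendelianResult(consistent=False, detail=detail)
    detail = "; ".join(
        f"child haplotype {hid}: "
        + ", ".join(
            f"{blk.name}<-{('/'.join(m) if m else 'none')}"
            for blk, m in per.items()
        )
        for hid, per in report.items()
    )
    return MendelianResult(
        consistent=False,
        violating_blocks=tuple(sorted(violating)),
        block_report=report,
        detail=detail,
    )


# ---------------------------------------------------------------------------
# Founder haplotype reconstruction
# ---------------------------------------------------------------------------

@dataclass
class FounderInference:
    founder_id: str
    consistent: bool
    bipartitions: list[tuple[frozenset[str], frozenset[str]]]
    note: str = ""

    @property
    def unique(self) -> bool:
        return self.consistent and len(self.bipartitions) == 1


def infer_founder_haplotypes(
    founder_id: str,
    genotypes: Mapping[str, GenotypeRecord],
    pedigree: PedigreeGraph,
    pool: Optional[HaplotypePool] = None,
    max_bipartitions: int = 64,
) -> FounderInference:
    """Reconstruct a founder's two haplotypes from offspring segregation.

    Every assignment of genotyped offspring to the two transmitted founder
    haplotypes is enumerated (offspring numbers are small, so this is exact).
    Within an assignment, evidence is propagated per allele: a founder allele
    present in an offspring but absent from the offspring's other typed
    parent was received (it sits on the transmitted side); a founder allele
    missing from a typed offspring locus is off the transmitted side; at a
    locus where a haplotype carries at most one allele, two observed founder
    alleles occupy opposite sides.  Alleles placed on both sides by evidence
    are treated as shared (the founder is homozygous for them); alleles with
    no evidence are enumerated over the two exclusive placements.  All
    distinct consistent bipartitions are returned; exactly one means the
    founder is resolved, none flags the founder for recombination analysis,
    and more than ``max_bipartitions`` is reported as too ambiguous.

    ``pool`` is accepted for interface symmetry but unused: reconstruction is
    deliberately pool-free (the point is to propose haplotypes not yet in the
    pool).
    """
    rec = genotypes.get(founder_id)
    if rec is None:
        raise ValueError(f"founder {founder_id} has no genotype record")
    offspring = [c for c in pedigree.children_of(founder_id) if c in genotypes]
    if not offspring:
        raise ValueError(f"founder {founder_id} has no genotyped offspring")

    allele_locus_map: dict[str, str] = {}
    for locus, names in rec.locus_alleles.items():
        for n in names:
            allele_locus_map[n] = locus
    alleles = sorted(allele_locus_map)
    single_copy_pairs = [
        tuple(sorted(rec.locus_alleles[locus]))
        for locus in SINGLE_COPY_LOCI
        if len(rec.locus_alleles.get(locus, frozenset())) == 2
    ]

    received_ev: dict[str, set[str]] = {}
    absent_ev: dict[str, set[str]] = {}
    for child_id in offspring:
        child = genotypes[child_id]
        crec = pedigree.get(child_id)
        other_id = crec.dam_id if crec.sire_id == founder_id else crec.sire_id
        other = genotypes.get(other_id) if other_id is not None else None
        got: set[str] = set()
        miss: set[str] = set()
        for locus, fnames in rec.locus_alleles.items():
            if locus in child.missing or locus not in child.locus_alleles:
                continue
            cnames = child.locus_alleles[locus]
            for a in fnames:
                if a not in cnames:
                    miss.add(a)
                elif (other is not None and locus in other.locus_alleles
                        and a not in other.locus_alleles[locus]):
                    got.add(a)
        received_ev[child_id] = got
        absent_ev[child_id] = miss

    seen: set[tuple[frozenset[str], frozenset[str]]] = set()
    overflow = False
    for mask in range(2 ** max(len(offspring) - 1, 0)):
        side_of = {offspring[0]: 0}
        for i, child_id in enumerate(offspring[1:]):
            side_of[child_id] = (mask >> i) & 1
        on: tuple[set[str], set[str]] = (set(), set())
        off: tuple[set[str], set[str]] = (set(), set())
        for child_id in offspring:
            s = side_of[child_id]
            on[s].update(received_ev[child_id])
            off[s].update(absent_ev[child_id])
        # propagate to fixpoint: an allele off one side must be on the other
        # (it was observed in the founder); at a single-copy locus each side
        # carries exactly one of the two observed alleles.
        changed = True
        while changed:
            changed = False
            for s in (0, 1):
                for a in list(off[s]):
                    if a not in on[1 - s]:
                        on[1 - s].add(a)
                        changed = True
            for a, b in single_copy_pairs:
                for s in (0, 1):
                    for x, y in ((a, b), (b, a)):
                        if x in on[s] and y not in off[s]:
                            off[s].add(y)
                            changed = True
                        if x in off[s] and y not in on[s]:
                            on[s].add(y)
                            changed = True
        if (on[0] & off[0]) or (on[1] & off[1]):
            continue  # contradictory offspring assignment
        free = [a for a in alleles if a not in on[0] and a not in on[1]]
        if 2 ** len(free) > 4 * max_bipartitions:
            overflow = True
            continue
        for fmask in range(2 ** len(free)):
            part0, part1 = set(on[0]), set(on[1])
            bad = False
            for i, a in enumerate(free):
                s = (fmask >> i) & 1
                if a in off[s]:
                    bad = True
                    break
                (part0 if s == 0 else part1).add(a)
            if bad:
                continue
            key = tuple(sorted(
                (frozenset(part0), frozenset(part1)), key=lambda p: sorted(p)
            ))
            seen.add((key[0], key[1]))
            if len(seen) > max_bipartitions:
                overflow = True
                break
        if overflow and len(seen) > max_bipartitions:
            break

    if overflow and len(seen) > max_bipartitions:
        return FounderInference(
            founder_id, True, [],
            note="too many consistent bipartitions to enumerate; need more "
                 "informative offspring",
        )
    if not seen:
        return FounderInference(
            founder_id, False, [],
            note="segregation constraints are contradictory; possible "
                 "recombination or genotyping error",
        )
    out = sorted(seen, key=lambda pair: (sorted(pair[0]), sorted(pair[1])))
    return FounderInference(founder_id, True, list(out), note="")
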