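"""Domain types: alleles, haplotypes, genotypes, pedigrees, diplotypes.

The central objects are :class:`Haplotype` (the allele content of one
chromosome, organised by region block, plus its microsatellite patterns and
cohort counts) and :class:`GenotypeRecord` (one animal's *unphased* typing
data: per locus, the set-union of its two haplotypes' alleles; per STR marker,
the union of the two fragment-length patterns).

Observation semantics
---------------------
Typing reports presence, not dosage, so all observed sets are plain sets:
homozygous contributions collapse.  Three distinct states are modelled:

* a non-empty observed set        -- alleles/fragments detected;
* an empty observed set           -- a determinate negative (no allele at a
                                     locus the haplotype lacks, or a
                                     reproducible null STR pattern);
* not determined (``nd``)         -- the assay failed or was not run; treated
                                     as a wildcard by all matching logic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

from .regions import (
    BLOCK_LOCI,
    GENOTYPE_LOCI,
    RegionBlock,
    STR_MARKERS,
    allele_locus,
    normalize_allele_name,
    parse_allele_name,
)

__all__ = [
    "Allele",
    "AlleleCatalog",
    "STRPattern",
    "DRBEntry",
    "Haplotype",
    "HaplotypePool",
    "GenotypeRecord",
    "AnimalRecord",
    "PedigreeGraph",
    "Diplotype",
    "genotype_from_diplotype",
    "block_match",
]

COMPLETENESS_LEVELS = ("full-length", "exon2-plus", "exon2-only", "lineage-only")
STATUS_LEVELS = ("known", "novel", "extension", "unassessed")
VALID_LOCI = (
    "A1", "A2", "A4", "A5", "I", "B",
    "DRA", "DRB", "DRB1", "DRB3", "DRB4", "DRB5", "DRB6",
    "DQA1", "DQB1", "DPA1", "DPB1",
)


# ---------------------------------------------------------------------------
# Alleles and the catalog
# ---------------------------------------------------------------------------

@dataclass
class Allele:
    """One named MHC allele.

    ``sequence`` is optional: the bundled catalog carries accessions as opaque
    metadata rather than nucleotide sequences.  ``transcribed`` is only
    meaningful for DRB entries (full-length RNA sequencing evidence).
    """

    name: str
    locus: str
    sequence: Optional[str] = None
    completeness: str = "full-length"
    status: str = "known"
    origins: frozenset[str] = frozenset()
    transcribed: Optional[bool] = None
    accession: Optional[str] = None
    reference_animal: Optional[str] = None

    def __post_init__(self) -> None:
        self.name = normalize_allele_name(self.name)
        parse_allele_name(self.name)  # raises on malformed names
        if self.locus not in VALID_LOCI:
            raise ValueError(f"{self.name}: unknown locus {self.locus!r}")
        if self.completeness not in COMPLETENESS_LEVELS:
            raise ValueError(f"{self.name}: bad completeness {self.completeness!r}")
        if self.status not in STATUS_LEVELS:
            raise ValueError(f"{self.name}: bad status {self.status!r}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
        self.origins = frozenset(self.origins)


class AlleleCatalog:
    """Registry of alleles, unique by name, indexed by locus."""

    def __init__(self, alleles: Iterable[Allele] = ()) -> None:
        self._by_name: dict[str, Allele] = {}
        for a in alleles:
            self.add(a)

    def add(self, allele: Allele) -> None:
        if allele.name in self._by_name:
            raise ValueError(f"duplicate allele name: {allele.name}")
        self._by_name[allele.name] = allele

    def register_stub(self, name: str) -> Allele:
        """Register a bare name (e.g. seen in a haplotype file) if absent."""
        name = normalize_allele_name(name)
        if name in self._by_name:
            return self._by_name[name]
        locus, _ = parse_allele_name(name)
        stub = Allele(name=name, locus=locus, status="unassessed",
                      completeness="lineage-only" if len(parse_allele_name(name)[1]) == 1
                      else "full-length")
        self._by_name[name] = stub
        return stub

    def get(self, name: str) -> Optional[Allele]:
        return self._by_name.get(normalize_allele_name(name))

    def by_locus(self, locus: str) -> list[Allele]:
        return [a for a in self._by_name.values() if a.locus == locus]

    def __contains__(self, name: str) -> bool:
        return normalize_allele_name(name) in self._by_name

    def __iter__(self) -> Iterator[Allele]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def validate_extensions(self) -> None:
        """Check the extension invariant on sequence-bearing catalogs.

        Every ``status="extension"`` allele with a sequence must strictly
        contain some exon2-only catalog sequence at the same locus.
        """
        for a in self._by_name.values():
            if a.status != "extension" or a.sequence is None:
                continue
            fragments = [
                b for b in self.by_locus(a.locus)
                if b.completeness == "exon2-only" and b.sequence
            ]
            if not any(b.sequence in a.sequence and b.sequence != a.sequence
                       for b in fragments):
                raise ValueError(
                    f"{a.name}: extension without a matching exon2-only "
                    f"fragment at locus {a.locus}"
                )


# ---------------------------------------------------------------------------
# STR patterns and haplotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class STRPattern:
    """Fragment-length pattern of one microsatellite on one haplotype.

    ``lengths`` is a frozenset of sizes in bp; the empty set is a reproducible
    null pattern (no amplification product) and is informative, while ``None``
    means the marker was not determined for this haplotype.
    """

    marker: str
    lengths: Optional[frozenset[int]]

    def __post_init__(self) -> None:
        if self.lengths is not None:
            object.__setattr__(self, "lengths", frozenset(int(x) for x in self.lengths))
            if any(x <= 0 for x in self.lengths):
                raise ValueError(f"{self.marker}: non-positive fragment length")

    @property
    def is_nd(self) -> bool:
        return self.lengths is None


@dataclass(frozen=True)
class DRBEntry:
    """One DRB gene copy on a haplotype.

    ``allele`` may be ``None`` for a copy whose sequence identity is unknown
    but whose D6S2878 intron-2 fragment length was observed.  ``d6s2878`` is
    ``None`` when no length was determined; ``uncertain_length`` marks lengths
    the source flags as tentative (excluded from hard matching, soft-matched
    within 2 bp).
    """

    allele: Optional[str]
    transcribed: bool = False
    d6s2878: Optional[int] = None
    uncertain_length: bool = False


@dataclass
class Haplotype:
    """Allele content of one chromosome, organised by region block."""

    id: str
    locus_alleles: dict[str, frozenset[str]]
    drb: tuple[DRBEntry, ...] = ()
    nd_loci: frozenset[str] = frozenset()
    uncertain_alleles: dict[str, frozenset[str]] = field(default_factory=dict)
    d6s2854: STRPattern = STRPattern("D6S2854", frozenset())
    d6s2859: STRPattern = STRPattern("D6S2859", frozenset())
    bprc_count: int = 0
    original_count: int = 0

    def __post_init__(self) -> None:
        if self.bprc_count < 0 or self.original_count < 0:
            raise ValueError(f"haplotype {self.id}: negative count")
        clean: dict[str, frozenset[str]] = {}
        for locus, names in self.locus_alleles.items():
            if locus not in GENOTYPE_LOCI or locus == "DRB":
                raise ValueError(f"haplotype {self.id}: bad locus {locus!r}")
            clean[locus] = frozenset(normalize_allele_name(n) for n in names)
        self.locus_alleles = clean
        self.nd_loci = frozenset(self.nd_loci)
        self.uncertain_alleles = {
            k: frozenset(normalize_allele_name(n) for n in v)
            for k, v in self.uncertain_alleles.items()
        }

    # -- content accessors --------------------------------------------------

    def alleles_at(self, locus: str) -> frozenset[str]:
        """Determined allele names at a genotype locus (``DRB`` = named copies)."""
        if locus == "DRB":
            return frozenset(e.allele for e in self.drb if e.allele is not None)
        return self.locus_alleles.get(locus, frozenset())

    def is_nd(self, key: str) -> bool:
        """Whether a locus or STR marker is not determined on this haplotype."""
        if key == "D6S2854":
            return self.d6s2854.is_nd
        if key == "D6S2859":
            return self.d6s2859.is_nd
        if key == "D6S2878":
            return False  # per-copy lengths; unknowns handled per entry
        return key in self.nd_loci or key in self.uncertain_alleles

    def marker_pattern(self, marker: str) -> Optional[frozenset[int]]:
        if marker == "D6S2854":
            return self.d6s2854.lengths
        if marker == "D6S2859":
            return self.d6s2859.lengths
        if marker == "D6S2878":
            return self.d6s2878_certain()
        raise KeyError(marker)

    def d6s2878_certain(self) -> frozenset[int]:
        return frozenset(
            e.d6s2878 for e in self.drb
            if e.d6s2878 is not None and not e.uncertain_length
        )

    def d6s2878_uncertain(self) -> frozenset[int]:
        return frozenset(
            e.d6s2878 for e in self.drb
            if e.d6s2878 is not None and e.uncertain_length
        )

    def block_alleles(self, block: RegionBlock) -> frozenset[str]:
        out: set[str] = set()
        for locus in BLOCK_LOCI[block]:
            out |= self.alleles_at(locus)
        return frozenset(out)

    def block_alleles_by_loci(self, loci: Sequence[str]) -> frozenset[str]:
        out: set[str] = set()
        for locus in loci:
            out |= self.alleles_at(locus)
        return frozenset(out)

    def a_signature(self) -> frozenset[str]:
        """A-block signature: the set of A-region allele names."""
        return self.block_alleles(RegionBlock.A)

    def all_allele_names(self) -> frozenset[str]:
        out: set[str] = set()
        for block in RegionBlock:
            out |= self.block_alleles(block)
        return frozenset(out)


class HaplotypePool:
    """Collection of haplotypes, unique by id."""

    def __init__(self, haplotypes: Iterable[Haplotype] = ()) -> None:
        self._by_id: dict[str, Haplotype] = {}
        for h in haplotypes:
            self.add(h)

    def add(self, hap: Haplotype) -> None:
        if hap.id in self._by_id:
            raise ValueError(f"duplicate haplotype id: {hap.id}")
        self._by_id[hap.id] = hap

    def get(self, hap_id: str) -> Haplotype:
        return self._by_id[str(hap_id)]

    def __contains__(self, hap_id: str) -> bool:
        return str(hap_id) in self._by_id

    def __iter__(self) -> Iterator[Haplotype]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def ids(self) -> list[str]:
        return list(self._by_id)

    def unordered_pairs(self, include_self: bool = True) -> Iterator[tuple[str, str]]:
        """All unordered id pairs (self-pairs included: homozygotes are legal)."""
        ids = self.ids
        for i, a in enumerate(ids):
            for b in ids[i if include_self else i + 1:]:
                yield (a, b)


# ---------------------------------------------------------------------------
# Genotypes and diplotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeRecord:
    """One animal's unphased typing data.

    ``locus_alleles`` maps genotype loci to observed allele-name sets (empty =
    determinate absence), ``str_profile`` maps STR markers to observed length
    sets (empty = null pattern), and ``missing`` lists loci/markers that were
    not determined.
    """

    animal_id: str
    locus_alleles: dict[str, frozenset[str]] = field(default_factory=dict)
    str_profile: dict[str, frozenset[int]] = field(default_factory=dict)
    missing: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.locus_alleles = {
            k: frozenset(normalize_allele_name(n) for n in v)
            for k, v in self.locus_alleles.items()
        }
        self.str_profile = {
            k: frozenset(int(x) for x in v) for k, v in self.str_profile.items()
        }
        self.missing = frozenset(self.missing)
        overlap = (set(self.locus_alleles) | set(self.str_profile)) & self.missing
        if overlap:
            raise ValueError(
                f"{self.animal_id}: {sorted(overlap)} both observed and missing"
            )

    def typed_fraction(self) -> float:
        """Fraction of loci+markers with an observation (quality field)."""
        total = len(GENOTYPE_LOCI) + len(STR_MARKERS)
        typed = sum(1 for k in (*GENOTYPE_LOCI, *STR_MARKERS)
                    if k in self.locus_alleles or k in self.str_profile)
        return typed / total


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of haplotype ids."""

    pair: tuple[str, str]
    provenance: str = "inferred"  # observed | inferred | simulated

    def __post_init__(self) -> None:
        a, b = self.pair
        object.__setattr__(self, "pair", tuple(sorted((str(a), str(b)))))

    @property
    def is_homozygous(self) -> bool:
        return self.pair[0] == self.pair[1]

    def __iter__(self) -> Iterator[str]:
        return iter(self.pair)

    def __str__(self) -> str:
        return f"({self.pair[0]},{self.pair[1]})"


def genotype_from_diplotype(
    d: Diplotype, pool: HaplotypePool, animal_id: str = "?"
) -> GenotypeRecord:
    """Observed genotype of a diplotype: per-locus/per-marker set union.

    Shared alleles collapse (set semantics).  A locus or A-region marker that
    is not determined on *both* haplotypes is reported missing; if only one
    side is undetermined, the union of the determined side is reported (the
    matching logic compensates with a superset rule).  D6S2878 lengths flagged
    uncertain are never emitted.
    """
    h1, h2 = (pool.get(i) for i in d.pair)
    locus_alleles: dict[str, frozenset[str]] = {}
    missing: set[str] = set()
    for locus in GENOTYPE_LOCI:
        if h1.is_nd(locus) and h2.is_nd(locus):
            missing.add(locus)
            continue
        locus_alleles[locus] = h1.alleles_at(locus) | h2.alleles_at(locus)
    str_profile: dict[str, frozenset[int]] = {}
    for marker in ("D6S2854", "D6S2859"):
        p1, p2 = h1.marker_pattern(marker), h2.marker_pattern(marker)
        if p1 is None and p2 is None:
            missing.add(marker)
            continue
        str_profile[marker] = (p1 or frozenset()) | (p2 or frozenset())
    str_profile["D6S2878"] = h1.d6s2878_certain() | h2.d6s2878_certain()
    return GenotypeRecord(
        animal_id=animal_id,
        locus_alleles=locus_alleles,
        str_profile=str_profile,
        missing=frozenset(missing),
    )


# ---------------------------------------------------------------------------
# Block-level comparison (recombination analysis)
# ---------------------------------------------------------------------------

def block_match(
    child: Haplotype,
    donor: Haplotype,
    block: RegionBlock,
    donor_wildcards: bool = False,
) -> tuple[bool, bool]:
    """Does ``donor``'s ``block`` equal ``child``'s?

    Returns ``(matched, used_wildcard)``.  Comparison is per locus on allele
    name sets; the A block additionally compares the D6S2854/D6S2859 patterns
    (they reside in the A region); DR-block equality requires the same DRA
    allele and the same set of named DRB alleles -- D6S2878 lengths are
    allele-linked and therefore not compared.

    A not-determined component on the *child* side is a wildcard (the child's
    content is unknown, so any donor is compatible).  A not-determined donor
    component only matches when ``donor_wildcards`` is true: by default an
    undetermined donor block is not accepted as positive evidence for a
    chimera call.
    """
    used_wildcard = False
    for locus in BLOCK_LOCI[block]:
        if child.is_nd(locus):
            used_wildcard = True
            continue
        if donor.is_nd(locus):
            if donor_wildcards:
                used_wildcard = True
                continue
            return False, used_wildcard
        if child.alleles_at(locus) != donor.alleles_at(locus):
            return False, used_wildcard
    if block is RegionBlock.A:
        for marker in ("D6S2854", "D6S2859"):
            pc = child.marker_pattern(marker)
            pd = donor.marker_pattern(marker)
            if pc is None:
                used_wildcard = True
                continue
            if pd is None:
                if donor_wildcards:
                    used_wildcard = True
                    continue
                return False, used_wildcard
            if pc != pd:
                return False, used_wildcard
    return True, used_wildcard


def haplotypes_block_equal(h1: Haplotype, h2: Haplotype) -> bool:
    """Exact block-wise equality of two haplotypes (wildcards on either side)."""
    return all(block_match(h1, h2, b, donor_wildcards=True)[0] for b in RegionBlock)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnimalRecord:
    animal_id: str
    sire_id: Optional[str]
    dam_id: Optional[str]
    sex: str = "U"  # M | F | U
    matriline: Optional[str] = None


class PedigreeGraph:
    """Parent-offspring structure; founders have both parents absent."""

    def __init__(self, animals: Iterable[AnimalRecord]) -> None:
        self._animals: dict[str, AnimalRecord] = {}
        self._graph = nx.DiGraph()
        for rec in animals:
            if rec.animal_id in self._animals:
                raise ValueError(f"duplicate animal id: {rec.animal_id}")
            self._animals[rec.animal_id] = rec
            self._graph.add_node(rec.animal_id)
        for rec in self._animals.values():
            for parent in (rec.sire_id, rec.dam_id):
                if parent is None:
                    continue
                if parent not in self._animals:
                    raise ValueError(
                        f"{rec.animal_id}: parent {parent!r} not in pedigree"
                    )
                self._graph.add_edge(parent, rec.animal_id)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise ValueError(f"pedigree contains a cycle: {cycle}")

    def __iter__(self) -> Iterator[AnimalRecord]:
        return iter(self._animals.values())

    def __len__(self) -> int:
        return len(self._animals)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._animals

    def get(self, animal_id: str) -> AnimalRecord:
        return self._animals[animal_id]

    def founders(self) -> list[AnimalRecord]:
        return [a for a in self._animals.values()
                if a.sire_id is None and a.dam_id is None]

    def children_of(self, animal_id: str) -> list[str]:
        return sorted(self._graph.successors(animal_id))

    def topological_ids(self) -> list[str]:
        """Animal ids ordered parents-before-children (lexicographic ties)."""
        return list(nx.lexicographical_topological_sort(self._graph))

    def matrilines(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in self._animals.values():
            if a.matriline is not None:
                out.setdefault(a.matriline, []).append(a.animal_id)
        return {k: sorted(v) for k, v in out.items()}
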