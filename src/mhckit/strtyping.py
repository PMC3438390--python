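"""Microsatellite-based fast typing.

Two STR systems make routine offspring screening possible without
sequencing: the D6S2854/D6S2859 multiplex, whose joint fragment-length
pattern tags the A-region content of a haplotype, and D6S2878 (DRB intron 2),
whose length is linked to the individual DRB allele carried.

The maps built here associate each A-block signature (the set of A-region
allele names) with its pattern pair, and each DRB allele with its observed
D6S2878 length(s).  Typing an animal is then an exhaustive search over
signature pairs (or, with phased parents, over the at most four transmissible
diplotypes) whose predicted pattern unions reproduce the observed profile;
zero survivors is the escalation signal for sequencing (possible crossover or
novel haplotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import Diplotype, GenotypeRecord, Haplotype, HaplotypePool
from .phasing import check_mendelian

__all__ = [
    "ASTRMap",
    "DRBSTRMap",
    "build_str_maps",
    "STRDecomposition",
    "decompose_str_profile",
    "FastTypeResult",
    "fast_type_offspring",
]

PatternPair = tuple[Optional[frozenset[int]], Optional[frozenset[int]]]


@dataclass
class ASTRMap:
    """A-block signature -> (D6S2854 pattern, D6S2859 pattern), plus reverse index.

    ``collisions`` lists pairs of *distinct* signatures that share a fully
    determined pattern pair -- violations of the one-pattern-per-A-haplotype
    expectation, reported rather than fatal.
    """

    forward: dict[frozenset[str], PatternPair] = field(default_factory=dict)
    reverse: dict[PatternPair, tuple[frozenset[str], ...]] = field(
        default_factory=dict
    )
    collisions: list[tuple[frozenset[str], frozenset[str]]] = field(
        default_factory=list
    )

    def signatures(self) -> list[frozenset[str]]:
        return list(self.forward)

    def is_injective(self) -> bool:
        return not self.collisions


@dataclass
class DRBSTRMap:
    """DRB allele -> observed D6S2878 lengths.

    ``certain`` holds firm lengths, ``uncertain`` tentatively printed ones
    (soft-matched within 2 bp).  ``conflicts`` lists alleles observed with
    more than one distinct firm length on different haplotypes.
    """

    certain: dict[str, frozenset[int]] = field(default_factory=dict)
    uncertain: dict[str, frozenset[int]] = field(default_factory=dict)
    conflicts: dict[str, frozenset[int]] = field(default_factory=dict)

    def length_of(self, allele: str) -> Optional[int]:
        """The unique firm length of an allele, or None if absent/conflicted."""
        lengths = self.certain.get(allele, frozenset())
        return next(iter(lengths)) if len(lengths) == 1 else None


def build_str_maps(
    pool: HaplotypePool, strict: bool = False
) -> tuple[ASTRMap, DRBSTRMap]:
    """Learn the STR association maps from a haplotype pool.

    Distinct signatures sharing one fully determined pattern pair are recorded
    as collisions (not fatal).  A DRB allele observed with conflicting firm
    lengths is recorded under ``conflicts``; with ``strict=True`` this is a
    hard error instead.  Two haplotypes with the same A-block signature but
    different patterns would make the forward map ill-defined and always
    raise.
    """
    a_map = ASTRMap()
    for hap in pool:
        sig = hap.a_signature()
        pair: PatternPair = (hap.d6s2854.lengths, hap.d6s2859.lengths)
        if sig in a_map.forward and a_map.forward[sig] != pair:
            raise ValueError(
                f"A-block signature {sorted(sig)} maps to two different "
                f"pattern pairs (haplotype {hap.id})"
            )
        a_map.forward[sig] = pair
    for sig, pair in a_map.forward.items():
        if pair[0] is None or pair[1] is None:
            continue  # undetermined pairs cannot participate in uniqueness
        a_map.reverse.setdefault(pair, ())
        a_map.reverse[pair] = (*a_map.reverse[pair], sig)
    for pair, sigs in a_map.reverse.items():
        for i, s1 in enumerate(sigs):
            for s2 in sigs[i + 1:]:
                a_map.collisions.append((s1, s2))

    drb_map = DRBSTRMap()
    for hap in pool:
        for e in hap.drb:
            if e.allele is None or e.d6s2878 is None:
                continue
            key = "uncertain" if e.uncertain_length else "certain"
            store = getattr(drb_map, key)
            store[e.allele] = store.get(e.allele, frozenset()) | {e.d6s2878}
    for allele, lengths in drb_map.certain.items():
        if len(lengths) > 1:
            if strict:
                raise ValueError(
                    f"DRB allele {allele} carries conflicting D6S2878 "
                    f"lengths {sorted(lengths)}"
                )
            drb_map.conflicts[allele] = lengths
    return a_map, drb_map


# ---------------------------------------------------------------------------
# Profile decomposition
# ---------------------------------------------------------------------------

def _lengths_match(
    observed: frozenset[int],
    certain: Optional[frozenset[int]],
    uncertain: frozenset[int] = frozenset(),
    tolerance: int = 0,
) -> bool:
    """Tolerant set comparison between an observed length set and a prediction.

    ``certain=None`` means the prediction is undetermined on one side: only
    containment of the determined part is required (handled by the caller
    passing the union of determined content).  Firm predicted lengths must all
    be observed (within ``tolerance``); every observed length must be
    explained by a firm prediction (within ``tolerance``) or by an uncertain
    one (within max(tolerance, 2) bp).
    """
    if certain is None:
        return True
    soft_tol = max(tolerance, 2)
    for p in certain:
        if not any(abs(o - p) <= tolerance for o in observed):
            return False
    for o in observed:
        if any(abs(o - p) <= tolerance for p in certain):
            continue
        if any(abs(o - u) <= soft_tol for u in uncertain):
            continue
        return False
    return True


def _pair_pattern_match(
    observed: frozenset[int],
    p1: Optional[frozenset[int]],
    p2: Optional[frozenset[int]],
    tolerance: int,
) -> bool:
    if p1 is None and p2 is None:
        return True
    if p1 is None or p2 is None:
        known = p1 if p1 is not None else p2
        # undetermined side may account for any surplus
        return all(any(abs(o - p) <= tolerance for o in observed) for p in known)
    return _lengths_match(observed, p1 | p2, frozenset(), tolerance)


@dataclass
class STRDecomposition:
    candidates: list[tuple[frozenset[str], frozenset[str]]]
    flagged: bool = False  # no candidate: possible novel/recombinant A haplotype
    note: str = ""


def decompose_str_profile(
    profile: Mapping[str, Optional[frozenset[int]]],
    a_map: ASTRMap,
    parental_constraint: Optional[tuple[Diplotype, Diplotype]] = None,
    pool: Optional[HaplotypePool] = None,
    tolerance: int = 0,
) -> STRDecomposition:
    """Decompose a D6S2854/D6S2859 profile into A-block signature pairs.

    Exhaustive over unordered signature pairs whose per-marker pattern union
    matches the observation.  With a parental constraint (two phased parents),
    only signature pairs transmissible from them are considered; ``pool`` is
    then required to resolve haplotype ids to signatures.
    """
    obs54 = profile.get("D6S2854")
    obs59 = profile.get("D6S2859")
    if obs54 is None and obs59 is None:
        raise ValueError("profile contains neither D6S2854 nor D6S2859")

    if parental_constraint is not None:
        if pool is None:
            raise ValueError("pool required with a parental constraint")
        sire, dam = parental_constraint
        sig_pairs = {
            tuple(sorted(
                (pool.get(s).a_signature(), pool.get(d).a_signature()),
                key=lambda x: sorted(x),
            ))
            for s in sire.pair for d in dam.pair
        }
        pairs = sorted(sig_pairs, key=lambda p: (sorted(p[0]), sorted(p[1])))
    else:
        sigs = sorted(a_map.forward, key=lambda s: sorted(s))
        pairs = [(s1, s2) for i, s1 in enumerate(sigs) for s2 in sigs[i:]]

    out: list[tuple[frozenset[str], frozenset[str]]] = []
    for s1, s2 in pairs:
        ok = True
        for obs, idx in ((obs54, 0), (obs59, 1)):
            if obs is None:
                continue
            p1 = a_map.forward[s1][idx]
            p2 = a_map.forward[s2][idx]
            if not _pair_pattern_match(obs, p1, p2, tolerance):
                ok = False
                break
        if ok:
            out.append((s1, s2))
    if not out:
        return STRDecomposition(
            candidates=[], flagged=True,
            note="no signature pair fits: possible novel or recombinant "
                 "A haplotype",
        )
    return STRDecomposition(candidates=out)


# ---------------------------------------------------------------------------
# Offspring fast typing
# ---------------------------------------------------------------------------

@dataclass
class FastTypeResult:
    status: str  # call | ambiguous | crossover-flag
    candidates: tuple[Diplotype, ...]
    note: str = ""

    @property
    def call(self) -> Optional[Diplotype]:
        return self.candidates[0] if self.status == "call" else None


def fast_type_offspring(
    child_profile: Mapping[str, Optional[frozenset[int]]],
    drb_lengths: Optional[frozenset[int]],
    sire: Optional[Diplotype],
    dam: Optional[Diplotype],
    pool: HaplotypePool,
    tolerance: int = 0,
) -> FastTypeResult:
    """Type an offspring from its STR profile and its parents' diplotypes.

    The at most four transmissible diplotypes are screened against the
    observed D6S2854/D6S2859 unions and the observed D6S2878 length set.  One
    survivor is a call; several are reported as an ambiguity; zero survivors
    raise the crossover flag -- the recommendation to sequence the animal.
    Every call is transmissible by construction and therefore Mendelian
    consistent.
    """
    for name, parent in (("sire", sire), ("dam", dam)):
        if parent is None:
            raise ValueError(f"{name} is not phased; fast typing needs both "
                             "parental diplotypes")
    candidates = sorted(
        {Diplotype((s, d)) for s in sire.pair for d in dam.pair},
        key=lambda d: d.pair,
    )
    survivors: list[Diplotype] = []
    for cand in candidates:
        h1, h2 = (pool.get(i) for i in cand.pair)
        ok = True
        for marker, attr in (("D6S2854", "d6s2854"), ("D6S2859", "d6s2859")):
            obs = child_profile.get(marker)
            if obs is None:
                continue
            p1 = getattr(h1, attr).lengths
            p2 = getattr(h2, attr).lengths
            if not _pair_pattern_match(obs, p1, p2, tolerance):
                ok = False
                break
        if ok and drb_lengths is not None:
            certain = h1.d6s2878_certain() | h2.d6s2878_certain()
            uncertain = h1.d6s2878_uncertain() | h2.d6s2878_uncertain()
            ok = _lengths_match(drb_lengths, certain, uncertain, tolerance)
        if ok:
            survivors.append(cand)
    if len(survivors) == 1:
        return FastTypeResult(status="call", candidates=tuple(survivors))
    if survivors:
        return FastTypeResult(
            status="ambiguous", candidates=tuple(survivors),
            note=f"{len(survivors)} transmissible diplotypes fit the profile",
        )
    return FastTypeResult(
        status="crossover-flag", candidates=(),
        note="no transmissible diplotype fits: sequence this animal "
             "(possible crossover or novel haplotype)",
    )
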