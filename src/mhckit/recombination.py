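"""Detection of block-chimeric (recombinant) haplotypes.

A haplotype is called chimeric when its five ordered region blocks can be
tiled from two donor haplotypes with at most ``max_breakpoints`` switches at
the four inter-block intervals.  Breakpoints are resolved to intervals only:
within-block locus order is unknown, so finer coordinates would be
fictitious.  Block equality follows :func:`mhckit.model.block_match`: a
not-determined block on the *candidate child* matches anything (and taints
the call with a ``wildcard_supported`` caveat), whereas a not-determined
donor block is never accepted as positive evidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional

from .model import Diplotype, Haplotype, HaplotypePool, block_match
from .regions import BLOCK_ORDER, INTERVALS, Interval, RegionBlock

__all__ = ["ChimeraCall", "CrossoverExplanation", "find_chimeras",
           "explain_crossover"]


@dataclass(frozen=True)
class ChimeraCall:
    child_id: str
    donor_pair: tuple[str, str]
    block_assignment: tuple[str, ...]  # donor id per block, A..DP order
    n_breakpoints: int
    wildcard_supported: bool = False
    note: str = ""

    def breakpoint_intervals(self) -> tuple[Interval, ...]:
        return tuple(
            iv for iv in INTERVALS
            if self.block_assignment[iv.value] != self.block_assignment[iv.value + 1]
        )


def _assignments(n_blocks: int, max_breakpoints: int):
    """Yield donor-index assignments (0/1 per block) with 1..max breakpoints.

    Assignments are canonicalised to start with donor 0 so each unordered
    donor labelling is produced once.
    """
    for mask in range(2 ** (n_blocks - 1)):
        assign = [0]
        for i in range(n_blocks - 1):
            assign.append(assign[-1] ^ ((mask >> i) & 1))
        nbp = sum(1 for i in range(n_blocks - 1) if assign[i] != assign[i + 1])
        if 1 <= nbp <= max_breakpoints:
            yield tuple(assign), nbp


def _match_assignment(
    child: Haplotype, donors: tuple[Haplotype, Haplotype], assign: tuple[int, ...]
) -> Optional[bool]:
    """None if some block mismatches; else whether a wildcard was used."""
    used = False
    for block, who in zip(BLOCK_ORDER, assign):
        ok, wc = block_match(child, donors[who], block)
        if not ok:
            return None
        used |= wc
    return used


def find_chimeras(
    pool: HaplotypePool, max_breakpoints: int = 2
) -> list[ChimeraCall]:
    """Scan a pool for haplotypes that are block-wise chimeras of two others.

    With ``max_breakpoints=0`` the scan degenerates to an exact-duplicate
    check (calls with 0 breakpoints and a single donor).  For each
    (child, donor pair) only the minimal-breakpoint assignments are emitted;
    swapped-donor duplicates are collapsed.  Calls are sorted by child id,
    then breakpoint count.
    """
    if len(pool) < 3 and max_breakpoints > 0:
        raise ValueError("chimera scan needs a pool of at least 3 haplotypes")
    calls: list[ChimeraCall] = []
    ids = pool.ids
    for child_id in ids:
        child = pool.get(child_id)
        if max_breakpoints == 0:
            for other_id in ids:
                if other_id == child_id:
                    continue
                ok = all(block_match(child, pool.get(other_id), b)[0]
                         for b in BLOCK_ORDER)
                if ok:
                    calls.append(ChimeraCall(
                        child_id=child_id,
                        donor_pair=(other_id, other_id),
                        block_assignment=tuple(other_id for _ in BLOCK_ORDER),
                        n_breakpoints=0,
                        note="exact duplicate",
                    ))
            continue
        for i, p_id in enumerate(ids):
            if p_id == child_id:
                continue
            for q_id in ids[i + 1:]:
                if q_id == child_id:
                    continue
                found: list[tuple[int, tuple[str, ...], bool]] = []
                for ordered in ((p_id, q_id), (q_id, p_id)):
                    donors = (pool.get(ordered[0]), pool.get(ordered[1]))
                    for assign, nbp in _assignments(
                        len(BLOCK_ORDER), max_breakpoints
                    ):
                        wc = _match_assignment(child, donors, assign)
                        if wc is None:
                            continue
                        found.append(
                            (nbp, tuple(ordered[w] for w in assign), wc)
                        )
                if found:
                    nbp, assignment, wc = min(found)
                    calls.append(ChimeraCall(
                        child_id=child_id,
                        donor_pair=(p_id, q_id),
                        block_assignment=assignment,
                        n_breakpoints=nbp,
                        wildcard_supported=wc,
                    ))
    calls.sort(key=lambda c: (_id_key(c.child_id), c.n_breakpoints, c.donor_pair))
    return calls


def _id_key(hap_id: str):
    return (0, int(hap_id)) if hap_id.isdigit() else (1, hap_id)


@dataclass(frozen=True)
class CrossoverExplanation:
    """Minimal-breakpoint explanation of a transmitted haplotype.

    ``n_breakpoints == 0`` means the haplotype is block-identical to one
    parental haplotype (no crossover).  For single-breakpoint explanations,
    ``intervals`` lists every interval placement consistent with the data:
    when the parental haplotypes share the blocks adjacent to the true
    breakpoint, several placements are observationally equivalent and all are
    reported rather than one being guessed.
    """

    child_blocks_from: tuple[tuple[str, ...], ...]  # one assignment per solution
    n_breakpoints: int
    intervals: tuple[tuple[Interval, ...], ...]  # per solution

    @property
    def is_crossover(self) -> bool:
        return self.n_breakpoints > 0

    def all_single_intervals(self) -> frozenset[Interval]:
        """Union of interval placements over single-breakpoint solutions."""
        return frozenset(iv for ivs in self.intervals for iv in ivs)


def explain_crossover(
    child_hap: Haplotype,
    parent: Diplotype,
    pool: HaplotypePool,
    max_breakpoints: int = 2,
) -> Optional[CrossoverExplanation]:
    """Explain a transmitted haplotype as a chimera of one parent's pair.

    Returns the minimal-breakpoint explanation (0 = non-recombinant), with
    all tied assignments listed, or ``None`` when no assignment with at most
    ``max_breakpoints`` breakpoints reproduces the child haplotype (the
    escalate-to-sequencing case).
    """
    donors = (pool.get(parent.pair[0]), pool.get(parent.pair[1]))
    # 0 breakpoints: identical to a parental haplotype
    zero: list[tuple[str, ...]] = []
    for who, donor in zip(parent.pair, donors):
        if all(block_match(child_hap, donor, b)[0] for b in BLOCK_ORDER):
            zero.append(tuple(who for _ in BLOCK_ORDER))
    if zero:
        return CrossoverExplanation(
            child_blocks_from=tuple(zero), n_breakpoints=0,
            intervals=tuple(() for _ in zero),
        )
    solutions: dict[int, list[tuple[str, ...]]] = {}
    for assign, nbp in _assignments(len(BLOCK_ORDER), max_breakpoints):
        for orient in ((0, 1), (1, 0)):
            d = (donors[orient[0]], donors[orient[1]])
            labels = (parent.pair[orient[0]], parent.pair[orient[1]])
            if _match_assignment(child_hap, d, assign) is not None:
                solutions.setdefault(nbp, []).append(
                    tuple(labels[w] for w in assign)
                )
    if not solutions:
        return None
    nbp = min(solutions)
    assigns = sorted(set(solutions[nbp]))
    intervals = tuple(
        tuple(iv for iv in INTERVALS if a[iv.value] != a[iv.value + 1])
        for a in assigns
    )
    return CrossoverExplanation(
        child_blocks_from=tuple(assigns), n_breakpoints=nbp, intervals=intervals,
    )


def replay_call(call: ChimeraCall, pool: HaplotypePool) -> dict[RegionBlock, frozenset[str]]:
    """Reconstruct the block contents implied by a chimera call."""
    return {
        block: pool.get(donor).block_alleles(block)
        for block, donor in zip(BLOCK_ORDER, call.block_assignment)
    }
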