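"""Region-block model of the macaque MHC.

The MHC of macaques is treated as five ordered gene-region blocks along the
chromosome, telomeric to centromeric:

    A  (Mafa-A1/-A2/-A4/-A5 loci, with the D6S2854 and D6S2859 microsatellites)
    B  (Mafa-B loci and the oligomorphic Mafa-I locus, which co-segregates with B)
    DR (Mafa-DRA plus a variable number of Mafa-DRB loci; D6S2878 lies in DRB intron 2)
    DQ (DQA1, DQB1)
    DP (DPA1, DPB1)

Meiotic crossovers are resolved to the four inter-block intervals; within-block
locus order is unknown and never used.
"""

from __future__ import annotations

import enum
import re
from typing import Iterable

__all__ = [
    "RegionBlock",
    "BLOCK_ORDER",
    "INTERVALS",
    "Interval",
    "BLOCK_LOCI",
    "GENOTYPE_LOCI",
    "STR_MARKERS",
    "block_of_locus",
    "locus_group",
    "parse_allele_name",
    "normalize_allele_name",
]


class RegionBlock(enum.IntEnum):
    """The five ordered MHC region blocks (A telomeric, DP centromeric)."""

    A = 0
    B = 1
    DR = 2
    DQ = 3
    DP = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


BLOCK_ORDER: tuple[RegionBlock, ...] = tuple(RegionBlock)


class Interval(enum.IntEnum):
    """Inter-block intervals where a crossover breakpoint can be located."""

    A_B = 0
    B_DR = 1
    DR_DQ = 2
    DQ_DP = 3

    def __str__(self) -> str:
        left, right = BLOCK_ORDER[self.value], BLOCK_ORDER[self.value + 1]
        return f"{left.name}|{right.name}"


INTERVALS: tuple[Interval, ...] = tuple(Interval)

# Genotype-level loci. The duplicated DRB loci (DRB1/3/4/5/6 and the DRB*W
# workshop groups) are pooled under the single group locus "DRB" because their
# physical order within the DR block is unknown.
GENOTYPE_LOCI: tuple[str, ...] = (
    "A1", "A2", "A4", "A5", "I", "B", "DRA", "DRB", "DQA1", "DQB1", "DPA1", "DPB1",
)

STR_MARKERS: tuple[str, ...] = ("D6S2854", "D6S2859", "D6S2878")

BLOCK_LOCI: dict[RegionBlock, tuple[str, ...]] = {
    RegionBlock.A: ("A1", "A2", "A4", "A5"),
    RegionBlock.B: ("I", "B"),
    RegionBlock.DR: ("DRA", "DRB"),
    RegionBlock.DQ: ("DQA1", "DQB1"),
    RegionBlock.DP: ("DPA1", "DPB1"),
}

_LOCUS_TO_BLOCK: dict[str, RegionBlock] = {
    locus: block for block, loci in BLOCK_LOCI.items() for locus in loci
}

_MARKER_TO_BLOCK: dict[str, RegionBlock] = {
    "D6S2854": RegionBlock.A,
    "D6S2859": RegionBlock.A,
    "D6S2878": RegionBlock.DR,
}

_NAME_RE = re.compile(r"^(?:Mafa-)?([A-Z0-9]+)\*(.+)$")


def block_of_locus(locus: str) -> RegionBlock:
    """Region block housing a genotype locus or STR marker."""
    key = locus_group(locus)
    if key in _LOCUS_TO_BLOCK:
        return _LOCUS_TO_BLOCK[key]
    if locus in _MARKER_TO_BLOCK:
        return _MARKER_TO_BLOCK[locus]
    raise KeyError(f"unknown locus or marker: {locus!r}")


def locus_group(locus: str) -> str:
    """Collapse individual DRB loci onto the group locus ``DRB``.

    ``DRB1``/``DRB3``/``DRB4``/``DRB5``/``DRB6`` and the bare ``DRB`` (used by
    the W-group workshop alleles) all map to ``DRB``; every other locus name is
    returned unchanged.
    """
    if locus.startswith("DRB"):
        return "DRB"
    return locus


def parse_allele_name(name: str) -> tuple[str, tuple[str, ...]]:
    """Split an MHC allele name into (locus, designation fields).

    Accepts names with or without the ``Mafa-`` species prefix, e.g.
    ``"Mafa-DPA1*02:19" -> ("DPA1", ("02", "19"))``.  Lineage-only names with a
    single field (``"Mafa-A4*14"``) are valid.  Raises ``ValueError`` for
    strings that do not follow ``locus*field[:field...]``.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"not a valid allele name: {name!r}")
    locus, rest = m.group(1), m.group(2)
    fields = tuple(rest.split(":"))
    if not all(fields):
        raise ValueError(f"not a valid allele name: {name!r}")
    return locus, fields


def normalize_allele_name(name: str) -> str:
    """Whitespace-normalize an allele name.

    Internal whitespace is removed (the published table prints variant suffixes
    as e.g. ``031:01 a``, which becomes ``031:01a``); the suffix letters are
    preserved because they denote distinct haplotype-specific variants.
    """
    return "".join(name.split())


def allele_locus(name: str) -> str:
    """Genotype locus (group level) of an allele name."""
    locus, _ = parse_allele_name(name)
    return locus_group(locus)


def sort_alleles(names: Iterable[str]) -> list[str]:
    """Deterministic ordering for allele-name sets (plain lexicographic)."""
    return sorted(names)
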