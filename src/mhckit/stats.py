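"""Haplotype frequency tables and cohort summaries.

Counts are haplotype occurrences (two per diploid animal), matching the way
colony totals are usually reported; percentages are rounded half-up to one
decimal so printed tables reproduce exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import pandas as pd

from .model import HaplotypePool
from .phasing import PhasedCohort

__all__ = [
    "haplotype_frequencies",
    "compare_cohorts",
    "CohortComparison",
    "find_homozygotes",
    "drb_region_summary",
    "DRBRegionSummary",
    "plot_frequencies",
]

COHORT_ATTR = {"bprc": "bprc_count", "original": "original_count"}


def round_half_up(x: Decimal | float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def haplotype_frequencies(pool: HaplotypePool, cohort: str) -> pd.DataFrame:
    """Per-haplotype counts and percentages for one cohort.

    Returns a DataFrame indexed by haplotype id with columns ``count`` and
    ``percentage`` (100*count/total, rounded half-up to one decimal);
    ``df.attrs`` carries the cohort label and total.
    """
    if cohort not in COHORT_ATTR:
        raise ValueError(f"unknown cohort {cohort!r} (use 'bprc' or 'original')")
    attr = COHORT_ATTR[cohort]
    counts = {h.id: getattr(h, attr) for h in pool}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative haplotype count")
    total = sum(counts.values())
    rows = []
    for hap_id, count in counts.items():
        pct = round_half_up(Decimal(100 * count) / Decimal(total)) if total else 0.0
        rows.append({"haplotype": hap_id, "count": count, "percentage": pct})
    df = pd.DataFrame(rows).set_index("haplotype")
    df.attrs["cohort"] = cohort
    df.attrs["total"] = total
    return df


@dataclass
class CohortComparison:
    table: pd.DataFrame  # per haplotype: counts, percentages, delta_pct
    absent_from_bprc: tuple[str, ...]
    largest_reduction: Optional[str]  # haplotype with most negative delta


def compare_cohorts(pool: HaplotypePool) -> CohortComparison:
    """Drift report between the original colony and the current cohort.

    ``delta_pct`` is the current-cohort percentage minus the original one;
    haplotypes no longer present and the largest percentage reduction are
    called out.
    """
    bprc = haplotype_frequencies(pool, "bprc")
    orig = haplotype_frequencies(pool, "original")
    table = pd.DataFrame({
        "bprc_count": bprc["count"],
        "bprc_pct": bprc["percentage"],
        "original_count": orig["count"],
        "original_pct": orig["percentage"],
    })
    table["delta_pct"] = (table["bprc_pct"] - table["original_pct"]).round(1)
    absent = tuple(
        table.index[(table["bprc_count"] == 0) & (table["original_count"] > 0)]
    )
    largest = None
    if len(table):
        reductions = table["delta_pct"]
        if (reductions < 0).any():
            largest = reductions.idxmin()
    return CohortComparison(
        table=table, absent_from_bprc=absent, largest_reduction=largest,
    )


def find_homozygotes(phased: PhasedCohort) -> list[tuple[str, str]]:
    """Animals whose resolved diplotype is a self-pair (MHC homozygotes)."""
    out = []
    for phase in phased.animals.values():
        if phase.status == "resolved" and phase.diplotype.is_homozygous:
            out.append((phase.animal_id, phase.diplotype.pair[0]))
    return sorted(out)


@dataclass
class DRBRegionSummary:
    loci_per_haplotype: pd.Series  # number of DRB gene copies per haplotype
    min_loci: int
    max_loci: int
    shared_combinations: list[tuple[frozenset[str], tuple[str, ...]]]
    dra_counts: pd.Series  # DRA allele -> number of haplotypes carrying it


def drb_region_summary(pool: HaplotypePool) -> DRBRegionSummary:
    """Summary of DRB region-configuration variation across a pool.

    The copy number counts every DRB gene on the haplotype, including
    unidentified copies known only from their D6S2878 product; shared
    combinations group haplotypes with identical *named* DRB allele sets.
    """
    n_loci = pd.Series({h.id: len(h.drb) for h in pool}, name="n_drb_loci")
    by_set: dict[frozenset[str], list[str]] = {}
    for h in pool:
        named = frozenset(e.allele for e in h.drb if e.allele is not None)
        by_set.setdefault(named, []).append(h.id)
    shared = sorted(
        ((s, tuple(ids)) for s, ids in by_set.items() if len(ids) > 1),
        key=lambda kv: kv[1],
    )
    dra: dict[str, int] = {}
    for h in pool:
        for name in h.alleles_at("DRA"):
            dra[name] = dra.get(name, 0) + 1
    return DRBRegionSummary(
        loci_per_haplotype=n_loci,
        min_loci=int(n_loci.min()),
        max_loci=int(n_loci.max()),
        shared_combinations=shared,
        dra_counts=pd.Series(dra, name="n_haplotypes").sort_index(),
    )


def plot_frequencies(pool: HaplotypePool, path) -> None:
    """Side-by-side bar chart of haplotype percentages in both cohorts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = compare_cohorts(pool).table
    ax = comp[["original_pct", "bprc_pct"]].plot.bar(figsize=(12, 4))
    ax.set_xlabel("haplotype")
    ax.set_ylabel("% of haplotypes in cohort")
    ax.legend(["original colony", "current cohort"])
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
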