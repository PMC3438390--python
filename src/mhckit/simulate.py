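"""Synthetic colony generator with full ground truth.

Emulates a closed breeding colony founded from a fixed haplotype pool:
founder animals receive haplotypes drawn (independently, weighted by their
original-colony counts) from the pool; matrilines propagate through dams
while sires are chosen freely across the colony (imported males were
unrelated); each meiosis transmits one parental haplotype, or, with a small
probability, a block-chimera of the two with a single breakpoint in one of
the four inter-block intervals.  Observations are then emitted per animal as
the set-union genotype of its true diplotype, with independent per-locus and
per-marker dropout.

Every random choice is routed through one ``numpy`` generator seeded from the
config, so runs are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .io import (
    _haplotype_to_dict,
    write_genotypes,
    write_pedigree,
    write_str_profiles,
)
from .model import (
    AnimalRecord,
    Diplotype,
    DRBEntry,
    GenotypeRecord,
    Haplotype,
    HaplotypePool,
    PedigreeGraph,
    STRPattern,
    genotype_from_diplotype,
)
from .regions import BLOCK_LOCI, BLOCK_ORDER, GENOTYPE_LOCI, Interval, RegionBlock

__all__ = [
    "SimConfig",
    "CrossoverEvent",
    "SimTruth",
    "simulate_meiosis",
    "simulate_colony",
    "emit_observations",
    "make_chimera",
    "founder_weights",
]


@dataclass
class SimConfig:
    """Colony simulation parameters.

    Defaults mirror the documented colony: ~30 founders, pedigrees up to 7
    generations in 12 matrilines, with a mean of 2 offspring per female per
    generation.  ``recomb_rate_per_meiosis`` (default 0.01) is a placeholder
    order of magnitude -- the MHC crossover rate is not known for this system;
    dropout defaults (0.05) represent occasional per-locus amplification
    failure.
    """

    n_founders: int = 30
    n_generations: int = 7
    mean_offspring: float = 2.0
    n_matrilines: int = 12
    recomb_rate_per_meiosis: float = 0.01
    breakpoint_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    dropout_rate_per_locus: float = 0.05
    str_dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        for p in (self.recomb_rate_per_meiosis, self.dropout_rate_per_locus,
                  self.str_dropout_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if len(self.breakpoint_weights) != 4 or any(
            w < 0 for w in self.breakpoint_weights
        ) or sum(self.breakpoint_weights) == 0:
            raise ValueError("breakpoint_weights: 4 non-negative reals, not all 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "breakpoint_weights" in doc:
            doc["breakpoint_weights"] = tuple(doc["breakpoint_weights"])
        return cls(**doc)


@dataclass(frozen=True)
class CrossoverEvent:
    meiosis_id: str           # "<child>:<sire|dam>"
    parent_pair: tuple[str, str]
    interval: Interval
    left_donor: str           # haplotype providing blocks left of the breakpoint
    right_donor: str
    transmitted_id: str
    observable: bool          # chimera differs from both parental haplotypes


@dataclass
class SimTruth:
    pedigree: PedigreeGraph
    diplotypes: dict[str, Diplotype]
    crossovers: list[CrossoverEvent]
    novel_haplotypes: dict[str, Haplotype]
    working_pool: HaplotypePool  # base pool plus any novel chimeras


def founder_weights(pool: HaplotypePool) -> tuple[list[str], np.ndarray]:
    """Founder haplotype sampling distribution: original counts, zeros -> 1."""
    ids = pool.ids
    w = np.array(
        [pool.get(i).original_count or 1 for i in ids], dtype=float
    )
    return ids, w / w.sum()


def make_chimera(
    left: Haplotype, right: Haplotype, interval: Interval, hap_id: str
) -> Haplotype:
    """Single-breakpoint chimera: blocks A..left of the interval from ``left``,
    the rest from ``right``."""
    locus_alleles: dict[str, frozenset[str]] = {}
    nd: set[str] = set()
    uncertain: dict[str, frozenset[str]] = {}
    drb: tuple[DRBEntry, ...] = ()
    d54 = d59 = None
    for block in BLOCK_ORDER:
        donor = left if block.value <= interval.value else right
        for locus in BLOCK_LOCI[block]:
            if locus == "DRB":
                drb = donor.drb
                continue
            locus_alleles[locus] = donor.alleles_at(locus)
            if locus in donor.nd_loci:
                nd.add(locus)
            if locus in donor.uncertain_alleles:
                uncertain[locus] = donor.uncertain_alleles[locus]
        if block is RegionBlock.A:
            d54, d59 = donor.d6s2854, donor.d6s2859
    return Haplotype(
        id=hap_id,
        locus_alleles=locus_alleles,
        drb=drb,
        nd_loci=frozenset(nd),
        uncertain_alleles=uncertain,
        d6s2854=STRPattern("D6S2854", d54.lengths),
        d6s2859=STRPattern("D6S2859", d59.lengths),
    )


def simulate_meiosis(
    parent: Diplotype,
    cfg: SimConfig,
    rng: np.random.Generator,
    pool: HaplotypePool,
    meiosis_id: str = "meiosis",
) -> tuple[str, Optional[CrossoverEvent], Optional[Haplotype]]:
    """One meiosis: returns (transmitted haplotype id, crossover event or
    None, newly created chimera Haplotype or None).

    With probability ``recomb_rate_per_meiosis`` a breakpoint interval is
    drawn from ``breakpoint_weights`` and the chimera (left blocks from one
    parental haplotype, right blocks from the other; orientation by coin
    flip) is transmitted; otherwise one parental haplotype is transmitted
    uniformly.  A chimera block-identical to a parental haplotype transmits
    that haplotype and the event is recorded as unobservable.
    """
    from .model import haplotypes_block_equal

    h = (pool.get(parent.pair[0]), pool.get(parent.pair[1]))
    if rng.random() >= cfg.recomb_rate_per_meiosis or parent.is_homozygous:
        return parent.pair[int(rng.integers(2))], None, None
    w = np.asarray(cfg.breakpoint_weights, dtype=float)
    interval = Interval(int(rng.choice(4, p=w / w.sum())))
    orient = int(rng.integers(2))
    left, right = (h[orient], h[1 - orient])
    chimera = make_chimera(left, right, interval,
                           hap_id=f"rec[{left.id}|{right.id}@{interval}]")
    for donor in h:
        if haplotypes_block_equal(chimera, donor):
            event = CrossoverEvent(
                meiosis_id=meiosis_id, parent_pair=parent.pair,
                interval=interval, left_donor=left.id, right_donor=right.id,
                transmitted_id=donor.id, observable=False,
            )
            return donor.id, event, None
    event = CrossoverEvent(
        meiosis_id=meiosis_id, parent_pair=parent.pair, interval=interval,
        left_donor=left.id, right_donor=right.id,
        transmitted_id=chimera.id, observable=True,
    )
    return chimera.id, event, chimera


def simulate_colony(
    cfg: SimConfig, pool: Optional[HaplotypePool] = None
) -> tuple[SimTruth, dict[str, GenotypeRecord]]:
    """Simulate a pedigreed colony and emit its (noisy) typing observations.

    Founders (half females, each seeding a matriline cyclically over
    ``n_matrilines``) form generation 0; every later generation draws its dams
    from the previous generation's females and its sires from all males born
    so far.  Returns the ground truth and the per-animal observation records.
    """
    if pool is None:
        from .io import fixture_pool

        pool = fixture_pool()
    rng = np.random.default_rng(cfg.seed)
    ids, weights = founder_weights(pool)

    animals: list[AnimalRecord] = []
    diplotypes: dict[str, Diplotype] = {}
    crossovers: list[CrossoverEvent] = []
    novel: dict[str, Haplotype] = {}
    working = HaplotypePool(list(pool))

    females: list[str] = []
    males: list[str] = []
    for i in range(cfg.n_founders):
        aid = f"F{i + 1:03d}"
        sex = "F" if i % 2 == 0 else "M"
        matriline = f"mat{(len(females) % cfg.n_matrilines) + 1:02d}" \
            if sex == "F" else None
        animals.append(AnimalRecord(aid, None, None, sex, matriline))
        (females if sex == "F" else males).append(aid)
        pair = tuple(rng.choice(ids, size=2, p=weights))
        diplotypes[aid] = Diplotype(pair, provenance="simulated")

    def transmit(parent_id: str, child_id: str, role: str) -> str:
        hap_id, event, chimera = simulate_meiosis(
            diplotypes[parent_id], cfg, rng, working,
            meiosis_id=f"{child_id}:{role}",
        )
        if chimera is not None:
            new_id = f"rec{len(novel) + 1:03d}"
            chimera = Haplotype(
                id=new_id, locus_alleles=dict(chimera.locus_alleles),
                drb=chimera.drb, nd_loci=chimera.nd_loci,
                uncertain_alleles=dict(chimera.uncertain_alleles),
                d6s2854=chimera.d6s2854, d6s2859=chimera.d6s2859,
            )
            novel[new_id] = chimera
            working.add(chimera)
            event = CrossoverEvent(
                meiosis_id=event.meiosis_id, parent_pair=event.parent_pair,
                interval=event.interval, left_donor=event.left_donor,
                right_donor=event.right_donor, transmitted_id=new_id,
                observable=True,
            )
            hap_id = new_id
        if event is not None:
            crossovers.append(event)
        return hap_id

    prev_females = list(females)
    matriline_of = {a.animal_id: a.matriline for a in animals}
    for gen in range(1, cfg.n_generations):
        if not prev_females or not males:
            break
        n_children = int(round(len(prev_females) * cfg.mean_offspring))
        gen_females: list[str] = []
        for j in range(n_children):
            aid = f"G{gen}_{j + 1:03d}"
            dam = str(rng.choice(prev_females))
            sire = str(rng.choice(males))
            sex = "F" if rng.random() < 0.5 else "M"
            animals.append(AnimalRecord(aid, sire, dam, sex, matriline_of[dam]))
            matriline_of[aid] = matriline_of[dam]
            hap_s = transmit(sire, aid, "sire")
            hap_d = transmit(dam, aid, "dam")
            diplotypes[aid] = Diplotype((hap_s, hap_d), provenance="simulated")
            if sex == "F":
                gen_females.append(aid)
            else:
                males.append(aid)
        prev_females = gen_females

    truth = SimTruth(
        pedigree=PedigreeGraph(animals),
        diplotypes=diplotypes,
        crossovers=crossovers,
        novel_haplotypes=novel,
        working_pool=working,
    )
    records = emit_observations(truth, cfg, rng)
    return truth, records


def emit_observations(
    truth: SimTruth, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, GenotypeRecord]:
    """Union genotypes of the true diplotypes, thinned by dropout.

    Each locus is independently marked not-determined with probability
    ``dropout_rate_per_locus`` and each STR marker with ``str_dropout_rate``;
    records are retained even when everything drops out.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    records: dict[str, GenotypeRecord] = {}
    for aid in sorted(truth.diplotypes):
        rec = genotype_from_diplotype(
            truth.diplotypes[aid], truth.working_pool, animal_id=aid
        )
        missing = set(rec.missing)
        loci = dict(rec.locus_alleles)
        strs = dict(rec.str_profile)
        for locus in GENOTYPE_LOCI:
            if locus in loci and rng.random() < cfg.dropout_rate_per_locus:
                del loci[locus]
                missing.add(locus)
        for marker in ("D6S2854", "D6S2859", "D6S2878"):
            if marker in strs and rng.random() < cfg.str_dropout_rate:
                del strs[marker]
                missing.add(marker)
        records[aid] = GenotypeRecord(
            animal_id=aid, locus_alleles=loci, str_profile=strs,
            missing=frozenset(missing),
        )
    return records


def write_simulation(
    truth: SimTruth,
    records: dict[str, GenotypeRecord],
    outdir,
) -> None:
    """Write the standard TSVs plus a truth.json into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(records, outdir / "genotypes.tsv")
    write_str_profiles(records, outdir / "str_profiles.tsv")
    write_pedigree(truth.pedigree, outdir / "pedigree.tsv")
    doc = {
        "diplotypes": {a: list(d.pair) for a, d in sorted(truth.diplotypes.items())},
        "crossovers": [
            {
                "meiosis": e.meiosis_id,
                "parent_pair": list(e.parent_pair),
                "interval": str(e.interval),
                "left_donor": e.left_donor,
                "right_donor": e.right_donor,
                "transmitted": e.transmitted_id,
                "observable": e.observable,
            }
            for e in truth.crossovers
        ],
        "novel_haplotypes": [
            _haplotype_to_dict(h) for _, h in sorted(truth.novel_haplotypes.items())
        ],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
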