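"""Readers and writers for the package's file formats.

Formats (all plain text):

* haplotype pool -- JSON, schema ``mhckit-haplotype-pool/1`` (see
  ``data/haplotypes.json`` for the documented bundled instance);
* allele catalog -- TSV ``name locus completeness status origins accession
  reference_animal`` plus an optional FASTA keyed by allele name;
* genotypes -- TSV ``animal_id locus alleles`` with alleles ``;``-separated,
  ``ND`` = not determined, ``-`` = determinate absence (no allele at the locus
  on either chromosome);
* STR profiles -- TSV ``animal_id marker lengths`` with lengths
  ``,``-separated in bp, ``ND`` = not determined, ``null`` = reproducible
  absence of product;
* pedigree -- TSV ``animal_id sire_id dam_id sex matriline`` with missing
  parents coded ``0``.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from Bio import SeqIO

from .model import (
    Allele,
    AlleleCatalog,
    AnimalRecord,
    DRBEntry,
    GenotypeRecord,
    Haplotype,
    HaplotypePool,
    PedigreeGraph,
    STRPattern,
)
from .regions import GENOTYPE_LOCI, STR_MARKERS

PathLike = Union[str, Path]

POOL_SCHEMA = "mhckit-haplotype-pool/1"


# ---------------------------------------------------------------------------
# Haplotype pool (JSON)
# ---------------------------------------------------------------------------

def _pattern(marker: str, raw, hap_id: str) -> STRPattern:
    if raw is None:
        return STRPattern(marker, None)
    try:
        lengths = frozenset(int(x) for x in raw)
        if any(x <= 0 for x in lengths):
            raise ValueError
    except (TypeError, ValueError):
        raise ValueError(
            f"haplotype {hap_id}: malformed {marker} lengths {raw!r}"
        ) from None
    return STRPattern(marker, lengths)


def _haplotype_from_dict(d: Mapping) -> Haplotype:
    hap_id = str(d["id"])
    locus_alleles: dict[str, frozenset[str]] = {
        locus: frozenset() for locus in GENOTYPE_LOCI if locus != "DRB"
    }
    nd = set(d.get("nd", ()))
    from .regions import allele_locus

    for key in ("A", "B", "DQ", "DP"):
        for name in d.get(key, ()):
            locus = allele_locus(name)
            locus_alleles[locus] = locus_alleles[locus] | {name}
    if d.get("DRA") is not None:
        locus_alleles["DRA"] = frozenset({d["DRA"]})
    drb = tuple(
        DRBEntry(
            allele=e.get("allele"),
            transcribed=bool(e.get("transcribed", False)),
            d6s2878=(None if e.get("d6s2878") is None else int(e["d6s2878"])),
            uncertain_length=bool(e.get("uncertain_length", False)),
        )
        for e in d.get("DRB", ())
    )
    counts = d.get("counts", {})
    return Haplotype(
        id=hap_id,
        locus_alleles=locus_alleles,
        drb=drb,
        nd_loci=frozenset(nd),
        uncertain_alleles={
            k: frozenset(v) for k, v in d.get("uncertain_alleles", {}).items()
        },
        d6s2854=_pattern("D6S2854", d.get("D6S2854"), hap_id),
        d6s2859=_pattern("D6S2859", d.get("D6S2859"), hap_id),
        bprc_count=int(counts.get("bprc", 0)),
        original_count=int(counts.get("original", 0)),
    )


def load_haplotype_pool(
    path: PathLike, catalog: Optional[AlleleCatalog] = None
) -> HaplotypePool:
    """Load a haplotype pool from JSON; validate invariants.

    Duplicate haplotype ids and malformed STR lengths are hard errors (the
    latter names the offending haplotype).  If a catalog is supplied, every
    allele name appearing in the pool is registered there as a stub when not
    already present.
    """
    with open(path) as fh:
        doc = json.load(fh)
    pool = HaplotypePool()
    for d in doc.get("haplotypes", ()):
        pool.add(_haplotype_from_dict(d))
    if catalog is not None:
        for hap in pool:
            for name in hap.all_allele_names():
                catalog.register_stub(name)
    return pool


def _haplotype_to_dict(h: Haplotype) -> dict:
    from .regions import sort_alleles

    d: dict = {"id": h.id}
    d["A"] = sort_alleles(h.block_alleles_by_loci(("A1", "A2", "A4", "A5")))
    d["B"] = sort_alleles(h.block_alleles_by_loci(("I", "B")))
    dra = h.locus_alleles.get("DRA", frozenset())
    d["DRA"] = next(iter(dra)) if dra else None
    d["DRB"] = [
        {
            "allele": e.allele,
            "transcribed": e.transcribed,
            "d6s2878": e.d6s2878,
            **({"uncertain_length": True} if e.uncertain_length else {}),
        }
        for e in h.drb
    ]
    d["DQ"] = sort_alleles(h.block_alleles_by_loci(("DQA1", "DQB1")))
    d["DP"] = sort_alleles(h.block_alleles_by_loci(("DPA1", "DPB1")))
    if h.nd_loci:
        d["nd"] = sorted(h.nd_loci)
    if h.uncertain_alleles:
        d["uncertain_alleles"] = {
            k: sort_alleles(v) for k, v in sorted(h.uncertain_alleles.items())
        }
    d["D6S2854"] = None if h.d6s2854.is_nd else sorted(h.d6s2854.lengths)
    d["D6S2859"] = None if h.d6s2859.is_nd else sorted(h.d6s2859.lengths)
    d["counts"] = {"bprc": h.bprc_count, "original": h.original_count}
    return d


def write_haplotype_pool(pool: HaplotypePool, path: PathLike) -> None:
    doc = {"schema": POOL_SCHEMA,
           "haplotypes": [_haplotype_to_dict(h) for h in pool]}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Allele catalog (TSV + optional FASTA)
# ---------------------------------------------------------------------------

_CATALOG_COLUMNS = ("name", "locus", "completeness", "status", "origins",
                    "accession", "reference_animal")


def load_allele_catalog(
    path: PathLike, fasta: Optional[PathLike] = None
) -> AlleleCatalog:
    """Load a catalog TSV; attach sequences from a FASTA keyed by allele name."""
    sequences: dict[str, str] = {}
    if fasta is not None:
        for rec in SeqIO.parse(str(fasta), "fasta"):
            sequences[rec.id] = str(rec.seq).upper()
    catalog = AlleleCatalog()
    with open(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header[:2]) != ("name", "locus"):
                    raise ValueError(f"{path}: unexpected catalog header {header}")
                continue
            row = dict(zip(header, fields))
            origins = frozenset(
                t for t in row.get("origins", "").split(",") if t
            )
            catalog.add(Allele(
                name=row["name"],
                locus=row["locus"],
                completeness=row.get("completeness") or "full-length",
                status=row.get("status") or "known",
                origins=origins,
                accession=row.get("accession") or None,
                reference_animal=row.get("reference_animal") or None,
                sequence=sequences.get(row["name"]),
            ))
    return catalog


def write_allele_catalog(catalog: AlleleCatalog, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for a in catalog:
            fh.write("\t".join([
                a.name, a.locus, a.completeness, a.status,
                ",".join(sorted(a.origins)),
                a.accession or "", a.reference_animal or "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Genotypes (TSV)
# ---------------------------------------------------------------------------

def load_genotypes(
    path: PathLike, catalog: Optional[AlleleCatalog] = None
) -> dict[str, GenotypeRecord]:
    """Load per-animal genotype rows into :class:`GenotypeRecord` objects.

    Allele names are validated against ``catalog`` when given: unknown names
    emit a warning but are retained.  An animal whose every locus is ND is
    retained (with a warning) so that it can still act as an untyped carrier
    during phasing.
    """
    per_animal: dict[str, dict[str, frozenset[str]]] = {}
    missing: dict[str, set[str]] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            animal, locus, alleles = fields[0], fields[1], fields[2]
            per_animal.setdefault(animal, {})
            missing.setdefault(animal, set())
            if alleles == "ND":
                missing[animal].add(locus)
                continue
            names = frozenset() if alleles == "-" else frozenset(
                a.strip() for a in alleles.split(";") if a.strip()
            )
            if catalog is not None:
                for n in names:
                    if n not in catalog:
                        warnings.warn(f"{animal}/{locus}: unknown allele {n}")
            per_animal[animal][locus] = names
    records: dict[str, GenotypeRecord] = {}
    for animal, loci in per_animal.items():
        if not loci:
            warnings.warn(f"{animal}: no typed loci; retained with all-missing flags")
        records[animal] = GenotypeRecord(
            animal_id=animal, locus_alleles=loci,
            missing=frozenset(missing[animal]),
        )
    return records


def write_genotypes(records: Mapping[str, GenotypeRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tlocus\talleles\n")
        for animal in sorted(records):
            rec = records[animal]
            for locus in GENOTYPE_LOCI:
                if locus in rec.missing:
                    fh.write(f"{animal}\t{locus}\tND\n")
                elif locus in rec.locus_alleles:
                    names = rec.locus_alleles[locus]
                    val = "-" if not names else ";".join(sorted(names))
                    fh.write(f"{animal}\t{locus}\t{val}\n")


# ---------------------------------------------------------------------------
# STR profiles (TSV)
# ---------------------------------------------------------------------------

def load_str_profiles(path: PathLike) -> dict[str, dict[str, Optional[frozenset[int]]]]:
    """Load STR profile rows: animal -> marker -> length set (None = ND)."""
    out: dict[str, dict[str, Optional[frozenset[int]]]] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            animal, marker, lengths = fields[0], fields[1], fields[2]
            out.setdefault(animal, {})
            if lengths == "ND":
                out[animal][marker] = None
            elif lengths == "null":
                out[animal][marker] = frozenset()
            else:
                out[animal][marker] = frozenset(
                    int(x) for x in lengths.split(",") if x.strip()
                )
    return out


def write_str_profiles(
    records: Mapping[str, GenotypeRecord], path: PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tmarker\tlengths\n")
        for animal in sorted(records):
            rec = records[animal]
            for marker in STR_MARKERS:
                if marker in rec.missing:
                    fh.write(f"{animal}\t{marker}\tND\n")
                elif marker in rec.str_profile:
                    lengths = rec.str_profile[marker]
                    val = "null" if not lengths else ",".join(
                        str(x) for x in sorted(lengths)
                    )
                    fh.write(f"{animal}\t{marker}\t{val}\n")


def attach_str_profiles(
    records: Mapping[str, GenotypeRecord],
    profiles: Mapping[str, Mapping[str, Optional[frozenset[int]]]],
) -> None:
    """Merge STR observations into genotype records in place."""
    for animal, markers in profiles.items():
        if animal not in records:
            continue
        rec = records[animal]
        miss = set(rec.missing)
        for marker, lengths in markers.items():
            if lengths is None:
                miss.add(marker)
                rec.str_profile.pop(marker, None)
            else:
                rec.str_profile[marker] = frozenset(lengths)
                miss.discard(marker)
        rec.missing = frozenset(miss)


# ---------------------------------------------------------------------------
# Pedigree (TSV)
# ---------------------------------------------------------------------------

def load_pedigree(path: PathLike) -> PedigreeGraph:
    animals: list[AnimalRecord] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            animal, sire, dam = fields[0], fields[1], fields[2]
            sex = fields[3] if len(fields) > 3 and fields[3] else "U"
            matriline = fields[4] if len(fields) > 4 and fields[4] else None
            animals.append(AnimalRecord(
                animal_id=animal,
                sire_id=None if sire == "0" else sire,
                dam_id=None if dam == "0" else dam,
                sex=sex,
                matriline=matriline,
            ))
    return PedigreeGraph(animals)


def write_pedigree(pedigree: PedigreeGraph, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tsire_id\tdam_id\tsex\tmatriline\n")
        for a in pedigree:
            fh.write("\t".join([
                a.animal_id, a.sire_id or "0", a.dam_id or "0",
                a.sex, a.matriline or "",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("mhckit.data").joinpath(name)

BPRC_TOTAL = 242
ORIGINAL_TOTAL = 390


def fixture_pool(catalog: Optional[AlleleCatalog] = None) -> HaplotypePool:
    """The bundled 32-haplotype colony pool, with its count totals asserted."""
    with resources.as_file(_data_path("haplotypes.json")) as p:
        pool = load_haplotype_pool(p, catalog=catalog)
    if len(pool) != 32:
        raise AssertionError(f"fixture pool has {len(pool)} haplotypes, expected 32")
    bprc = sum(h.bprc_count for h in pool)
    orig = sum(h.original_count for h in pool)
    if (bprc, orig) != (BPRC_TOTAL, ORIGINAL_TOTAL):
        raise AssertionError(
            f"fixture counts sum to ({bprc}, {orig}), expected "
            f"({BPRC_TOTAL}, {ORIGINAL_TOTAL})"
        )
    return pool


def fixture_catalog() -> AlleleCatalog:
    """The bundled DP/DQ allele catalog (75 alleles)."""
    with resources.as_file(_data_path("allele_catalog.tsv")) as p:
        return load_allele_catalog(p)
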