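"""Clone-consensus allele calling and novelty classification.

Full-length class II transcripts are RT-PCR amplified, cloned, and a set of
colonies sequenced per sample.  A sequence is accepted as an allele only when
it is supported by at least ``min_identical_clones`` identical clones within a
single sample *and* is observed in at least ``min_samples`` distinct samples
(animals or independent RT-PCR reactions) -- the standard guard against PCR
and cloning artefacts.  Defaults are 3 identical clones and 2 samples.

Accepted sequences are classified against a reference catalog as ``known``
(exact match to a full-length catalog sequence at the locus), ``extension``
(the query strictly contains a known exon-2-only fragment at the locus), or
``novel``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO

from .model import AlleleCatalog

__all__ = [
    "CloneSet",
    "AlleleCall",
    "call_alleles",
    "classify_novelty",
    "summarize_catalog",
    "read_clone_fastas",
]


@dataclass
class CloneSet:
    """Sequenced clones from one sample (animal or RT-PCR reaction) at one locus."""

    sample_id: str
    locus: str
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"{self.sample_id}/{self.locus}: empty clone set")
        self.sequences = [s.upper() for s in self.sequences]


@dataclass
class AlleleCall:
    sequence: str
    locus: str
    supporting_clones: int  # best within-sample identical-clone count
    supporting_samples: int  # distinct samples in which the sequence occurs
    accepted: bool
    reasons: tuple[str, ...] = ()
    novelty: str = "unassessed"

    def __post_init__(self) -> None:
        if self.accepted and self.reasons:
            raise ValueError("accepted call cannot carry rejection reasons")


def call_alleles(
    clone_sets: Iterable[CloneSet],
    min_identical_clones: int = 3,
    min_samples: int = 2,
    catalog: Optional[AlleleCatalog] = None,
) -> list[AlleleCall]:
    """Group clone sequences by exact identity within locus and apply the
    acceptance rule.

    A sequence is accepted iff some single sample contributes at least
    ``min_identical_clones`` identical clones of it AND it occurs in at least
    ``min_samples`` distinct samples.  Rejected sequences are returned with
    ``accepted=False`` and the failed conditions listed.  Sequences are
    compared exactly (uppercased, no mismatch tolerance).  If a ``catalog`` is
    given, accepted calls are novelty-classified against it.

    A sample id appearing with more than one locus is a hard error: locus
    assignment is an input, not something this step infers.
    """
    if min_identical_clones < 1 or min_samples < 1:
        raise ValueError("thresholds must be >= 1")
    clone_sets = list(clone_sets)
    sample_locus: dict[str, str] = {}
    for cs in clone_sets:
        seen = sample_locus.get(cs.sample_id)
        if seen is not None and seen != cs.locus:
            raise ValueError(
                f"sample {cs.sample_id} spans loci {seen} and {cs.locus}"
            )
        sample_locus[cs.sample_id] = cs.locus

    # (locus, sequence) -> sample -> identical clone count
    support: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for cs in clone_sets:
        for seq in cs.sequences:
            support[(cs.locus, seq)][cs.sample_id] += 1

    calls: list[AlleleCall] = []
    for (locus, seq) in sorted(support):
        per_sample = support[(locus, seq)]
        best = max(per_sample.values())
        n_samples = len(per_sample)
        reasons: list[str] = []
        if best < min_identical_clones:
            reasons.append(
                f"max {best} identical clones in one sample "
                f"(need {min_identical_clones})"
            )
        if n_samples < min_samples:
            reasons.append(f"seen in {n_samples} sample(s) (need {min_samples})")
        accepted = not reasons
        novelty = "unassessed"
        if accepted and catalog is not None:
            novelty = classify_novelty(seq, locus, catalog)
        calls.append(AlleleCall(
            sequence=seq, locus=locus,
            supporting_clones=best, supporting_samples=n_samples,
            accepted=accepted, reasons=tuple(reasons), novelty=novelty,
        ))
    return calls


def classify_novelty(seq: str, locus: str, catalog: AlleleCatalog) -> str:
    """Classify an accepted sequence as known / extension / novel.

    ``known``: exactly equals a full-length catalog sequence at the locus.
    ``extension``: strictly contains (exact substring) an exon2-only catalog
    sequence at the locus without being known.  ``novel`` otherwise.  A locus
    absent from the catalog yields ``novel`` with a warning.
    """
    if not seq:
        raise ValueError("empty query sequence")
    seq = seq.upper()
    entries = [a for a in catalog.by_locus(locus) if a.sequence]
    if not catalog.by_locus(locus):
        import warnings

        warnings.warn(f"locus {locus} absent from catalog; classifying as novel")
        return "novel"
    for a in entries:
        if a.completeness == "full-length" and a.sequence == seq:
            return "known"
    for a in entries:
        if (a.completeness == "exon2-only" and a.sequence in seq
                and a.sequence != seq):
            return "extension"
    return "novel"


def summarize_catalog(catalog: AlleleCatalog) -> pd.DataFrame:
    """Per-locus summary of a catalog: allele counts by status and origin.

    Returns a DataFrame indexed by locus with columns ``n_alleles``,
    ``novel``, ``extension``, ``known`` and one ``origin_<tag>`` column per
    population tag present, plus a ``total`` row.
    """
    rows: dict[str, Counter] = defaultdict(Counter)
    tags = sorted({t for a in catalog for t in a.origins})
    for a in catalog:
        c = rows[a.locus]
        c["n_alleles"] += 1
        if a.status in ("novel", "extension", "known"):
            c[a.status] += 1
        for t in a.origins:
            c[f"origin_{t}"] += 1
    columns = ["n_alleles", "novel", "extension", "known"] + [
        f"origin_{t}" for t in tags
    ]
    df = pd.DataFrame(
        [{**{"locus": locus}, **{col: rows[locus].get(col, 0) for col in columns}}
         for locus in sorted(rows)]
    ).set_index("locus")
    df.loc["total"] = df.sum()
    return df.astype(int)


def read_clone_fastas(directory: Union[str, Path]) -> list[CloneSet]:
    """Read per-sample clone FASTAs with headers ``>sampleID|locus|cloneN``."""
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for path in sorted(Path(directory).glob("*.fasta")) + sorted(
        Path(directory).glob("*.fa")
    ):
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.id.split("|")
            if len(parts) < 2:
                raise ValueError(f"{path}: header {rec.id!r} lacks sample|locus fields")
            sample, locus = parts[0], parts[1]
            groups[(sample, locus)].append(str(rec.seq))
    return [
        CloneSet(sample_id=s, locus=l, sequences=seqs)
        for (s, l), seqs in sorted(groups.items())
    ]


def write_calls(calls: Iterable[AlleleCall], path: Union[str, Path]) -> None:
    df = pd.DataFrame([
        {
            "locus": c.locus,
            "accepted": c.accepted,
            "novelty": c.novelty,
            "supporting_clones": c.supporting_clones,
            "supporting_samples": c.supporting_samples,
            "reasons": "; ".join(c.reasons),
            "sequence": c.sequence,
        }
        for c in calls
    ])
    df.to_csv(path, sep="\t", index=False)
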