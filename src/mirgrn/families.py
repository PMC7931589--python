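"""miRNA family assignment, mature-sequence grouping, and family ages.

A miRNA family is a set of loci sharing an identical seed (mature positions
2-8) and a common ancestral precursor.  Expressed precursors are assigned to
known families by local sequence similarity against a reference catalog
(primary tier first, e.g. a MirGeneDB-like catalog; then a secondary
miRBase-like tier, whose hits are flagged for manual review).  A hit is
accepted only when the aligned portion covers at least 80% of the query
precursor and the aligned identity is at least 70%; loci with no acceptable
hit are putative novel, species-specific miRNAs.

Local alignment uses Smith-Waterman scoring match +2 / mismatch -3 /
gap open -5 / gap extend -2 (the open score is charged to the first gapped
position).  Ties between reference entries are broken by higher score, then
higher identity, then lexicographically smallest family name, so assignment
is deterministic and independent of reference order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align

from .io import FastaRecord, normalize_rna

MIN_COVERAGE = 0.80   # aligned query positions / query length
MIN_IDENTITY = 0.70


@dataclass(frozen=True)
class ReferenceEntry:
    family: str
    precursor: str
    tier: str = "primary"      # "primary" | "secondary"


@dataclass
class MiRNALocus:
    species: str
    locus_id: str
    precursor: str
    mature: str
    arm: str = "5p"
    raw_count: int = 0
    cpm: float = 0.0
    detected: bool = False

    def __post_init__(self):
        self.precursor = normalize_rna(self.precursor, context=self.locus_id)
        self.mature = normalize_rna(self.mature, context=self.locus_id)
        if self.mature not in self.precursor:
            raise ValueError(f"{self.locus_id}: mature is not a substring of precursor")
        if self.raw_count < 0:
            raise ValueError(f"{self.locus_id}: negative raw count")


@dataclass
class FamilyAssignment:
    family: str | None
    coverage: float
    identity: float
    tier: str                  # "primary" | "secondary" | "none"
    score: float = 0.0
    needs_review: bool = False

    @property
    def status(self) -> str:
        return "known" if self.family is not None else "novel"


@dataclass
class MiRNAFamily:
    name: str
    members: list = field(default_factory=list)   # MiRNALocus
    status: str = "known"
    tier: str = "primary"
    age_mya: float | None = None


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(alignment, query: str, target: str) -> tuple[float, float]:
    """(coverage, identity) of a local alignment.

    Coverage is aligned query positions over query length; identity is the
    fraction of those aligned positions that match the reference exactly.
    """
    taligned, qaligned = alignment.aligned  # target blocks, query blocks
    aligned = 0
    matches = 0
    for (ts, te), (qs, qe) in zip(taligned, qaligned):
        aligned += qe - qs
        matches += sum(1 for i in range(te - ts) if target[ts + i] == query[qs + i])
    if aligned == 0:
        return 0.0, 0.0
    return aligned / len(query), matches / aligned


def assign_family(
    precursor: str,
    reference: Iterable[ReferenceEntry],
    *,
    min_coverage: float = MIN_COVERAGE,
    min_identity: float = MIN_IDENTITY,
) -> FamilyAssignment:
    """Assign a precursor to the best-matching reference family.

    The primary tier is searched first; only if it yields no acceptable hit
    is the secondary tier consulted (secondary hits carry a needs-review
    flag, mirroring manual curation of second-pass database hits).
    """
    query = normalize_rna(precursor, context="precursor")
    if len(query) < 40:
        raise ValueError("precursor shorter than 40 nt")
    entries = list(reference)
    if not entries:
        raise ValueError("empty reference catalog")

    aligner = _make_aligner()
    for tier in ("primary", "secondary"):
        tier_entries = [e for e in entries if e.tier == tier]
        if not tier_entries:
            continue
        scores = [(aligner.score(e.precursor, query), e) for e in tier_entries]
        best_score = max(s for s, _ in scores)
        if best_score <= 0:
            continue
        candidates = []
        for s, e in scores:
            if s < best_score:
                continue
            aln = aligner.align(e.precursor, query)[0]
            cov, ident = _alignment_stats(aln, query, e.precursor)
            candidates.append((s, ident, e.family, cov))
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
        score, ident, fam, cov = candidates[0]
        if cov >= min_coverage and ident >= min_identity:
            return FamilyAssignment(fam, cov, ident, tier, score=score,
                                    needs_review=(tier == "secondary"))
    return FamilyAssignment(None, 0.0, 0.0, "none")


def assign_catalog(
    loci: Sequence[MiRNALocus],
    reference: Sequence[ReferenceEntry],
    **kwargs,
) -> pd.DataFrame:
    """Assign every locus; returns the per-locus assignment report table."""
    rows = []
    for locus in loci:
        a = assign_family(locus.precursor, reference, **kwargs)
        rows.append({
            "locus_id": locus.locus_id,
            "species": locus.species,
            "family": a.family if a.family is not None else "",
            "coverage": round(a.coverage, 4),
            "identity": round(a.identity, 4),
            "tier": a.tier,
            "status": a.status,
            "needs_review": a.needs_review,
        })
    return pd.DataFrame(rows)


def group_by_mature(loci: Sequence[MiRNALocus]) -> list[list[MiRNALocus]]:
    """Group loci into equivalence classes of exactly identical matures.

    Any single-nucleotide difference — including at the 3' terminus —
    separates groups.  Groups are returned sorted by mature sequence.
    """
    groups: dict[str, list[MiRNALocus]] = {}
    for locus in loci:
        groups.setdefault(locus.mature, []).append(locus)
    return [groups[m] for m in sorted(groups)]


def load_age_table(table: pd.DataFrame) -> dict[str, float]:
    """Family -> age (MYA) lookup; conflicting duplicate rows are an error."""
    ages: dict[str, float] = {}
    for _, row in table.iterrows():
        fam, age = str(row.iloc[0]), float(row.iloc[1])
        if fam in ages and ages[fam] != age:
            raise ValueError(f"conflicting ages for family {fam}: {ages[fam]} vs {age}")
        ages[fam] = age
    return ages


def annotate_age(family: MiRNAFamily, ages: dict[str, float]) -> MiRNAFamily:
    """Copy the family's age from the table when present; never guessed."""
    family.age_mya = ages.get(family.name)
    return family
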