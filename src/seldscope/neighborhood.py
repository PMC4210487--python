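"""Genomic-context extraction around anchor genes and domain-fusion detection.

Functionally related genes tend to cluster; the neighborhood report lists
every locus overlapping a fixed nucleotide window either side of an anchor
gene (10,000 nt by default). Fusion detection scans a single protein with
two or more domain queries and calls a fusion when distinct domains hit
essentially non-overlapping regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core_model import ConfigurationError, GeneLocus, Genome, ProteinRecord
from .homology import HomologyCriteria, ScoringScheme, smith_waterman

__all__ = [
    "DEFAULT_WINDOW_NT",
    "NeighborhoodMember",
    "NeighborhoodReport",
    "extract_neighborhood",
    "DomainHit",
    "FusionCall",
    "detect_fusion",
    "shared_neighbors",
]

#: Default context window either side of the anchor, in nucleotides.
DEFAULT_WINDOW_NT = 10_000

#: Two domain hits on one protein count as distinct (a fusion) when their
#: spans overlap by less than this fraction of the shorter span.
FUSION_MAX_OVERLAP = 0.20


@dataclass(frozen=True)
class NeighborhoodMember:
    locus: GeneLocus
    distance_nt: int      # 0 if overlapping the anchor; signed gap length otherwise
    same_strand: bool


@dataclass
class NeighborhoodReport:
    """All loci within ``window_nt`` of the anchor on the anchor's contig."""

    genome_id: str
    anchor: GeneLocus
    window_nt: int
    members: list[NeighborhoodMember]
    annotation_counts: dict[str, int] = field(default_factory=dict)

    def member_labels(self) -> frozenset[str]:
        labels: set[str] = set()
        for m in self.members:
            labels |= m.locus.domain_labels
        return frozenset(labels)


def _signed_distance(anchor: GeneLocus, other: GeneLocus) -> int:
    """0 for overlapping loci, else the gap length, negative upstream."""
    if other.end < anchor.start:
        return -(anchor.start - other.end - 1)
    if other.start > anchor.end:
        return other.start - anchor.end - 1
    return 0


def extract_neighborhood(genome: Genome, anchor_gene_id: str,
                         window_nt: int = DEFAULT_WINDOW_NT) -> NeighborhoodReport:
    """Loci overlapping ``[anchor.start - window, anchor.end + window]``.

    Membership is inclusive of partial overlaps, measured from the anchor's
    outermost coordinates; loci on other contigs are excluded, as is the
    anchor itself. Members come back sorted by start coordinate. Strand is
    recorded but never filters membership.
    """
    anchor = genome.locus(anchor_gene_id)
    lo, hi = anchor.start - window_nt, anchor.end + window_nt
    members = [
        NeighborhoodMember(
            locus=l,
            distance_nt=_signed_distance(anchor, l),
            same_strand=(l.strand == anchor.strand),
        )
        for l in genome.sorted_loci(anchor.contig_id)
        if l.gene_id != anchor.gene_id and l.end >= lo and l.start <= hi
    ]
    counts: dict[str, int] = {}
    for m in members:
        for label in sorted(m.locus.domain_labels) or [m.locus.annotation]:
            if label:
                counts[label] = counts.get(label, 0) + 1
    return NeighborhoodReport(
        genome_id=genome.genome_id, anchor=anchor, window_nt=window_nt,
        members=members, annotation_counts=counts,
    )


@dataclass(frozen=True)
class DomainHit:
    label: str
    span: tuple[int, int]   # 1-based inclusive span on the scanned protein
    evalue: float


@dataclass(frozen=True)
class FusionCall:
    """Domain hits on one protein and whether they constitute a fusion."""

    protein_id: str
    hits: tuple[DomainHit, ...]
    fused: bool


def _overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    overlap = min(a[1], b[1]) - max(a[0], b[0]) + 1
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return max(overlap, 0) / shorter


def detect_fusion(protein: ProteinRecord,
                  domain_queries: Mapping[str, ProteinRecord],
                  criteria: HomologyCriteria,
                  scheme: ScoringScheme = ScoringScheme()) -> FusionCall:
    """Scan one protein with labelled domain queries and call fusions.

    Each query is locally aligned against the protein; labels with a
    criteria-passing hit are reported with the hit's span on the protein.
    A fusion is called when at least two labels hit with spans overlapping
    by less than 20% of the shorter span.
    """
    if len(domain_queries) < 2:
        raise ConfigurationError("fusion detection needs >= 2 domain queries")
    hits: list[DomainHit] = []
    for label in sorted(domain_queries):
        hit = smith_waterman(domain_queries[label], protein, scheme)
        if hit is not None and criteria.passes(hit):
            hits.append(DomainHit(label, hit.subject_span, hit.evalue))
    fused = any(
        _overlap_fraction(a.span, b.span) < FUSION_MAX_OVERLAP
        for i, a in enumerate(hits) for b in hits[i + 1:]
    )
    return FusionCall(protein.protein_id, tuple(hits), fused)


def shared_neighbors(reports: Iterable[NeighborhoodReport]) -> dict[str, int]:
    """Per domain label: number of genomes whose neighborhood contains it.

    Returned mapping iterates in descending count order (ties by label).
    """
    reports = list(reports)
    counts: dict[str, int] = {}
    for report in reports:
        for label in report.member_labels():
            counts[label] = counts.get(label, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
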