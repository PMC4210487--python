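"""Ortholog assignment by bidirectional best hits (BBH).

Two proteins in two genomes are called orthologs when each is the other's
top-ranked homology hit under the configured criteria. Domain-label
agreement (from the annotated gene loci) is recorded, and can optionally be
required, as a stand-in for the curated conserved-domain check used
alongside BBH in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_model import Genome
from .homology import (
    AlignmentResult,
    HomologyCriteria,
    ScoringScheme,
    SELD_SEARCH_CRITERIA,
    search,
)

__all__ = ["OrthologPair", "best_hit", "bidirectional_best_hits"]


@dataclass(frozen=True)
class OrthologPair:
    """One BBH ortholog pair, reported with genome ids in lexicographic order."""

    genome_a: str
    protein_a: str
    genome_b: str
    protein_b: str
    evalue_ab: float
    evalue_ba: float
    domain_consistent: bool


def best_hit(query, target_genome: Genome,
             criteria: HomologyCriteria = SELD_SEARCH_CRITERIA,
             scheme: ScoringScheme = ScoringScheme()) -> AlignmentResult | None:
    """Top-ranked passing hit of ``query`` in ``target_genome``, or ``None``.

    Ranking follows the search ordering: ascending E-value, then descending
    bitscore, then lexicographic subject id — so equally diverged paralogs
    resolve deterministically to the smaller protein id.
    """
    hits = search(query, target_genome, criteria, scheme)
    return hits[0] if hits else None


def bidirectional_best_hits(ga: Genome, gb: Genome,
                            criteria: HomologyCriteria = SELD_SEARCH_CRITERIA,
                            require_domain_match: bool = False,
                            scheme: ScoringScheme = ScoringScheme()) -> list[OrthologPair]:
    """All BBH pairs between two genomes.

    ``(p, q)`` is reported iff p's best hit in ``gb`` is q and q's best hit
    in ``ga`` is p. With ``require_domain_match``, pairs whose loci both
    carry domain labels that do not intersect are dropped; pairs with no
    labels on either side are kept with ``domain_consistent=False``.

    The output is symmetric in the genome arguments: pairs are canonicalised
    to lexicographic genome-id order and sorted by protein id.
    """
    first, second = (ga, gb) if ga.genome_id <= gb.genome_id else (gb, ga)
    forward = {p.protein_id: best_hit(p, second, criteria, scheme)
               for p in first.proteins}
    backward = {p.protein_id: best_hit(p, first, criteria, scheme)
                for p in second.proteins}
    pairs: list[OrthologPair] = []
    for pid, hit in sorted(forward.items()):
        if hit is None:
            continue
        back = backward.get(hit.subject_id)
        if back is None or back.subject_id != pid:
            continue
        labels_a = first.domain_labels_for(pid)
        labels_b = second.domain_labels_for(hit.subject_id)
        consistent = bool(labels_a and labels_b and (labels_a & labels_b))
        if require_domain_match and labels_a and labels_b and not consistent:
            continue
        pairs.append(OrthologPair(
            genome_a=first.genome_id, protein_a=pid,
            genome_b=second.genome_id, protein_b=hit.subject_id,
            evalue_ab=hit.evalue, evalue_ba=back.evalue,
            domain_consistent=consistent,
        ))
    return pairs
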