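"""The exclusive co-occurrence screen (phylogenetic profiling).

Every protein of a reference genome is searched against a panel of target
genomes under strict homology rules (E < 1e-07, alignment over half the
query length, identity >= 30%), giving a boolean presence/absence matrix.
Candidate trait-associated genes are those present in *all* genomes of a
positive set and absent from *every* genome of a negative set; candidates
are then annotated with their occurrence in outgroup clades
(all / some / none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core_model import ConfigurationError, Genome, GenomeSet, ProteinRecord
from .homology import HomologyCriteria, PROFILING_CRITERIA, ScoringScheme, search

__all__ = [
    "PresenceMatrix",
    "ScreenResult",
    "build_presence_matrix",
    "exclusive_screen",
    "outgroup_occurrence",
]


@dataclass
class PresenceMatrix:
    """Reference-gene x genome boolean matrix under a recorded criteria set."""

    reference_genes: list[str]
    genome_ids: list[str]
    values: np.ndarray
    criteria: HomologyCriteria

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.reference_genes), len(self.genome_ids)):
            raise ConfigurationError(
                f"presence matrix shape {self.values.shape} inconsistent with "
                f"{len(self.reference_genes)} genes x {len(self.genome_ids)} genomes"
            )

    def present(self, protein_id: str, genome_id: str) -> bool:
        return bool(self.values[self.reference_genes.index(protein_id),
                                self.genome_ids.index(genome_id)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.astype(int),
                            index=self.reference_genes, columns=self.genome_ids)

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            self.to_dataframe().rename_axis("protein_id").to_csv(fh, sep="\t")


@dataclass
class ScreenResult:
    """One candidate gene surviving the exclusive screen."""

    protein_id: str
    annotation: str
    domain_labels: frozenset[str]
    present_in_positives: frozenset[str]
    occurrence_outgroup: dict[str, str] = field(default_factory=dict)
    record: ProteinRecord | None = None


def _reference_order(reference: Genome) -> list[ProteinRecord]:
    """Reference proteins in gene order (loci by contig then start), then
    any proteins without a locus in proteome order."""
    ordered: list[ProteinRecord] = []
    seen: set[str] = set()
    contigs = sorted({l.contig_id for l in reference.loci})
    for contig in contigs:
        for locus in reference.sorted_loci(contig):
            if locus.protein_id not in seen:
                ordered.append(reference.proteome[locus.protein_id])
                seen.add(locus.protein_id)
    for pid, rec in reference.proteome.items():
        if pid not in seen:
            ordered.append(rec)
            seen.add(pid)
    return ordered


def build_presence_matrix(reference: Genome, targets: GenomeSet,
                          criteria: HomologyCriteria = PROFILING_CRITERIA,
                          scheme: ScoringScheme = ScoringScheme()) -> PresenceMatrix:
    """Presence/absence of every reference protein across target genomes.

    Cell (g, t) is true iff the reference protein g has at least one hit in
    genome t passing the criteria.
    """
    if not reference.proteome:
        raise ConfigurationError("reference proteome is empty")
    queries = _reference_order(reference)
    genome_ids = sorted(targets.genomes)
    values = np.zeros((len(queries), len(genome_ids)), dtype=bool)
    for i, query in enumerate(queries):
        for j, gid in enumerate(genome_ids):
            values[i, j] = bool(search(query, targets[gid], criteria, scheme))
    return PresenceMatrix([q.protein_id for q in queries], genome_ids, values, criteria)


def exclusive_screen(matrix: PresenceMatrix, positives: Iterable[str],
                     negatives: Iterable[str],
                     reference: Genome | None = None,
                     min_positive_fraction: float = 1.0) -> list[ScreenResult]:
    """Reference genes absent from all negatives and present in all positives.

    The dismissal-on-negatives rule runs first, mirroring the screening
    procedure's step order (the final set is order-independent). With
    ``min_positive_fraction`` < 1 the all-positives requirement relaxes to a
    fraction of the positive set. When ``reference`` is given, annotation,
    domain labels and the query record are attached from its loci.
    """
    positives, negatives = set(positives), set(negatives)
    if positives & negatives:
        raise ConfigurationError(
            f"positive and negative sets overlap: {sorted(positives & negatives)}"
        )
    unknown = (positives | negatives) - set(matrix.genome_ids)
    if unknown:
        raise ConfigurationError(f"genomes not in matrix: {sorted(unknown)}")

    pos_idx = [matrix.genome_ids.index(g) for g in sorted(positives)]
    neg_idx = [matrix.genome_ids.index(g) for g in sorted(negatives)]
    results: list[ScreenResult] = []
    for i, pid in enumerate(matrix.reference_genes):
        if neg_idx and matrix.values[i, neg_idx].any():
            continue  # dismissed: present in a negative genome
        present = {matrix.genome_ids[j] for j in pos_idx if matrix.values[i, j]}
        if len(present) < min_positive_fraction * len(positives) or not positives:
            continue
        if min_positive_fraction >= 1.0 and present != positives:
            continue
        annotation, labels, record = "", frozenset(), None
        if reference is not None:
            record = reference.proteome.get(pid)
            annotation = next(
                (l.annotation for l in reference.loci if l.protein_id == pid), ""
            )
            labels = reference.domain_labels_for(pid)
        results.append(ScreenResult(
            protein_id=pid, annotation=annotation, domain_labels=labels,
            present_in_positives=frozenset(present), record=record,
        ))
    return results


def outgroup_occurrence(candidates: list[ScreenResult],
                        outgroups: Mapping[str, GenomeSet],
                        criteria: HomologyCriteria = PROFILING_CRITERIA,
                        scheme: ScoringScheme = ScoringScheme()) -> list[ScreenResult]:
    """Annotate candidates with per-clade occurrence: all / some / none.

    A single-genome clade reports "all" when the candidate is present.
    Candidates must carry their query record (attach the reference genome in
    :func:`exclusive_screen`).
    """
    annotated: list[ScreenResult] = []
    for cand in candidates:
        if cand.record is None:
            raise ConfigurationError(
                f"candidate {cand.protein_id!r} lacks its query record"
            )
        occurrence: dict[str, str] = {}
        for clade, genomes in outgroups.items():
            n_hit = sum(
                bool(search(cand.record, g, criteria, scheme)) for g in genomes
            )
            occurrence[clade] = (
                "all" if n_hit == len(genomes) and len(genomes) > 0
                else "some" if n_hit > 0 else "none"
            )
        annotated.append(replace(cand, occurrence_outgroup=occurrence))
    return annotated
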