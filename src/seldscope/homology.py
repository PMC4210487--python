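"""Pairwise local protein alignment and homology search.

Optimal Smith–Waterman local alignment under BLOSUM scoring with affine gaps
(executed through Biopython's :class:`Bio.Align.PairwiseAligner`), with
Karlin–Altschul E-values

    E = K * m * n * exp(-lambda * S)

computed from fixed matrix parameters, and identity/query-coverage statistics
derived from the traceback. This is the desk-scale stand-in for BLAST-style
database searches: presence/absence and identity calls on small genome sets
do not need heuristic seeding.

Conventions match BLAST output: identity uses the
full alignment length (gap columns in the denominator), and selenocysteine
``U`` is scored as ``C`` so that Sec/Cys correspondence counts as identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Union

from Bio import Align
from Bio.Align import substitution_matrices

from .core_model import Genome, GenomeSet, ProteinRecord, ValidationError

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "HomologyCriteria",
    "smith_waterman",
    "evalue",
    "bitscore",
    "search",
    "percent_identity",
    "PercentIdentity",
    "SELD_SEARCH_CRITERIA",
    "PROFILING_CRITERIA",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin–Altschul parameters.

    Defaults are the classic BLASTP parameterisation: BLOSUM62 with gap
    open 11 / extend 1, for which ungapped lambda = 0.267 and K = 0.041.
    A gap of length ``k`` costs ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValidationError("gap_extend must not exceed gap_open")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValidationError("lambda and K must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        return _make_aligner(self.matrix_name, self.gap_open, self.gap_extend)


@lru_cache(maxsize=8)
def _make_aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gapped residue pays open + extend, matching BLAST's convention
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _scorable(sequence: str) -> str:
    """Map stored residues onto the substitution-matrix alphabet (U -> C)."""
    return sequence.replace("U", "C")


@dataclass(frozen=True)
class AlignmentResult:
    """One local alignment hit.

    ``identity`` counts identical aligned residue pairs over the full
    alignment length (gap columns included in the denominator);
    ``query_cover`` is the aligned query span over the query length. Spans
    are 1-based inclusive.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bitscore: float
    evalue: float
    identity: float
    aln_length: int
    query_cover: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    subject_genome: str | None = None

    def sort_key(self):
        return (self.evalue, -self.bitscore, self.subject_id)


@dataclass(frozen=True)
class HomologyCriteria:
    """A named homology-acceptance rule set.

    ``evalue_inclusive`` selects between "E <= cutoff" and the strict
    "E < cutoff"; coverage is compared strictly (">") and identity
    inclusively (">=") — the conventions of the two rule sets used in the
    study design (see :data:`SELD_SEARCH_CRITERIA` and
    :data:`PROFILING_CRITERIA`).
    """

    max_evalue: float = 0.1
    min_query_cover: float | None = None
    min_identity: float | None = None
    evalue_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValidationError("max_evalue must be positive")

    def passes(self, hit: AlignmentResult) -> bool:
        if self.evalue_inclusive:
            if hit.evalue > self.max_evalue:
                return False
        elif hit.evalue >= self.max_evalue:
            return False
        if self.min_query_cover is not None and not hit.query_cover > self.min_query_cover:
            return False
        if self.min_identity is not None and not hit.identity >= self.min_identity:
            return False
        return True

    def max_score_needed(self, m: int, n: int, scheme: ScoringScheme) -> float:
        """Smallest raw score whose E-value can still pass the E cutoff."""
        return (math.log(scheme.K * m * n) - math.log(self.max_evalue)) / scheme.lambda_


#: Homolog-occurrence searching: E-value <= 0.1, no further filters.
SELD_SEARCH_CRITERIA = HomologyCriteria(max_evalue=0.1, evalue_inclusive=True)

#: The presence/absence screen rules: E < 1e-07 (strict), alignment extending
#: over half the query length (strict), identity at least 30% (inclusive).
PROFILING_CRITERIA = HomologyCriteria(
    max_evalue=1e-7, min_query_cover=0.5, min_identity=0.30, evalue_inclusive=False
)


def evalue(raw_score: float, query_len: int, subject_total_len: int,
           scheme: ScoringScheme = ScoringScheme()) -> float:
    """Karlin–Altschul expected number of hits: ``K * m * n * exp(-lambda*S)``."""
    if query_len < 1 or subject_total_len < 1:
        raise ValidationError("sequence lengths must be >= 1")
    return scheme.K * query_len * subject_total_len * math.exp(-scheme.lambda_ * raw_score)


def bitscore(raw_score: float, scheme: ScoringScheme = ScoringScheme()) -> float:
    """Normalised score ``(lambda*S - ln K) / ln 2``."""
    return (scheme.lambda_ * raw_score - math.log(scheme.K)) / math.log(2)


def _align(query: ProteinRecord, subject: ProteinRecord, scheme: ScoringScheme,
           db_length: int) -> AlignmentResult | None:
    """Optimal local alignment of one pair, or None when no cell scores > 0."""
    aligner = scheme.aligner()
    qseq, sseq = _scorable(query.sequence), _scorable(subject.sequence)
    alignments = aligner.align(qseq, sseq)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    length = aln.length
    qblocks, sblocks = aln.aligned
    qspan = (int(qblocks[0][0]) + 1, int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]) + 1, int(sblocks[-1][1]))
    score = int(round(alignments.score))
    return AlignmentResult(
        query_id=query.protein_id,
        subject_id=subject.protein_id,
        raw_score=score,
        bitscore=bitscore(score, scheme),
        evalue=evalue(score, len(query), db_length, scheme),
        identity=counts.identities / length,
        aln_length=length,
        query_cover=(qspan[1] - qspan[0] + 1) / len(query),
        query_span=qspan,
        subject_span=sspan,
        subject_genome=subject.genome_id,
    )


def smith_waterman(query: ProteinRecord, subject: ProteinRecord,
                   scheme: ScoringScheme = ScoringScheme()) -> AlignmentResult | None:
    """Optimal local alignment of two proteins.

    Returns ``None`` when no positive-scoring local alignment exists (the
    no-hit sentinel). The E-value uses n = subject length.
    """
    return _align(query, subject, scheme, db_length=len(subject))


DatabaseLike = Union[Genome, GenomeSet, Mapping[str, ProteinRecord], Iterable[ProteinRecord]]


def _iter_db(db: DatabaseLike) -> list[ProteinRecord]:
    if isinstance(db, Genome):
        return db.proteins
    if isinstance(db, GenomeSet):
        return [p for g in db for p in g.proteins]
    if isinstance(db, Mapping):
        return list(db.values())
    return list(db)


def search(query: ProteinRecord, db: DatabaseLike,
           criteria: HomologyCriteria = SELD_SEARCH_CRITERIA,
           scheme: ScoringScheme = ScoringScheme()) -> list[AlignmentResult]:
    """Search a query against a protein database.

    One best local alignment per subject protein; hits failing the criteria
    are removed. ``n`` in the E-value formula is the summed length of all
    database proteins. Results are sorted by ascending E-value, ties broken
    by descending bitscore, then lexicographic subject id.

    A cheap score-only pass computes each pair's optimal score first; the
    traceback (needed only for identity and coverage) runs solely for pairs
    whose E-value can pass, which keeps all-vs-all screens affordable.
    """
    subjects = _iter_db(db)
    if not subjects:
        return []
    db_length = sum(len(s) for s in subjects)
    aligner = scheme.aligner()
    qseq = _scorable(query.sequence)
    min_score = criteria.max_score_needed(len(query), db_length, scheme)
    hits: list[AlignmentResult] = []
    for subject in subjects:
        score = aligner.score(qseq, _scorable(subject.sequence))
        if score <= 0 or score < min_score - 1e-9:
            continue
        hit = _align(query, subject, scheme, db_length)
        if hit is not None and criteria.passes(hit):
            hits.append(hit)
    hits.sort(key=AlignmentResult.sort_key)
    return hits


@dataclass(frozen=True)
class PercentIdentity:
    """Display-ready pairwise identity: integer percent plus a no-hit flag."""

    percent: int
    no_hit: bool = False


def percent_identity(a: ProteinRecord, b: ProteinRecord,
                     scheme: ScoringScheme = ScoringScheme()) -> PercentIdentity:
    """Identity of the optimal local alignment, as an integer percentage.

    Sequence pairs with no positive-scoring alignment report 0 with the
    no-hit flag set.
    """
    hit = smith_waterman(a, b, scheme)
    if hit is None:
        return PercentIdentity(0, no_hit=True)
    return PercentIdentity(int(round(hit.identity * 100)), no_hit=False)


BLAST_TAB_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def hits_to_rows(hits: Iterable[AlignmentResult]) -> list[list]:
    """Render hits in the 12-column tabular layout of BLAST outfmt 6.

    Mismatch/gapopen counts are not retained on :class:`AlignmentResult`;
    the mismatch column reports non-identical columns and gapopen 0.
    """
    rows = []
    for h in hits:
        n_ident = int(round(h.identity * h.aln_length))
        rows.append([
            h.query_id, h.subject_id, round(h.identity * 100, 2), h.aln_length,
            h.aln_length - n_ident, 0,
            h.query_span[0], h.query_span[1], h.subject_span[0], h.subject_span[1],
            f"{h.evalue:.2e}", round(h.bitscore, 1),
        ])
    return rows
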