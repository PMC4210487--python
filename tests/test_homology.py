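"""Local alignment, Karlin–Altschul statistics and database search.

The Smith–Waterman oracle here is an independent exhaustive computation:
the optimal local score equals the best global affine-gap alignment score
over all substring pairs (including the empty pair, score 0), evaluated by
plain memoized recursion.
"""

import math
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from seldscope import (
    HomologyCriteria,
    PROFILING_CRITERIA,
    ProteinRecord,
    ScoringScheme,
    SELD_SEARCH_CRITERIA,
    ValidationError,
    bitscore,
    evalue,
    percent_identity,
    search,
    smith_waterman,
)

_B62 = substitution_matrices.load("BLOSUM62")


def oracle_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive local alignment score: best global affine alignment over
    all substring pairs (empty alignment scores 0)."""

    def global_affine(x: str, y: str) -> float:
        @lru_cache(maxsize=None)
        def rec(i: int, j: int, state: int) -> float:
            if i == len(x) and j == len(y):
                return 0.0
            best = -math.inf
            if i < len(x) and j < len(y):
                best = max(best, _B62[x[i], y[j]] + rec(i + 1, j + 1, 0))
            if i < len(x):
                cost = gap_extend if state == 2 else gap_open + gap_extend
                best = max(best, -cost + rec(i + 1, j, 2))
            if j < len(y):
                cost = gap_extend if state == 1 else gap_open + gap_extend
                best = max(best, -cost + rec(i, j + 1, 1))
            return best

        return rec(0, 0, 0)

    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, global_affine(a[i1:i2], b[j1:j2]))
    return int(best)


class TestSmithWaterman:
    def test_self_alignment_fully_identical(self):
        hit = smith_waterman(ProteinRecord("q", "", "MKV"), ProteinRecord("s", "", "MKV"))
        assert hit.identity == 1.0
        assert hit.aln_length == 3
        assert hit.query_span == (1, 3) and hit.subject_span == (1, 3)

    def test_no_positive_cell_is_no_hit(self):
        assert smith_waterman(ProteinRecord("q", "", "AAAA"),
                              ProteinRecord("s", "", "WWWW")) is None

    def test_selenocysteine_scored_as_cysteine(self):
        hit = smith_waterman(ProteinRecord("q", "", "MKUCV"), ProteinRecord("s", "", "MKCCV"))
        assert hit.identity == 1.0  # U aligned to C counts as identical

    def test_illegal_residue_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            ProteinRecord("q", "", "MKO")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ARND", min_size=1, max_size=8),
        b=st.text(alphabet="ARND", min_size=1, max_size=8),
    )
    def test_score_equals_exhaustive_oracle(self, a, b):
        """Optimal local score matches exhaustive substring enumeration."""
        expected = oracle_local_score(a, b)
        hit = smith_waterman(ProteinRecord("q", "", a), ProteinRecord("s", "", b))
        got = hit.raw_score if hit is not None else 0
        assert got == expected

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ARNDCQEG", min_size=1, max_size=12),
        b=st.text(alphabet="ARNDCQEG", min_size=1, max_size=12),
    )
    def test_score_symmetric_under_exchange(self, a, b):
        """BLOSUM is symmetric, so the optimal score is exchange-invariant."""
        ha = smith_waterman(ProteinRecord("q", "", a), ProteinRecord("s", "", b))
        hb = smith_waterman(ProteinRecord("q", "", b), ProteinRecord("s", "", a))
        assert (ha.raw_score if ha else 0) == (hb.raw_score if hb else 0)


class TestEvalue:
    def test_algebraic_identity_E_equals_one(self):
        scheme = ScoringScheme()
        m, n = 250, 4000
        s = math.log(scheme.K * m * n) / scheme.lambda_
        assert evalue(s, m, n, scheme) == pytest.approx(1.0)

    def test_doubling_database_doubles_E(self):
        assert evalue(50, 100, 2_000) == pytest.approx(2 * evalue(50, 100, 1_000))

    def test_frozen_regression_value(self):
        # computed once with 40-digit arbitrary-precision arithmetic
        assert evalue(100, 300, 10**5) == pytest.approx(3.1206311883307654e-6, rel=1e-12)
        assert bitscore(100) == pytest.approx(43.128189871779326, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s=st.integers(min_value=0, max_value=500),
        ds=st.integers(min_value=1, max_value=100),
        m=st.integers(min_value=1, max_value=10_000),
        n=st.integers(min_value=1, max_value=10**7),
    )
    def test_monotonicity(self, s, ds, m, n):
        """E strictly decreases in S and increases in m and n."""
        assert evalue(s + ds, m, n) < evalue(s, m, n)
        assert evalue(s, m + 1, n) > evalue(s, m, n)
        assert evalue(s, m, n + 1) > evalue(s, m, n)


def _mutated(rng, seq: str, frac: float) -> str:
    chars = list(seq)
    sites = rng.choice(len(chars), size=int(frac * len(chars)), replace=False)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for i in sites:
        chars[i] = aas[(aas.index(chars[i]) + 1 + int(rng.integers(18))) % 20]
    return "".join(chars)


@pytest.fixture(scope="module")
def planted_db():
    rng = np.random.default_rng(1234)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    query = ProteinRecord("query", "", "".join(aas[i] for i in rng.integers(0, 20, 120)))
    close = ProteinRecord("close", "", _mutated(rng, query.sequence, 0.20))
    distant = ProteinRecord("distant", "", _mutated(rng, query.sequence, 0.80))
    noise = [
        ProteinRecord(f"bg{i}", "", "".join(aas[j] for j in rng.integers(0, 20, 110)))
        for i in range(10)
    ]
    return query, close, distant, noise


class TestSearch:
    def test_planted_homolog_passes_strict_criteria(self, planted_db):
        query, close, _, noise = planted_db
        hits = search(query, [close] + noise, PROFILING_CRITERIA)
        assert [h.subject_id for h in hits] == ["close"]
        assert hits[0].identity >= 0.5 and hits[0].query_cover > 0.5

    def test_heavily_mutated_subject_rejected_by_identity(self, planted_db):
        query, _, distant, noise = planted_db
        hits = search(query, [distant] + noise, PROFILING_CRITERIA)
        assert "distant" not in [h.subject_id for h in hits]

    def test_stricter_criteria_give_subset(self, planted_db):
        query, close, distant, noise = planted_db
        db = [close, distant] + noise
        loose = {h.subject_id for h in search(query, db, SELD_SEARCH_CRITERIA)}
        strict = {h.subject_id for h in search(query, db, PROFILING_CRITERIA)}
        assert strict <= loose

    def test_empty_db_empty_result(self, planted_db):
        assert search(planted_db[0], [], SELD_SEARCH_CRITERIA) == []

    def test_sorted_by_evalue(self, planted_db):
        query, close, distant, noise = planted_db
        hits = search(query, [distant, close] + noise, SELD_SEARCH_CRITERIA)
        assert hits[0].subject_id == "close"
        assert [h.evalue for h in hits] == sorted(h.evalue for h in hits)

    def test_self_hit_tops_own_proteome(self, small_sim):
        genomes, _ = small_sim
        genome = genomes["TP01"]
        for rec in genome.proteins[:5]:
            hits = search(rec, genome, SELD_SEARCH_CRITERIA)
            assert hits and hits[0].subject_id == rec.protein_id


class TestPercentIdentity:
    def test_identical_sequences_100(self):
        a = ProteinRecord("a", "", "MKVLWQEDFAHS")
        assert percent_identity(a, a).percent == 100

    def test_no_hit_flagged_zero(self):
        res = percent_identity(ProteinRecord("a", "", "AAAA"), ProteinRecord("b", "", "WWWW"))
        assert res.percent == 0 and res.no_hit
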