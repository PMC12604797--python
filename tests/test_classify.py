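"""Local alignment, E-value surrogate, database search, and hit filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from verifid import simulate as sim
from verifid.classify import (
    AlignmentHit,
    HitFilterParams,
    ScoringParams,
    evalue,
    filter_hits,
    local_align,
    read_hit_table,
    search_db,
    write_hit_table,
)
from verifid.refdb_io import ReferenceDB, ReferenceRecord, reverse_complement

SCORING = ScoringParams()


def _gotoh_local_score(a, b, scoring=SCORING):
    """Brute-force affine-gap local alignment (score only), O(nm)."""
    n, m = len(a), len(b)
    NEG = -10**9
    M = [[0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            M[i][j] = max(0, max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s)
            X[i][j] = max(
                M[i - 1][j] + scoring.gap_open,
                X[i - 1][j] + scoring.gap_extend,
                Y[i - 1][j] + scoring.gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + scoring.gap_open,
                Y[i][j - 1] + scoring.gap_extend,
                X[i][j - 1] + scoring.gap_open,
            )
            best = max(best, M[i][j])
    return best


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        s, pident, qcovs, _ = local_align("ACGTACGTAC", "ACGTACGTAC")
        assert s == 20 and pident == 100.0 and qcovs == 100.0

    def test_single_mismatch_eight_mer(self):
        s, pident, qcovs, _ = local_align("ACGTACGT", "ACGTTCGT")
        assert s == 7 * 2 - 3 == 11
        assert pident == pytest.approx(87.5)
        assert qcovs == pytest.approx(100.0)

    def test_disjoint_sequences_score_at_most_one_match(self):
        s, _, _, span = local_align("AAAA", "CCCC")
        assert s == 0
        s2, _, _, span2 = local_align("AAAA", "CCAC")
        assert s2 <= 2 and span2[1] - span2[0] <= 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_score_matches_brute_force_gotoh_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            a = sim.random_sequence(int(rng.integers(5, 31)), rng)
            b = sim.random_sequence(int(rng.integers(5, 31)), rng)
            s, _, _, _ = local_align(a, b)
            assert s == _gotoh_local_score(a, b)


class TestEvalue:
    def test_linear_in_database_length(self):
        assert evalue(10, 100, 2000) == pytest.approx(2 * evalue(10, 100, 1000))

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 100, 1000) for s in range(0, 50, 5)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_worked_example(self):
        # K*m*n*exp(-lambda*S) = 0.41 * 8 * 8 * exp(-6.875)
        expected = 0.41 * 64 * math.exp(-0.625 * 11)
        assert evalue(11, 8, 8) == pytest.approx(expected)
        assert expected == pytest.approx(0.0271, abs=2e-4)


def _toy_db(toy_taxonomy):
    rng = np.random.default_rng(4)
    seqs = {t: sim.random_sequence(150, rng) for t in (10000, 10001, 10002, 10003)}
    records = {}
    for taxid, seq in seqs.items():
        acc = f"ACC{taxid}"
        records[acc] = ReferenceRecord(
            accession=acc, taxid=taxid, molecule="mitochondrial",
            record_class="barcode_locus", gene_label="COI", sequence=seq,
            title=f"{toy_taxonomy.name(taxid)} COI",
        )
    # an annotated non-coding RNA and a genus-level record share Capra hircus's sequence
    records["NCR1"] = ReferenceRecord(
        accession="NCR1", taxid=10000, molecule="mitochondrial",
        record_class="ncRNA_other", gene_label="misc_RNA", sequence=seqs[10000],
        title="Capra hircus predicted ncRNA",
    )
    records["GEN1"] = ReferenceRecord(
        accession="GEN1", taxid=1000, molecule="mitochondrial",
        record_class="barcode_locus", gene_label="COI", sequence=seqs[10000],
        title="Capra sp. COI",
    )
    return ReferenceDB(records=records, taxonomy=toy_taxonomy), seqs


class TestSearchDb:
    def test_exact_subsequence_ranks_first_with_full_identity(self, toy_taxonomy):
        db, seqs = _toy_db(toy_taxonomy)
        rows = search_db(seqs[10002][20:120], db, qseqid="q")
        assert rows[0].staxids == 10002
        assert rows[0].pident == pytest.approx(100.0)
        assert rows[0].qcovs == pytest.approx(100.0)

    def test_reverse_complement_query_found_equally(self, toy_taxonomy):
        db, seqs = _toy_db(toy_taxonomy)
        rows = search_db(reverse_complement(seqs[10002][20:120]), db, qseqid="q")
        assert rows[0].staxids == 10002
        assert rows[0].pident == pytest.approx(100.0)

    def test_perfect_match_outranks_single_mismatch(self, toy_taxonomy):
        db, seqs = _toy_db(toy_taxonomy)
        q = seqs[10003]
        rows = search_db(q, db, qseqid="q")
        assert rows[0].accession == "ACC10003"

    def test_all_n_query_yields_no_rows(self, toy_taxonomy):
        db, _ = _toy_db(toy_taxonomy)
        assert search_db("N" * 80, db, qseqid="q") == []

    def test_row_order_is_deterministic(self, toy_taxonomy):
        db, seqs = _toy_db(toy_taxonomy)
        r1 = search_db(seqs[10000], db, qseqid="q")
        r2 = search_db(seqs[10000], db, qseqid="q")
        assert [(h.accession, h.evalue) for h in r1] == [
            (h.accession, h.evalue) for h in r2
        ]

    def test_empty_database_rejected(self, toy_taxonomy):
        with pytest.raises(ValueError):
            search_db("ACGT", ReferenceDB(records={}, taxonomy=toy_taxonomy))


def _hit(taxid, pident, ev, record_class="barcode_locus", acc="A"):
    return AlignmentHit(
        qseqid="q", qlen=100, evalue=ev, qcovs=100.0, pident=pident,
        staxids=taxid, stitle="t", scomnames="n", score=10.0, accession=acc,
        subject_molecule="mitochondrial", subject_record_class=record_class,
    )


class TestFilterHits:
    def test_weak_top_match_discards_the_query(self, toy_taxonomy):
        rows = [_hit(10000, 89.9, 1e-30), _hit(10001, 85.0, 1e-20)]
        assert filter_hits(rows, toy_taxonomy) == []

    def test_dedupe_keeps_best_row_per_taxid(self, toy_taxonomy):
        rows = [_hit(10000, 99.0, 1e-30, acc="A1"), _hit(10000, 97.0, 1e-25, acc="A2")]
        kept = filter_hits(rows, toy_taxonomy)
        assert [(h.staxids, h.pident) for h in kept] == [(10000, 99.0)]

    def test_non_species_top_hit_cascades_to_next_species_row(self, toy_taxonomy):
        rows = [
            _hit(1000, 99.5, 1e-35),   # genus-rank record
            _hit(10000, 98.0, 1e-30),
        ]
        kept = filter_hits(rows, toy_taxonomy)
        assert [h.staxids for h in kept] == [10000]

    def test_ncrna_subjects_are_excluded(self, toy_taxonomy):
        rows = [
            _hit(10000, 99.5, 1e-35, record_class="ncRNA_other"),
            _hit(10001, 98.0, 1e-30),
        ]
        kept = filter_hits(rows, toy_taxonomy)
        assert [h.staxids for h in kept] == [10001]

    def test_ties_at_the_top_are_all_retained(self, toy_taxonomy):
        rows = [
            _hit(10000, 99.0, 1e-30, acc="A1"),
            _hit(10001, 99.0, 1e-30, acc="A2"),
            _hit(10002, 95.0, 1e-20, acc="A3"),
        ]
        kept = filter_hits(rows, toy_taxonomy)
        assert sorted(h.staxids for h in kept) == [10000, 10001]

    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from([10000, 10001, 10002, 10003, 1000]),
                st.floats(min_value=50, max_value=100),
                st.sampled_from(["barcode_locus", "ncRNA_other", "other"]),
            ),
            max_size=12,
        )
    )
    def test_no_retained_row_violates_an_active_rule(self, data, toy_taxonomy):
        rows = sorted(
            (
                _hit(t, round(p, 2), 10.0 ** -(i + 1), record_class=rc, acc=f"A{i}")
                for i, (t, p, rc) in enumerate(data)
            ),
            key=lambda h: (h.evalue, -h.pident),
        )
        params = HitFilterParams()
        kept = filter_hits(rows, toy_taxonomy, params)
        assert len({h.staxids for h in kept}) <= len({h.staxids for h in rows})
        for h in kept:
            assert h.pident >= params.min_pident
            assert toy_taxonomy.rank(h.staxids) == "species"
            assert h.subject_record_class != "ncRNA_other"


class TestHitTableIO:
    def test_round_trip_through_outfmt7_dialect(self, tmp_path, toy_taxonomy):
        db, seqs = _toy_db(toy_taxonomy)
        rows = search_db(seqs[10001], db, qseqid="sample|COI|forward|120")
        path = tmp_path / "hits.tsv"
        write_hit_table(rows, path)
        text = path.read_text()
        assert text.startswith("# ")
        assert "qseqid" in text
        back = read_hit_table(path)
        assert [h.staxids for h in back] == [h.staxids for h in rows]
        assert back[0].qseqid == "sample|COI|forward|120"
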