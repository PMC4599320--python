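import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampliclass import (
    AssignmentStatus,
    SequenceRecord,
    Strand,
    UndefinedScoreError,
    assign_levels,
    bootstrap_confidence,
    classify,
    extract_kmers,
    reverse_complement,
    similarity_score,
    top_hits,
)

from .conftest import make_db, random_db
from .oracles import brute_force_bootstrap, brute_force_top_hits

A_REGION = "ATATTAAATT"
B_REGION = "GCCGGGCGGC"


class TestExtractKmers:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ATTTGCG", 4, {"ATTT", "TTTG", "TTGC", "TGCG"}),
            ("GTTTGCG", 4, {"GTTT", "TTTG", "TTGC", "TGCG"}),
            ("AAAAA", 2, {"AA"}),
            ("ACNGT", 2, {"AC", "GT"}),  # windows spanning N are skipped
            ("AC", 4, set()),  # shorter than k
        ],
    )
    def test_enumeration(self, seq, k, expected):
        ks = extract_kmers(seq, k)
        assert ks.kmers == frozenset(expected)
        assert ks.source_length == len(seq)
        assert len(ks) <= max(0, len(seq) - k + 1)

    @given(st.text(alphabet="ACGTN", max_size=60), st.integers(1, 8))
    def test_members_are_valid_windows(self, seq, k):
        ks = extract_kmers(seq, k)
        for kmer in ks.kmers:
            assert len(kmer) == k and set(kmer) <= set("ACGT")
            assert kmer in seq


class TestSimilarityScore:
    def test_concatenation_swap_scores_high(self):
        # two-region sequence vs its region-swapped form: 14 of 17 4-mers shared
        query = extract_kmers(A_REGION + B_REGION, 4)
        ref = extract_kmers(B_REGION + A_REGION, 4)
        assert len(query) == 17
        assert similarity_score(query, ref) == pytest.approx(14 / 17)

    @pytest.mark.parametrize(
        "query,ref,expected",
        [
            ("GTTTGCG", "ATTTGCG", 3 / 4),  # substitution at the start
            ("ATTCGCG", "ATTTGCG", 0.0),  # substitution in the middle
            ("ATTTGCG", "ATTTGCG", 1.0),
        ],
    )
    def test_substitution_examples(self, query, ref, expected):
        score = similarity_score(extract_kmers(query, 4), extract_kmers(ref, 4))
        assert score == pytest.approx(expected)
        assert 0.0 <= score <= 1.0

    def test_empty_query_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            similarity_score(extract_kmers("AC", 4), extract_kmers("ACGTACGT", 4))

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_score(extract_kmers("ACGTACGT", 4), extract_kmers("ACGTACGT", 5))

    @given(st.text(alphabet="ACGT", min_size=8, max_size=60))
    def test_self_similarity_is_one(self, seq):
        ks = extract_kmers(seq, 4)
        assert similarity_score(ks, ks) == 1.0


class TestTopHits:
    def test_single_reference_start_substitution(self):
        db = make_db([("r1", "G", "G s", "ATTTGCG")], k=4)
        score, hits, strand = top_hits(SequenceRecord("q", "GTTTGCG"), db)
        assert (score, hits, strand) == (0.75, frozenset({"r1"}), Strand.FORWARD)

    def test_exact_match_scores_one_forward(self):
        db = make_db([("r1", "G", "G s", "ATTTGCGGA"), ("r2", "G", "G t", "CCCCCCCCC")], k=4)
        score, hits, strand = top_hits(SequenceRecord("q", "ATTTGCGGA"), db)
        assert score == 1.0 and hits == frozenset({"r1"}) and strand == Strand.FORWARD

    def test_reverse_complement_query_found_on_reverse_strand(self):
        seq = "ATTTGCGGATCCAGT"
        db = make_db([("r1", "G", "G s", seq)], k=4)
        score, hits, strand = top_hits(
            SequenceRecord("q", reverse_complement(seq)), db
        )
        assert score == 1.0 and hits == frozenset({"r1"})
        assert strand in (Strand.REVERSE, Strand.BOTH)
        expected = brute_force_top_hits(SequenceRecord("q", reverse_complement(seq)), db)
        assert (score, hits, strand) == expected

    def test_no_valid_kmers_signals_unassigned(self):
        db = make_db([("r1", "G", "G s", "ATTTGCG")], k=4)
        with pytest.raises(UndefinedScoreError):
            top_hits(SequenceRecord("q", "NNNNNN"), db)

    def test_matches_brute_force_on_random_databases(self):
        rng = np.random.default_rng(42)
        for trial in range(25):
            k = int(rng.choice([4, 8]))
            db = random_db(rng, n_refs=int(rng.integers(2, 15)), max_len=80, k=k)
            length = int(rng.integers(k, 60))
            query = SequenceRecord(
                "q", "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
            )
            got = top_hits(query, db)
            want = brute_force_top_hits(query, db)
            assert got[1] == want[1] and got[2] == want[2]
            assert math.isclose(got[0], want[0])

    def test_accumulated_counts_equal_direct_intersections(self):
        rng = np.random.default_rng(7)
        db = random_db(rng, n_refs=10, max_len=100, k=4)
        qk = extract_kmers("ACGTACGTTGCATGCA", 4)
        counts = db.index.shared_counts(qk.kmers)
        for rec_id, rec in db.records.items():
            direct = len(qk.kmers & extract_kmers(rec.sequence, 4).kmers)
            assert counts.get(rec_id, 0) == direct

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_substitutions_never_increase_score(self, seed):
        # mutate a copy of the reference at fresh positions; its score
        # against the original can only drop as substitutions accumulate
        rng = np.random.default_rng(seed)
        ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        ref_k = extract_kmers(ref, 8)
        positions = rng.permutation(150)[:20]
        seq = list(ref)
        prev = 1.0
        for pos in positions:
            seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1 + int(rng.integers(0, 3))) % 4]
            score = similarity_score(extract_kmers("".join(seq), 8), ref_k)
            assert score <= prev + 1e-12
            prev = score
        assert prev < 1.0


class TestAssignLevels:
    def test_singleton_hit_assigns_all_levels(self):
        db = make_db([("r1", "Bacillus", "Bacillus subtilis", "ATTTGCG")], k=4)
        out = assign_levels({"r1"}, db.taxonomy, db.level_names)
        assert all(a.status is AssignmentStatus.ASSIGNED for a in out)
        assert [a.label for a in out] == ["Bacillus", "Bacillus subtilis"]

    def test_species_ambiguity_leaves_genus_and_cluster_assigned(self):
        db = make_db(
            [
                ("r1", "Clostridium", "Clostridium butyricum", "ATTTGCG", "Cluster I"),
                ("r2", "Clostridium", "Clostridium beijerinckii", "ATTTGCG", "Cluster I"),
            ],
            k=4,
        )
        by_level = {a.level_name: a for a in assign_levels({"r1", "r2"}, db.taxonomy, db.level_names)}
        assert by_level["genus"].status is AssignmentStatus.ASSIGNED
        assert by_level["genus"].label == "Clostridium"
        assert by_level["species"].status is AssignmentStatus.AMBIGUOUS
        assert by_level["cluster"].status is AssignmentStatus.ASSIGNED
        assert by_level["cluster"].label == "Cluster I"

    def test_different_genera_are_ambiguous_everywhere(self):
        db = make_db(
            [("r1", "A", "A a", "ATTTGCG"), ("r2", "B", "B b", "ATTTGCG")], k=4
        )
        out = assign_levels({"r1", "r2"}, db.taxonomy, ["genus", "species"])
        assert all(a.status is AssignmentStatus.AMBIGUOUS for a in out)

    def test_partial_cluster_annotation_is_unassigned(self):
        db = make_db(
            [
                ("r1", "A", "A a", "ATTTGCG", "Cluster I"),
                ("r2", "A", "A a", "CTTTGCG"),
            ],
            k=4,
        )
        by_level = {a.level_name: a for a in assign_levels({"r1", "r2"}, db.taxonomy, db.level_names)}
        assert by_level["cluster"].status is AssignmentStatus.UNASSIGNED


class TestBootstrap:
    def test_single_reference_confidence_is_one(self):
        db = make_db([("r1", "G", "G s", "ATTTGCGGATCCAGTACGT")], k=4)
        query = SequenceRecord("q", "ATTTGCGGATCCAGTACGT")
        for n_boot in (1, 7, 40):
            result = classify(query, db, n_boot=n_boot, seed=1)
            for a in result.assignments:
                assert a.status is AssignmentStatus.ASSIGNED
                assert a.confidence == 1.0

    def test_forced_ambiguity_yields_no_species_confidence(self):
        seq = "ATTTGCGGATCCAGTACGT"
        db = make_db([("r1", "G", "G a", seq), ("r2", "G", "G b", seq)], k=4)
        result = classify(SequenceRecord("q", seq), db, n_boot=10, seed=0)
        assert result.species.status is AssignmentStatus.AMBIGUOUS
        assert result.species.confidence is None
        genus = result.assignment("genus")
        assert genus.status is AssignmentStatus.ASSIGNED
        assert genus.confidence == 1.0
        assert result.ambiguous_labels["species"] == ["G a", "G b"]

    def test_matches_brute_force_oracle(self, well_separated_db):
        db = well_separated_db
        # light mutation of one reference of a well-separated species
        base = db.records["G1_S1_R1"].sequence
        mutated = base[:50] + "ACGT"[("ACGT".index(base[50]) + 1) % 4] + base[51:]
        query = SequenceRecord("q", mutated)
        _, hits, _ = top_hits(query, db)
        assignments = assign_levels(hits, db.taxonomy, db.level_names)
        qk = extract_kmers(mutated, db.k)
        for seed in (0, 5, 123):
            got = bootstrap_confidence(qk, db, assignments, n_boot=25, seed=seed)
            want = brute_force_bootstrap(qk, db, assignments, n_boot=25, seed=seed)
            assert got == want

    def test_confidence_invariant_under_reference_order(self):
        entries = [
            ("r1", "A", "A a", "ATTTGCGGATCCAGTACGTAAAT"),
            ("r2", "B", "B b", "CCGGTTAACCGGTTAACCGGTTA"),
            ("r3", "A", "A c", "ATTTGCGGATCCAGAACGTAAAT"),
        ]
        query = SequenceRecord("q", "ATTTGCGGATCCAGTACGTAAAT")
        results = []
        for order in (entries, entries[::-1]):
            db = make_db(order, k=4)
            results.append(classify(query, db, n_boot=30, seed=9))
        first, second = results
        assert [(a.level_name, a.label, a.confidence) for a in first.assignments] == [
            (a.level_name, a.label, a.confidence) for a in second.assignments
        ]


class TestClassify:
    def test_composed_start_substitution_scenario(self):
        db = make_db([("r1", "Bacillus", "Bacillus subtilis", "ATTTGCG")], k=4)
        result = classify(SequenceRecord("q", "GTTTGCG"), db, n_boot=10, seed=0)
        assert result.best_score == pytest.approx(0.75)
        assert result.species.status is AssignmentStatus.ASSIGNED
        assert result.species.label == "Bacillus subtilis"
        assert result.species.confidence == 1.0

    def test_empty_and_kmerless_queries_are_unassigned(self):
        db = make_db([("r1", "G", "G s", "ATTTGCG")], k=4)
        for seq in ("", "AC", "NNNNNNNN"):
            result = classify(SequenceRecord("q", seq), db)
            assert result.best_score == 0.0
            assert all(a.status is AssignmentStatus.UNASSIGNED for a in result.assignments)
            assert result.hit_ids == frozenset()

    def test_strand_invariance(self, well_separated_db):
        db = well_separated_db
        for rec_id in ("G1_S2_R1", "G3_S4_R2"):
            seq = db.records[rec_id].sequence
            fwd = classify(SequenceRecord("q", seq), db, n_boot=5, seed=2)
            rev = classify(SequenceRecord("q", reverse_complement(seq)), db, n_boot=5, seed=2)
            assert fwd.best_score == rev.best_score
            assert fwd.hit_ids == rev.hit_ids
            assert [(a.level_name, a.label, a.status) for a in fwd.assignments] == [
                (a.level_name, a.label, a.status) for a in rev.assignments
            ]
            assert {fwd.strand, rev.strand} <= {Strand.FORWARD, Strand.REVERSE, Strand.BOTH}

    def test_best_score_equals_score_against_every_hit(self):
        rng = np.random.default_rng(3)
        db = random_db(rng, n_refs=12, max_len=60, k=4)
        query = SequenceRecord("q", "ACGTTGCAACGTTGCA")
        result = classify(query, db)
        assert result.hit_ids, "fixture should produce at least one hit"
        qk_fwd = extract_kmers(query.sequence, db.k)
        qk_rev = extract_kmers(reverse_complement(query.sequence), db.k)
        for hit in result.hit_ids:
            rk = extract_kmers(db.records[hit].sequence, db.k)
            best_for_hit = max(
                similarity_score(qk_fwd, rk), similarity_score(qk_rev, rk)
            )
            assert math.isclose(result.best_score, best_for_hit)
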