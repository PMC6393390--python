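"""Local alignment and F-segment database mining."""

from functools import lru_cache

import numpy as np
import pytest

from dehydrin.motif_scan import F_EXPANDED, blosum62_score, default_motifs
from dehydrin.segment_mining import (
    alignment_is_gapped,
    copy_number_table,
    filter_gapped_segments,
    local_align,
    mine_database,
)
from dehydrin.seqio import SequenceRecord
from dehydrin.synthetic_data import simulate_segment_db


def sw_oracle(query: str, target: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Brute-force local alignment score by suffix recursion.

    Independently of the matrix DP: from any start pair, recursively either
    stop, align a residue pair, or extend a gap (first gap residue costs
    open + extend, continuation costs extend).  The best over all start
    pairs is the Smith-Waterman score.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        options = [0.0]  # stopping is always allowed (local alignment)
        if i < len(query) and j < len(target):
            options.append(
                blosum62_score(query[i], target[j]) + best(i + 1, j + 1, "m")
            )
        if j < len(target):  # gap in query, consumes target
            cost = gap_extend if state == "gt" else gap_open + gap_extend
            options.append(-cost + best(i, j + 1, "gt"))
        if i < len(query):  # gap in target, consumes query
            cost = gap_extend if state == "gq" else gap_open + gap_extend
            options.append(-cost + best(i + 1, j, "gq"))
        return max(options)

    return max(
        best(i, j, "m")
        for i in range(len(query) + 1)
        for j in range(len(target) + 1)
    )


class TestLocalAlign:
    def test_identical_segments_self_align(self):
        aln = local_align(F_EXPANDED, F_EXPANDED)
        self_score = sum(blosum62_score(c, c) for c in F_EXPANDED)
        assert aln.score == self_score
        assert (aln.q_start, aln.q_end, aln.t_start, aln.t_end) == (1, 18, 1, 18)
        assert aln.identity == 1.0 and not aln.gapped

    def test_oppositely_charged_homopolymers_have_no_alignment(self):
        aln = local_align("KKKK", "DDDD")
        assert aln.score == 0
        assert aln.aligned_query == "" and aln.aligned_target == ""

    def test_aligned_strings_recover_coordinate_slices(self):
        target = "GGG" + F_EXPANDED[:9] + "CG" + F_EXPANDED[9:] + "GGG"
        aln = local_align(F_EXPANDED, target)
        assert aln.aligned_query.replace("-", "") == F_EXPANDED[aln.q_start - 1 : aln.q_end]
        assert aln.aligned_target.replace("-", "") == target[aln.t_start - 1 : aln.t_end]
        assert len(aln.aligned_query) == len(aln.aligned_target)

    def test_score_equals_rescoring_the_alignment(self):
        target = "GGG" + F_EXPANDED[:9] + "CG" + F_EXPANDED[9:] + "GGG"
        aln = local_align(F_EXPANDED, target)
        score, open_gap = 0.0, {"q": False, "t": False}
        for a, b in zip(aln.aligned_query, aln.aligned_target):
            if a == "-":
                score -= 1.0 if open_gap["q"] else 12.0
                open_gap["q"], open_gap["t"] = True, False
            elif b == "-":
                score -= 1.0 if open_gap["t"] else 12.0
                open_gap["t"], open_gap["q"] = True, False
            else:
                score += blosum62_score(a, b)
                open_gap["q"] = open_gap["t"] = False
        assert score == aln.score

    def test_matches_brute_force_oracle_on_random_short_pairs(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            q = "".join(rng.choice(aas, size=int(rng.integers(1, 11))))
            t = "".join(rng.choice(aas, size=int(rng.integers(1, 11))))
            assert local_align(q, t).score == sw_oracle(q, t), (q, t)

    def test_score_is_symmetric(self):
        rng = np.random.default_rng(5)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            a = "".join(rng.choice(aas, size=int(rng.integers(3, 15))))
            b = "".join(rng.choice(aas, size=int(rng.integers(3, 15))))
            assert local_align(a, b).score == local_align(b, a).score

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MK")


class TestMineDatabase:
    @pytest.fixture
    def f_motif(self):
        return default_motifs()["F_expanded"]

    def test_motif_itself_yields_single_full_span_hit(self, f_motif):
        db = [SequenceRecord("q", F_EXPANDED)]
        res = mine_database(f_motif, db)
        assert list(res.hits) == ["q"]
        (hit,) = res.hits["q"]
        assert (hit.start, hit.end) == (1, 18)

    def test_exact_duplicates_are_merged(self, f_motif):
        db = [
            SequenceRecord("a", F_EXPANDED),
            SequenceRecord("b", F_EXPANDED),
        ]
        res = mine_database(f_motif, db)
        assert res.removed_duplicates == 1
        assert res.n_hits() == 1

    def test_empty_database_rejected(self, f_motif):
        with pytest.raises(ValueError):
            mine_database(f_motif, [])

    def test_planted_database_recovered_exactly_without_mutation(self, f_motif):
        """Sensitivity 1.0, no false discoveries, exact coordinates at rate 0."""
        db = simulate_segment_db(n_proteins=30, mutation_rate=0.0, seed=17)
        res = mine_database(f_motif, db.records)
        for pid, segs in db.truth.items():
            found = {(m.start, m.end) for m in res.hits.get(pid, [])}
            assert found == {(s.start, s.end) for s in segs}

    def test_planted_database_recovered_under_mutation(self, f_motif):
        """At 5% substitutions every planted copy maps one-to-one to a hit
        covering >= 80% of it, with no spurious hits (optimal local
        alignments may trim mutated segment termini)."""
        db = simulate_segment_db(n_proteins=30, mutation_rate=0.05, seed=17)
        res = mine_database(f_motif, db.records)
        for pid, segs in db.truth.items():
            hits = res.hits.get(pid, [])
            assert len(hits) == len(segs)
            for seg in segs:
                overlaps = [
                    m
                    for m in hits
                    if min(m.end, seg.end) - max(m.start, seg.start) + 1
                    >= 0.8 * (seg.end - seg.start + 1)
                ]
                assert len(overlaps) == 1

    def test_hits_never_overlap_and_rescore_above_threshold(self, f_motif):
        db = simulate_segment_db(n_proteins=15, copy_distribution={3: 1.0}, seed=2)
        res = mine_database(f_motif, db.records)
        cutoff = 0.5 * f_motif.self_score()
        for matches in res.hits.values():
            for m in matches:
                assert m.score >= cutoff
            starts = sorted((m.start, m.end) for m in matches)
            for (s1, e1), (s2, e2) in zip(starts, starts[1:]):
                assert e1 < s2

    def test_dedup_is_order_independent(self, f_motif):
        recs = [
            SequenceRecord("a", "GTE" * 10 + F_EXPANDED),
            SequenceRecord("b", F_EXPANDED + "AKE" * 10),
            SequenceRecord("c", "GTE" * 10 + F_EXPANDED),  # duplicate of a
        ]
        fwd = mine_database(f_motif, recs)
        rev = mine_database(f_motif, recs[::-1])
        assert fwd.removed_duplicates == rev.removed_duplicates == 1
        fwd_spans = {tuple((m.start, m.end) for m in v) for v in fwd.hits.values()}
        rev_spans = {tuple((m.start, m.end) for m in v) for v in rev.hits.values()}
        assert fwd_spans == rev_spans


class TestGapFilter:
    @pytest.fixture
    def f_motif(self):
        return default_motifs()["F_expanded"]

    def test_cg_insertion_segment_is_removed(self, f_motif):
        inserted = F_EXPANDED[:9] + "CG" + F_EXPANDED[9:]
        assert alignment_is_gapped(inserted, F_EXPANDED)
        db = [SequenceRecord("ins", "GGG" + inserted + "GGG")]
        res = filter_gapped_segments(mine_database(f_motif, db), f_motif)
        assert res.removed_gapped == 1
        assert res.n_hits() == 0

    def test_substituted_segment_is_retained(self, f_motif):
        mutated = list(F_EXPANDED)
        mutated[2], mutated[10] = "A", "A"
        mutated = "".join(mutated)
        assert not alignment_is_gapped(mutated, F_EXPANDED)
        db = [SequenceRecord("sub", mutated)]
        res = filter_gapped_segments(mine_database(f_motif, db), f_motif)
        assert res.removed_gapped == 0
        assert res.n_hits() == 1

    def test_empty_result_passes_through(self, f_motif):
        from dehydrin.segment_mining import MiningResult

        res = filter_gapped_segments(MiningResult(hits={}), f_motif)
        assert res.hits == {} and res.removed_gapped == 0


class TestCopyNumberTable:
    def test_counts_classes_and_sort_order(self):
        f_motif = default_motifs()["F_expanded"]
        db = simulate_segment_db(
            n_proteins=9, copy_distribution={0: 1 / 3, 2: 1 / 3, 3: 1 / 3}, seed=23
        )
        res = mine_database(f_motif, db.records)
        table = copy_number_table(res)
        truth = db.copy_counts()
        assert set(table["protein_id"]) == {p for p, c in truth.items() if c > 0}
        for _, row in table.iterrows():
            assert row["copies"] == truth[row["protein_id"]]
            assert row["f_class"] == f"F{row['copies']}"
        copies = table["copies"].tolist()
        assert copies == sorted(copies, reverse=True)
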