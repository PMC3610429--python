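from __future__ import annotations

import pytest

from orthotrace.records import GenomeAnnotation, OrthologyGroups
from orthotrace.synteny import (
    assign_by_synteny,
    score_candidates,
    syntenic_score,
    window,
)

from oracles import optimal_matching_score, synteny_count_oracle


class TestWindow:
    @pytest.fixture()
    def chrom20(self):
        return GenomeAnnotation({"at": {"chr1": [f"g{i:02d}" for i in range(20)]}})

    def test_edge_truncation_at_chromosome_start(self, chrom20):
        assert window("g00", chrom20, 7) == [f"g{i:02d}" for i in range(1, 8)]

    def test_interior_gene_full_window(self):
        ann = GenomeAnnotation({"at": {"chr1": [f"g{i:02d}" for i in range(21)]}})
        win = window("g10", ann, 7)
        assert len(win) == 14
        assert "g10" not in win

    def test_w_one_gives_at_most_two(self, chrom20):
        assert window("g05", chrom20, 1) == ["g04", "g06"]
        assert window("g19", chrom20, 1) == ["g18"]

    def test_absent_gene_is_error(self, chrom20):
        with pytest.raises(KeyError):
            window("nope", chrom20, 7)


class TestSyntenicScore:
    def test_disjoint_windows_score_zero(self, duplicated_genome):
        annotation, groups, a_genes, b_genes = duplicated_genome
        # decoy pairing of opposite chromosome ends shares no group in window
        s = syntenic_score(a_genes[0], b_genes[29], annotation, groups)
        assert s.total == 0

    def test_verbatim_duplication_interior_pair_scores_full_window(
        self, duplicated_genome
    ):
        annotation, groups, a_genes, b_genes = duplicated_genome
        s = syntenic_score(a_genes[15], b_genes[15], annotation, groups)
        assert s.per_method == {"m1": 14, "m2": 14}
        assert s.total == 28

    def test_matches_brute_force_window_scan(self, rng):
        for _ in range(25):
            n = 12
            a_genes = [f"a{i}" for i in range(n)]
            b_genes = [f"b{i}" for i in range(n)]
            annotation = GenomeAnnotation(
                {"at": {"c": a_genes}, "sl": {"c": b_genes}}
            )
            # random partial orthology: each a-gene pairs with a distinct b-gene
            raw_groups = []
            perm = rng.permutation(n)
            for i, a in enumerate(a_genes):
                if rng.random() < 0.7:
                    raw_groups.append({("at", a), ("sl", b_genes[perm[i]])})
            groups = {"m": OrthologyGroups("m", raw_groups)}
            w = int(rng.integers(1, 4))
            ga = a_genes[int(rng.integers(0, n))]
            gb = b_genes[int(rng.integers(0, n))]
            s = syntenic_score(ga, gb, annotation, groups, w=w)
            win_a = window(ga, annotation, w)
            win_b = window(gb, annotation, w)
            group_list = [set(g) for g in groups["m"].groups]
            ab = synteny_count_oracle(win_a, win_b, "at", "sl", group_list)
            ba = synteny_count_oracle(win_b, win_a, "sl", "at", group_list)
            assert s.per_method["m"] == min(ab, ba)
            assert s.directional["m"] == (ab, ba)

    def test_monotone_in_window_size(self, duplicated_genome):
        annotation, groups, a_genes, b_genes = duplicated_genome
        prev = -1
        for w in range(1, 8):
            s = syntenic_score(a_genes[10], b_genes[10], annotation, groups, w=w)
            assert s.per_method["m1"] >= prev
            prev = s.per_method["m1"]

    def test_invariant_under_relabeling(self, duplicated_genome):
        annotation, groups, a_genes, b_genes = duplicated_genome
        ren = {g: f"X{g}" for g in a_genes + b_genes}
        annotation2 = GenomeAnnotation(
            {
                "at": {"K": [ren[g] for g in a_genes]},
                "sl": {"L": [ren[g] for g in b_genes]},
            }
        )
        groups2 = {
            m: OrthologyGroups(m, [{(sp, ren[g]) for sp, g in fs} for fs in gr.groups])
            for m, gr in groups.items()
        }
        s1 = syntenic_score(a_genes[9], b_genes[9], annotation, groups)
        s2 = syntenic_score(ren[a_genes[9]], ren[b_genes[9]], annotation2, groups2)
        assert s1.per_method == s2.per_method

    def test_pairs_count_unit_counts_every_pair(self):
        a_genes = ["a0", "a1", "a2"]
        b_genes = ["b0", "b1", "b2"]
        annotation = GenomeAnnotation({"at": {"c": a_genes}, "sl": {"c": b_genes}})
        # a0 co-grouped with both b0 and b2
        groups = {
            "m": OrthologyGroups("m", [{("at", "a0"), ("sl", "b0"), ("sl", "b2")}])
        }
        s_genes = syntenic_score("a1", "b1", annotation, groups, w=2, count_unit="genes")
        s_pairs = syntenic_score("a1", "b1", annotation, groups, w=2, count_unit="pairs")
        assert s_genes.per_method["m"] == 1
        assert s_pairs.per_method["m"] == 2


class TestAssignBySynteny:
    def test_dominant_diagonal_both_flagged(self):
        cands = [("a1", "t1"), ("a1", "t2"), ("a2", "t1"), ("a2", "t2")]
        scores = {("a1", "t1"): 10, ("a1", "t2"): 0, ("a2", "t1"): 0, ("a2", "t2"): 8}
        assert assign_by_synteny(cands, scores) == [
            (("a1", "t1"), True),
            (("a2", "t2"), True),
        ]

    def test_all_zero_scores_no_flags(self):
        cands = [("a1", "t1"), ("a1", "t2")]
        result = assign_by_synteny(cands, {p: 0 for p in cands})
        assert all(not flagged for _, flagged in result)

    def test_tie_matches_without_flag(self):
        cands = [("a1", "t1"), ("a1", "t2")]
        scores = {("a1", "t1"): 5, ("a1", "t2"): 5}
        ((pair, flagged),) = assign_by_synteny(cands, scores)
        assert pair == ("a1", "t1") and not flagged

    def test_greedy_vs_exhaustive_optimal_on_random_matrices(self, rng):
        disagreements = 0
        for _ in range(60):
            na, nb = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            cands = [(f"a{i}", f"t{j}") for i in range(na) for j in range(nb)]
            scores = {p: int(rng.integers(0, 10)) for p in cands}
            greedy = assign_by_synteny(cands, scores)
            greedy_total = sum(scores[p] for p, _ in greedy)
            best = optimal_matching_score(cands, scores)
            assert greedy_total <= best
            if greedy_total < best:
                disagreements += 1
            opt = assign_by_synteny(cands, scores, optimal=True)
            assert sum(scores[p] for p, _ in opt) == best
        # greedy is near-optimal at these sizes; a few disagreements are expected
        assert disagreements < 15

    def test_score_candidates_totals_feed_assignment(self, duplicated_genome):
        annotation, groups, a_genes, b_genes = duplicated_genome
        cands = [(a_genes[10], b_genes[10]), (a_genes[10], b_genes[25])]
        scored = score_candidates(cands, annotation, groups)
        totals = {p: s.total for p, s in scored.items()}
        ((top, flagged),) = assign_by_synteny(cands, totals)
        assert top == (a_genes[10], b_genes[10]) and flagged
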