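from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthotrace.domains import (
    Architecture,
    EquivalenceMap,
    agreement_statistic,
    architectures_equal,
    build_architecture,
    detect_fusion,
)
from orthotrace.records import DomainHit, GenomeAnnotation, OrthologyGroups
from orthotrace.simulate import SimConfig, generate_dataset

from oracles import fusion_pairs_oracle, overlap_resolution_oracle


class TestBuildArchitecture:
    def test_three_consecutive_wd40_repeats_kept_distinct(self):
        hits = [
            DomainHit("g", "WD40", 10, 40, 20.0),
            DomainHit("g", "WD40", 50, 80, 20.0),
            DomainHit("g", "WD40", 90, 120, 20.0),
        ]
        assert build_architecture(hits).domains == ("WD40", "WD40", "WD40")

    def test_same_interval_keeps_higher_score(self):
        hits = [
            DomainHit("g", "A", 1, 50, 30.0),
            DomainHit("g", "B", 1, 50, 10.0),
        ]
        assert build_architecture(hits).domains == ("A",)

    def test_score_tie_keeps_lower_start(self):
        hits = [
            DomainHit("g", "A", 5, 60, 10.0),
            DomainHit("g", "B", 10, 60, 10.0),
        ]
        assert build_architecture(hits).domains == ("A",)

    def test_half_overlap_boundary_keeps_both(self):
        # overlap of exactly 50% of the shorter hit does not trigger the rule
        hits = [
            DomainHit("g", "A", 1, 20, 5.0),  # len 20
            DomainHit("g", "B", 11, 40, 50.0),  # overlap 10 == 0.5 * 20
        ]
        assert build_architecture(hits).domains == ("A", "B")

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        for _ in range(80):
            n = int(rng.integers(1, 9))
            hits = []
            for _ in range(n):
                start = int(rng.integers(1, 80))
                end = start + int(rng.integers(5, 40))
                hits.append(
                    DomainHit(
                        "g",
                        f"D{rng.integers(0, 5)}",
                        start,
                        end,
                        float(rng.integers(1, 6)) * 10,
                    )
                )
            expected = tuple(h.domain_name for h in overlap_resolution_oracle(hits))
            assert build_architecture(hits).domains == expected


class TestEquality:
    def test_identical_single_domain(self):
        a = Architecture("x", ("SRP54",))
        b = Architecture("y", ("SRP54",))
        assert architectures_equal(a, b, EquivalenceMap.identity())

    def test_ring_variants_equal_under_default_map(self):
        a = Architecture("x", ("RING_2",))
        b = Architecture("y", ("C3HC4_2",))
        assert architectures_equal(a, b, EquivalenceMap.default())
        assert not architectures_equal(a, b, EquivalenceMap.identity())

    def test_order_matters(self):
        a = Architecture("x", ("WD40", "RING_2"))
        b = Architecture("y", ("RING_2", "WD40"))
        assert not architectures_equal(a, b, EquivalenceMap.default())

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        archs=st.lists(
            st.tuples(
                st.lists(st.sampled_from(["RING_2", "C3HC4_2", "WD40", "PX"]),
                         min_size=1, max_size=4)
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_equivalence_relation(self, archs):
        eq = EquivalenceMap.default()
        a, b, c = (Architecture(f"g{i}", tuple(d[0])) for i, d in enumerate(archs))
        assert architectures_equal(a, a, eq)  # reflexive
        assert architectures_equal(a, b, eq) == architectures_equal(b, a, eq)
        if architectures_equal(a, b, eq) and architectures_equal(b, c, eq):
            assert architectures_equal(a, c, eq)  # transitive


class TestAgreementStatistic:
    def _arch(self, pairs):
        return {g: Architecture(g, tuple(doms)) for g, doms in pairs.items()}

    def test_identical_duplicated_proteomes_give_one(self):
        groups = OrthologyGroups(
            "m", [[("at", f"a{i}"), ("sl", f"t{i}")] for i in range(5)]
        )
        archs = self._arch(
            {f"a{i}": ["D1", "D2"] for i in range(5)}
            | {f"t{i}": ["D1", "D2"] for i in range(5)}
        )
        assert agreement_statistic(groups, archs, "at", "sl") == 1.0

    def test_one_planted_change_among_ten_pairs(self):
        groups = OrthologyGroups(
            "m", [[("at", f"a{i}"), ("sl", f"t{i}")] for i in range(10)]
        )
        archs = self._arch(
            {f"a{i}": ["D1"] for i in range(10)}
            | {f"t{i}": ["D1"] for i in range(9)}
            | {"t9": ["D2"]}
        )
        assert agreement_statistic(groups, archs, "at", "sl") == pytest.approx(18 / 20)

    def test_empty_groups_is_error(self):
        groups = OrthologyGroups("m", [])
        with pytest.raises(ValueError):
            agreement_statistic(groups, {}, "at", "sl")

    def test_equals_one_on_architecture_preserving_simulation(self):
        # loss 0 so every family keeps cross-species members; architectures
        # are inherited unchanged, so every grouped protein must match
        ds = generate_dataset(SimConfig(seed=3, n_ancestral_genes=40, loss_prob=0.0))
        stat = agreement_statistic(
            ds.truth.groups,
            ds.architectures(),
            ds.config.species_a,
            ds.config.species_b,
        )
        assert stat == 1.0


class TestDetectFusion:
    @pytest.fixture()
    def fig_case(self):
        annotation = GenomeAnnotation(
            {
                "at": {"chr1": ["AT1G21651"]},
                "sl": {"chr11": ["Solyc11g005040", "Solyc11g005030"]},
            }
        )
        archs = {
            "AT1G21651": Architecture("AT1G21651", ("RING_2", "WD40", "WD40", "WD40")),
            "Solyc11g005040": Architecture("Solyc11g005040", ("C3HC4_2",)),
            "Solyc11g005030": Architecture(
                "Solyc11g005030", ("WD40", "WD40", "WD40")
            ),
        }
        return annotation, archs

    def test_split_gene_found_through_class_map(self, fig_case):
        annotation, archs = fig_case
        assert detect_fusion("AT1G21651", "sl", annotation, archs) == [
            ("Solyc11g005040", "Solyc11g005030")
        ]

    def test_single_domain_architecture_cannot_be_a_fusion(self, fig_case):
        annotation, archs = fig_case
        archs = dict(archs) | {"X": Architecture("X", ("RING_2",))}
        annotation2 = GenomeAnnotation(
            {"at": {"chr1": ["X"]}, "sl": {"chr11": ["Solyc11g005040", "Solyc11g005030"]}}
        )
        assert detect_fusion("X", "sl", annotation2, archs) == []

    def test_missing_architecture_warns_and_returns_empty(self, fig_case):
        annotation, archs = fig_case
        with pytest.warns(UserWarning, match="no architecture"):
            assert detect_fusion("nosuch", "sl", annotation, archs) == []

    def test_matches_exhaustive_concatenation_oracle(self, rng):
        domains = ["D0", "D1", "D2", "D3"]
        for trial in range(40):
            genes = [f"g{i}" for i in range(8)]
            archs = {
                g: Architecture(
                    g,
                    tuple(rng.choice(domains, size=int(rng.integers(1, 4)))),
                )
                for g in genes
            }
            target_arch = tuple(rng.choice(domains, size=int(rng.integers(2, 5))))
            archs["X"] = Architecture("X", target_arch)
            annotation = GenomeAnnotation({"at": {"c": ["X"]}, "sl": {"c": genes}})
            max_gap = int(rng.integers(1, 4))
            got = detect_fusion(
                "X", "sl", annotation, archs, EquivalenceMap.identity(), max_gap
            )
            expected = fusion_pairs_oracle(
                target_arch, genes, {g: archs[g].domains for g in genes}, max_gap
            )
            assert got == expected

    def test_zero_false_positives_without_planted_fusions(self):
        for seed in (1, 2, 3):
            ds = generate_dataset(
                SimConfig(
                    seed=seed,
                    n_ancestral_genes=30,
                    fusion_prob=0.0,
                    domain_alphabet_size=200,  # architectures effectively distinct
                )
            )
            archs = ds.architectures()
            assert ds.truth.fusions == []
            for bait in list(ds.truth.factor_baits.values())[:10]:
                arch = archs[bait]
                if len(arch.domains) < 2:
                    continue
                hits = detect_fusion(bait, ds.config.species_b, ds.annotation, archs)
                # any hit must coincidentally share the full architecture split;
                # with a 30-name alphabet this must not happen
                assert hits == []
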