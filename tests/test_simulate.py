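from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pytest

from orthotrace.consolidate import map_factors_to_groups, overlap_statistic
from orthotrace.records import OrthologyGroups
from orthotrace.simulate import (
    Event,
    SimConfig,
    TruthTable,
    emulate_method_outputs,
    generate_dataset,
    simulate_ancestor,
)


def _bundle_digest(config: SimConfig, outdir: Path) -> str:
    generate_dataset(config).write(outdir)
    h = hashlib.sha256()
    for p in sorted(outdir.iterdir()):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


class TestAncestor:
    def test_gene_count_and_ranks(self):
        cfg = SimConfig(seed=0, n_ancestral_genes=10, n_chromosomes=1)
        anc = simulate_ancestor(cfg)
        assert len(anc) == 10
        assert [a.chromosome for a in anc] == ["chr1"] * 10

    def test_seeded_reproducibility(self):
        cfg = SimConfig(seed=4, n_ancestral_genes=15)
        a1 = simulate_ancestor(cfg)
        a2 = simulate_ancestor(cfg)
        assert [(g.gene_id, g.seq, g.architecture) for g in a1] == [
            (g.gene_id, g.seq, g.architecture) for g in a2
        ]

    def test_architecture_lengths_within_configured_range(self):
        cfg = SimConfig(seed=1, n_ancestral_genes=60, architecture_length_range=(2, 4))
        anc = simulate_ancestor(cfg)
        assert all(2 <= len(g.architecture) <= 4 for g in anc)


class TestLineageEvolution:
    def test_full_retention_no_loss_doubles_gene_count(self):
        cfg = SimConfig(
            seed=2,
            n_ancestral_genes=40,
            events_a=(Event("wgd", 1.0),),
            events_b=(),
            loss_prob=0.0,
        )
        ds = generate_dataset(cfg)
        assert len(ds.genes["spA"]) == 80
        assert len(ds.genes["spB"]) == 40

    def test_triplication_with_full_retention_triples(self):
        cfg = SimConfig(
            seed=2,
            n_ancestral_genes=30,
            events_a=(),
            events_b=(Event("triplication", 1.0),),
            loss_prob=0.0,
        )
        ds = generate_dataset(cfg)
        assert len(ds.genes["spB"]) == 90

    def test_expected_count_under_wgd_retention_and_loss(self):
        # E[count] = n * (1 + p) * (1 - q); check within 3 binomial sd over seeds
        n, p, q = 300, 0.3, 0.1
        counts = []
        for seed in range(5):
            cfg = SimConfig(
                seed=seed,
                n_ancestral_genes=n,
                events_a=(Event("wgd", p),),
                events_b=(),
                loss_prob=q,
                rearrangement_ops=0,
            )
            counts.append(len(generate_dataset(cfg).genes["spA"]))
        expected = n * (1 + p) * (1 - q)
        var = n * (p * (1 - p) * (1 - q) ** 2) + n * (1 + p) * q * (1 - q)
        sd = np.sqrt(var)
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(len(counts))

    def test_planted_fusions_logged_with_adjacent_partners(self):
        ds = generate_dataset(SimConfig(seed=7, n_ancestral_genes=60, fusion_prob=0.3))
        assert ds.truth.fusions
        for fused, p1, p2 in ds.truth.fusions:
            sp1, c1, r1 = ds.annotation.locate(p1)
            sp2, c2, r2 = ds.annotation.locate(p2)
            assert sp1 == sp2 and c1 == c2 and abs(r1 - r2) == 1
            # fused copy carries the concatenated architecture
            archs = ds.architectures()
            assert archs[fused].domains == archs[p1].domains + archs[p2].domains

    def test_every_surviving_gene_in_exactly_one_planted_group(self, small_dataset):
        ds = small_dataset
        membership = {}
        for fs in ds.truth.groups.groups:
            for m in fs:
                assert m not in membership
                membership[m] = fs
        # genes outside groups are those whose family survived as a singleton
        all_genes = {(sp, g.gene_id) for sp, gl in ds.genes.items() for g in gl}
        assert set(membership) <= all_genes


class TestEmulation:
    def _toy_truth(self, n_groups=20, group_size=3):
        truth = TruthTable()
        groups = []
        for i in range(n_groups):
            members = [("spA", f"a{i}")] + [
                ("spB", f"b{i}_{j}") for j in range(group_size - 1)
            ]
            groups.append(members)
            truth.factor_baits[f"F{i}"] = f"a{i}"
        truth.groups = OrthologyGroups("planted", groups)
        return truth

    def test_d_zero_gives_identical_methods(self):
        truth = self._toy_truth()
        out = emulate_method_outputs(truth, 0.0, np.random.default_rng(0))
        assert out["pgap"] == out["mcl"]

    def test_d_one_perturbs_every_factor_group(self):
        truth = self._toy_truth()
        out = emulate_method_outputs(truth, 1.0, np.random.default_rng(0))
        assert all(
            g not in set(out["pgap"].groups) for g in out["mcl"].groups
        )

    def test_perturbed_fraction_within_binomial_band(self):
        truth = self._toy_truth(n_groups=500)
        out = emulate_method_outputs(truth, 0.2, np.random.default_rng(3))
        planted = set(out["pgap"].groups)
        perturbed = sum(1 for g in out["mcl"].groups if g not in planted)
        # binomial 99% band around 0.2 with n=500
        sd = np.sqrt(0.2 * 0.8 / 500)
        assert abs(perturbed / 500 - 0.2) < 2.58 * sd


class TestDeterminismAndRecovery:
    def test_bundle_byte_identical_for_same_seed(self, tmp_path):
        cfg = SimConfig(seed=13, n_ancestral_genes=25, fusion_prob=0.1)
        d1 = _bundle_digest(cfg, tmp_path / "r1")
        d2 = _bundle_digest(cfg, tmp_path / "r2")
        assert d1 == d2

    def test_different_seeds_differ(self, tmp_path):
        a = _bundle_digest(SimConfig(seed=1, n_ancestral_genes=25), tmp_path / "s1")
        b = _bundle_digest(SimConfig(seed=2, n_ancestral_genes=25), tmp_path / "s2")
        assert a != b

    def test_clean_conditions_recover_all_one_to_one_pairs(self):
        cfg = SimConfig(
            seed=21,
            n_ancestral_genes=30,
            events_a=(),
            events_b=(),
            loss_prob=0.0,
            substitution_rate=0.0,
            method_disagreement_rate=0.0,
        )
        ds = generate_dataset(cfg)
        records = map_factors_to_groups(
            ds.inventory, ds.groups_by_method, ["spA", "spB"]
        )
        assert overlap_statistic(records) == 1.0
        by_bait = {
            [g for s, g in r.baits if s == "spA"][0]: r for r in records
        }
        for a, b, rel in ds.truth.pairs:
            assert rel == "one2one"
            assert b in by_bait[a].consensus("spB")
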