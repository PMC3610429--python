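"""Paired-genome simulator with planted truth.

Two descendant proteomes are evolved from a common ancestor under the
duplication history the inventory analysis assumes: lineage A undergoes two
rounds of whole-genome duplication, lineage B a single whole-genome
triplication, each retained copy surviving independently.  Gene loss, local
gene-order rearrangement (composed adjacent transpositions), split-gene
(fusion/fission) events, uniform per-site sequence substitution, and
4-tissue expression profiles with platform-specific scale factors and
lognormal noise complete the picture.  Every event is logged to a
:class:`TruthTable`, so each pipeline stage can be scored against planted
ground truth.

All randomness descends from one master seed through spawned NumPy
generator streams (one per sub-process), so any part of a dataset can be
regenerated independently and the whole bundle is byte-identical across
runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import io as otio
from .domains import Architecture
from .records import (
    CANONICAL_TISSUES,
    DomainHit,
    ExpressionProfile,
    FactorEntry,
    FactorInventory,
    GenomeAnnotation,
    Member,
    OrthologyGroups,
)
from .report import PipelineInputs

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Event:
    """One polyploidisation event: each gene gains ``extra_copies`` duplicates,
    each independently retained with probability ``retention``."""

    kind: str  # {"wgd", "triplication"}
    retention: float

    @property
    def extra_copies(self) -> int:
        if self.kind == "wgd":
            return 1
        if self.kind == "triplication":
            return 2
        raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class ExpressionSettings:
    profile_sd: float = 1.0  # lognormal sigma of ancestral tissue profiles
    noise_sd: float = 0.25  # per-copy lognormal noise sigma
    platforms: tuple[str, str] = ("microarray", "rnaseq")  # species A, B


@dataclass
class SimConfig:
    """Study conditions for one simulated genome pair.

    The defaults encode the assumed duplication history (two WGD rounds in
    lineage A, one triplication in lineage B) with moderate copy retention,
    10% gene loss, 5% per-site divergence and 20 local rearrangement
    operations per lineage.
    """

    n_ancestral_genes: int = 150
    n_chromosomes: int = 2
    protein_length_range: tuple[int, int] = (60, 120)
    domain_alphabet_size: int = 30
    architecture_length_range: tuple[int, int] = (1, 3)
    events_a: tuple[Event, ...] = (Event("wgd", 0.3), Event("wgd", 0.3))
    events_b: tuple[Event, ...] = (Event("triplication", 0.4),)
    loss_prob: float = 0.1
    rearrangement_ops: int = 20
    fusion_prob: float = 0.0  # gene fused in A, split into two adjacent genes in B
    fission_prob: float = 0.0  # mirror event: fused in B, split in A
    substitution_rate: float = 0.05
    expression: ExpressionSettings = field(default_factory=ExpressionSettings)
    method_disagreement_rate: float = 0.18
    species_a: str = "spA"
    species_b: str = "spB"
    n_factors: int | None = None  # None = every ancestral gene surviving in A
    n_qc_short_decoys: int = 0
    n_qc_stop_decoys: int = 0
    seed: int = 0


@dataclass
class AncestralGene:
    gene_id: str
    chromosome: str
    seq: str
    architecture: tuple[str, ...]
    base_expression: tuple[float, ...]


@dataclass
class SimGene:
    gene_id: str
    species: str
    ancestral_id: str
    chromosome: str
    rank: int
    seq: str
    architecture: tuple[str, ...]


@dataclass
class TruthTable:
    """Planted ground truth for parameter-recovery tests."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)
    fusions: list[tuple[str, str, str]] = field(default_factory=list)
    groups: OrthologyGroups | None = None
    factor_baits: dict[str, str] = field(default_factory=dict)
    copies: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def pair_set(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.pairs}


# ------------------------------------------------------------- ancestor


def simulate_ancestor(config: SimConfig, rng: np.random.Generator | None = None) -> list[AncestralGene]:
    """Draw the ancestral genome: i.i.d. sequences, random architectures,
    gene order 0..n-1 over ``n_chromosomes``, lognormal base expression."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lo, hi = config.protein_length_range
    alo, ahi = config.architecture_length_range
    alphabet = [f"Dom{i:03d}" for i in range(config.domain_alphabet_size)]
    genes: list[AncestralGene] = []
    per_chrom = -(-config.n_ancestral_genes // config.n_chromosomes)
    for i in range(config.n_ancestral_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length))
        k = int(rng.integers(alo, ahi + 1))
        arch = tuple(str(rng.choice(alphabet)) for _ in range(k))
        base = tuple(
            float(v)
            for v in rng.lognormal(mean=3.0, sigma=config.expression.profile_sd, size=len(CANONICAL_TISSUES))
        )
        chrom = f"chr{i // per_chrom + 1}"
        genes.append(
            AncestralGene(
                gene_id=f"anc{i:04d}",
                chromosome=chrom,
                seq=seq,
                architecture=arch,
                base_expression=base,
            )
        )
    return genes


# ------------------------------------------------------------- lineage


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    if mask.any():
        arr[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()))
    return "".join(arr)


@dataclass
class LineageResult:
    genes: list[SimGene]
    # ancestral_id -> gene ids in this lineage
    copies: dict[str, list[str]]
    # applied split events: ancestral_id -> (part1_id, part2_id)
    splits: dict[str, tuple[str, str]]


def evolve_lineage(
    ancestor: Sequence[AncestralGene],
    events: Sequence[Event],
    config: SimConfig,
    rng: np.random.Generator,
    species: str,
    split_candidates: Iterable[str] = (),
) -> LineageResult:
    """Evolve one descendant genome and log its lineage truth.

    Order of operations: polyploidisation events (tandem-appended retained
    copies), gene loss, split-gene events (only applied to ancestral genes
    with exactly one surviving copy and >= 2 domains), id assignment,
    per-copy sequence substitution, then local rearrangement by adjacent
    transpositions that never separate split partners.
    """
    by_id = {g.gene_id: g for g in ancestor}
    chroms: dict[str, list[str]] = {}
    for g in ancestor:
        chroms.setdefault(g.chromosome, []).append(g.gene_id)

    # duplications: each event appends retained copies in tandem
    genome: dict[str, list[str]] = {c: list(gs) for c, gs in chroms.items()}
    for event in events:
        new_genome: dict[str, list[str]] = {}
        for chrom, gene_list in genome.items():
            out: list[str] = []
            for anc_id in gene_list:
                out.append(anc_id)
                for _ in range(event.extra_copies):
                    if rng.random() < event.retention:
                        out.append(anc_id)
            new_genome[chrom] = out
        genome = new_genome

    # loss
    if config.loss_prob > 0:
        genome = {
            chrom: [g for g in gene_list if rng.random() >= config.loss_prob]
            for chrom, gene_list in genome.items()
        }

    # split-gene events
    counts: dict[str, int] = {}
    for gene_list in genome.values():
        for anc_id in gene_list:
            counts[anc_id] = counts.get(anc_id, 0) + 1
    applied_splits: dict[str, int] = {}
    for anc_id in split_candidates:
        anc = by_id[anc_id]
        if counts.get(anc_id) == 1 and len(anc.architecture) >= 2:
            applied_splits[anc_id] = int(
                rng.integers(1, len(anc.architecture))
            )

    # materialise genes with ids; splits expand into two adjacent entries
    genes: list[SimGene] = []
    copies: dict[str, list[str]] = {}
    splits: dict[str, tuple[str, str]] = {}
    counter = 0
    layout: dict[str, list[SimGene]] = {}
    for chrom in sorted(genome):
        placed: list[SimGene] = []
        for anc_id in genome[chrom]:
            anc = by_id[anc_id]
            if anc_id in applied_splits:
                cut = applied_splits[anc_id]
                frac = cut / len(anc.architecture)
                seq_cut = max(1, min(len(anc.seq) - 1, round(len(anc.seq) * frac)))
                parts = (
                    (anc.seq[:seq_cut], anc.architecture[:cut]),
                    (anc.seq[seq_cut:], anc.architecture[cut:]),
                )
                part_ids = []
                for part_seq, part_arch in parts:
                    gid = f"{species}g{counter:05d}"
                    counter += 1
                    placed.append(
                        SimGene(gid, species, anc_id, chrom, -1, part_seq, part_arch)
                    )
                    part_ids.append(gid)
                splits[anc_id] = (part_ids[0], part_ids[1])
                copies.setdefault(anc_id, []).extend(part_ids)
            else:
                gid = f"{species}g{counter:05d}"
                counter += 1
                placed.append(
                    SimGene(gid, species, anc_id, chrom, -1, anc.seq, anc.architecture)
                )
                copies.setdefault(anc_id, []).append(gid)
        layout[chrom] = placed

    # per-copy substitution
    for placed in layout.values():
        for g in placed:
            g.seq = _mutate(g.seq, config.substitution_rate, rng)

    # local rearrangement: adjacent transpositions, partner adjacency kept
    partner_pairs = set(splits.values())

    def adjacency_ok(placed: list[SimGene]) -> bool:
        pos = {g.gene_id: i for i, g in enumerate(placed)}
        for p1, p2 in partner_pairs:
            if p1 in pos and p2 in pos and abs(pos[p1] - pos[p2]) != 1:
                return False
        return True

    chrom_names = sorted(layout)
    sizes = np.array([len(layout[c]) for c in chrom_names], dtype=float)
    if sizes.sum() > 0:
        applied = 0
        attempts = 0
        while applied < config.rearrangement_ops and attempts < 50 * (config.rearrangement_ops + 1):
            attempts += 1
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=sizes / sizes.sum()))]
            placed = layout[chrom]
            if len(placed) < 2:
                continue
            i = int(rng.integers(0, len(placed) - 1))
            placed[i], placed[i + 1] = placed[i + 1], placed[i]
            if adjacency_ok(placed):
                applied += 1
            else:
                placed[i], placed[i + 1] = placed[i + 1], placed[i]

    for chrom in chrom_names:
        for rank, g in enumerate(layout[chrom]):
            g.rank = rank
            genes.append(g)
    return LineageResult(genes=genes, copies=copies, splits=splits)


# ------------------------------------------------------------- emulation


def emulate_method_outputs(
    truth: TruthTable,
    d: float,
    rng: np.random.Generator,
    method_ids: tuple[str, str] = ("pgap", "mcl"),
) -> dict[str, OrthologyGroups]:
    """Emulate two prediction methods with a controlled disagreement rate.

    Method 1 returns the planted groups verbatim.  Method 2 perturbs each
    *factor-linked* group independently with probability ``d``: a random
    non-bait member is dropped (groups of 3+) or replaced by a decoy gene
    (groups of 2), so a perturbed group always changes the factor's
    orthologue set in some species.
    """
    if truth.groups is None:
        raise ValueError("truth has no planted groups")
    if not 0 <= d <= 1:
        raise ValueError("d must lie in [0, 1]")
    baits = set(truth.factor_baits.values())
    perturbed: list[frozenset[Member]] = []
    decoy_counter = 0
    for group in truth.groups.groups:
        members = sorted(group)
        group_baits = [m for m in members if m[1] in baits]
        if not group_baits or rng.random() >= d:
            perturbed.append(group)
            continue
        non_bait = [m for m in members if m[1] not in baits] or members
        victim = non_bait[int(rng.integers(0, len(non_bait)))]
        rest = [m for m in members if m != victim]
        if len(members) >= 3:
            perturbed.append(frozenset(rest))
        else:
            decoy = (victim[0], f"decoy{decoy_counter:05d}")
            decoy_counter += 1
            perturbed.append(frozenset(rest + [decoy]))
    return {
        method_ids[0]: OrthologyGroups(method_ids[0], truth.groups.groups),
        method_ids[1]: OrthologyGroups(method_ids[1], perturbed),
    }


# ------------------------------------------------------------- dataset


@dataclass
class SimulatedDataset:
    """A self-consistent input bundle plus its planted truth."""

    config: SimConfig
    ancestor: list[AncestralGene]
    genes: dict[str, list[SimGene]]  # species -> genes in genome order
    annotation: GenomeAnnotation
    sequences: dict[Member, str]
    domain_hits: list[DomainHit]
    expression: dict[str, dict[str, ExpressionProfile]]
    inventory: FactorInventory
    groups_by_method: dict[str, OrthologyGroups]
    truth: TruthTable
    qc_decoys: list[tuple[str, str]]  # (gene_id, planted reason)

    def protein_records(self, species: str, with_decoys: bool = False) -> list[tuple[str, str]]:
        recs = [
            (g.gene_id, g.seq) for g in self.genes[species]
        ]
        if with_decoys and species == self.config.species_a:
            recs += [(gid, seq) for (gid, _), seq in zip(self.qc_decoys, self._decoy_seqs)]
        return recs

    _decoy_seqs: list[str] = field(default_factory=list)

    def architectures(self) -> dict[str, Architecture]:
        out = {}
        for species_genes in self.genes.values():
            for g in species_genes:
                out[g.gene_id] = Architecture(g.gene_id, g.architecture)
        return out

    def protein_lengths(self) -> dict[str, int]:
        return {
            g.gene_id: len(g.seq)
            for species_genes in self.genes.values()
            for g in species_genes
        }

    def pipeline_inputs(
        self, groups_by_method: Mapping[str, OrthologyGroups] | None = None
    ) -> PipelineInputs:
        return PipelineInputs(
            inventory=self.inventory,
            groups_by_method=dict(groups_by_method or self.groups_by_method),
            species_a=self.config.species_a,
            species_b=self.config.species_b,
            annotation=self.annotation,
            architectures=self.architectures(),
            expression=self.expression,
            protein_lengths=self.protein_lengths(),
            seed=self.config.seed,
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.genes):
            otio.write_fasta(
                outdir / f"proteins_{sp}.fasta", self.protein_records(sp, with_decoys=True)
            )
            cds = [
                (g.gene_id, _cds_for(g.seq, self.config.seed, g.gene_id))
                for g in self.genes[sp]
            ]
            otio.write_fasta(outdir / f"cds_{sp}.fasta", cds)
            otio.write_expression(outdir / f"expression_{sp}.tsv", self.expression[sp])
        otio.write_gene_map(outdir / "gene_map.tsv", self.annotation)
        otio.write_domain_table(outdir / "domains.tsv", self.domain_hits)
        otio.write_inventory(outdir / "inventory.tsv", self.inventory)
        for method, groups in sorted(self.groups_by_method.items()):
            otio.write_groups(outdir / f"groups_{method}.txt", groups)
        assert self.truth.groups is not None
        otio.write_groups(outdir / "truth_groups.txt", self.truth.groups)
        with open(outdir / "truth_pairs.tsv", "w") as fh:
            fh.write("gene_a\tgene_b\trelation\n")
            for a, b, rel in sorted(self.truth.pairs):
                fh.write(f"{a}\t{b}\t{rel}\n")
        with open(outdir / "truth_fusions.tsv", "w") as fh:
            fh.write("fused_gene\tpartner1\tpartner2\n")
            for row in sorted(self.truth.fusions):
                fh.write("\t".join(row) + "\n")
        with open(outdir / "config.json", "w") as fh:
            json.dump(_config_dict(self.config), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_dict(config: SimConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=list))


def _cds_for(protein: str, seed: int, gene_id: str) -> str:
    """A deterministic stand-in CDS of length 3*(L+1) for QC length checks."""
    sub = np.random.default_rng(
        np.random.SeedSequence(
            [seed % (2**31), zlib.crc32(gene_id.encode()) % (2**31)]
        )
    )
    return "".join(sub.choice(NUCLEOTIDES, size=3 * (len(protein) + 1)))


def _domain_hits_for(gene: SimGene) -> list[DomainHit]:
    k = len(gene.architecture)
    L = len(gene.seq)
    if k == 0 or L < k:
        return []
    seg = L // k
    hits = []
    for i, name in enumerate(gene.architecture):
        start = i * seg + 1
        end = (i + 1) * seg if i < k - 1 else L
        hits.append(DomainHit(gene.gene_id, name, start, end, score=50.0))
    return hits


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full input bundle and its truth table."""
    ss = np.random.SeedSequence(config.seed)
    anc_ss, split_ss, a_ss, b_ss, expr_ss, emu_ss, decoy_ss = ss.spawn(7)
    ancestor = simulate_ancestor(config, np.random.default_rng(anc_ss))

    split_rng = np.random.default_rng(split_ss)
    split_in_b = [
        g.gene_id
        for g in ancestor
        if len(g.architecture) >= 2 and split_rng.random() < config.fusion_prob
    ]
    split_in_a = [
        g.gene_id
        for g in ancestor
        if g.gene_id not in split_in_b
        and len(g.architecture) >= 2
        and split_rng.random() < config.fission_prob
    ]

    lineage_a = evolve_lineage(
        ancestor, config.events_a, config, np.random.default_rng(a_ss),
        config.species_a, split_candidates=split_in_a,
    )
    lineage_b = evolve_lineage(
        ancestor, config.events_b, config, np.random.default_rng(b_ss),
        config.species_b, split_candidates=split_in_b,
    )

    truth = TruthTable()
    for anc in ancestor:
        a_copies = lineage_a.copies.get(anc.gene_id, [])
        b_copies = lineage_b.copies.get(anc.gene_id, [])
        truth.copies[anc.gene_id] = {
            config.species_a: list(a_copies),
            config.species_b: list(b_copies),
        }
        relation = "one2one" if len(a_copies) == 1 and len(b_copies) == 1 else "co_orthologue"
        for a in a_copies:
            for b in b_copies:
                truth.pairs.append((a, b, relation))
    for anc_id, (p1, p2) in sorted(lineage_b.splits.items()):
        for fused in lineage_a.copies.get(anc_id, []):
            truth.fusions.append((fused, p1, p2))
    for anc_id, (p1, p2) in sorted(lineage_a.splits.items()):
        for fused in lineage_b.copies.get(anc_id, []):
            truth.fusions.append((fused, p1, p2))

    planted_groups = []
    for anc in ancestor:
        members = [
            (config.species_a, gid) for gid in lineage_a.copies.get(anc.gene_id, [])
        ] + [
            (config.species_b, gid) for gid in lineage_b.copies.get(anc.gene_id, [])
        ]
        if len(members) >= 2:
            planted_groups.append(members)
    truth.groups = OrthologyGroups("planted", planted_groups)

    # factors: ancestral genes surviving in A whose planted group exists
    factor_entries = []
    eligible = [
        anc for anc in ancestor
        if lineage_a.copies.get(anc.gene_id)
    ]
    if config.n_factors is not None:
        eligible = eligible[: config.n_factors]
    for anc in eligible:
        bait = sorted(lineage_a.copies[anc.gene_id])[0]
        name = f"FAC_{anc.gene_id}"
        factor_entries.append(
            FactorEntry(
                factor_name=name,
                compartment="sim",
                baits=[(config.species_a, bait)],
            )
        )
        truth.factor_baits[name] = bait
    inventory = FactorInventory(factor_entries)

    groups_by_method = emulate_method_outputs(
        truth, config.method_disagreement_rate, np.random.default_rng(emu_ss)
    )

    genes = {config.species_a: lineage_a.genes, config.species_b: lineage_b.genes}
    orders: dict[str, dict[str, list[str]]] = {}
    sequences: dict[Member, str] = {}
    domain_hits: list[DomainHit] = []
    for sp, sp_genes in genes.items():
        orders[sp] = {}
        for g in sorted(sp_genes, key=lambda g: (g.chromosome, g.rank)):
            orders[sp].setdefault(g.chromosome, []).append(g.gene_id)
            sequences[(sp, g.gene_id)] = g.seq
            domain_hits.extend(_domain_hits_for(g))
    annotation = GenomeAnnotation(orders)

    expr_rng = np.random.default_rng(expr_ss)
    anc_by_id = {a.gene_id: a for a in ancestor}
    platforms = dict(
        zip((config.species_a, config.species_b), config.expression.platforms)
    )
    expression: dict[str, dict[str, ExpressionProfile]] = {}
    for sp, sp_genes in genes.items():
        profiles = {}
        for g in sorted(sp_genes, key=lambda g: g.gene_id):
            base = np.array(anc_by_id[g.ancestral_id].base_expression)
            noise = expr_rng.lognormal(
                mean=0.0, sigma=config.expression.noise_sd, size=len(base)
            )
            profiles[g.gene_id] = ExpressionProfile(
                gene_id=g.gene_id,
                platform=platforms[sp],
                values=tuple(float(v) for v in base * noise),
            )
        expression[sp] = profiles

    decoy_rng = np.random.default_rng(decoy_ss)
    qc_decoys: list[tuple[str, str]] = []
    decoy_seqs: list[str] = []
    for i in range(config.n_qc_short_decoys):
        qc_decoys.append((f"decoyshort{i:03d}", "short_protein"))
        decoy_seqs.append("".join(decoy_rng.choice(AMINO_ACIDS, size=int(decoy_rng.integers(1, 10)))))
    for i in range(config.n_qc_stop_decoys):
        qc_decoys.append((f"decoystop{i:03d}", "high_stop_fraction"))
        n = int(decoy_rng.integers(20, 40))
        seq = decoy_rng.choice(AMINO_ACIDS, size=n)
        n_stops = int(np.ceil(0.2 * n)) + 1
        stop_pos = decoy_rng.choice(n, size=n_stops, replace=False)
        seq[stop_pos] = "*"
        decoy_seqs.append("".join(seq))

    dataset = SimulatedDataset(
        config=config,
        ancestor=ancestor,
        genes=genes,
        annotation=annotation,
        sequences=sequences,
        domain_hits=domain_hits,
        expression=expression,
        inventory=inventory,
        groups_by_method=groups_by_method,
        truth=truth,
        qc_decoys=qc_decoys,
    )
    dataset._decoy_seqs = decoy_seqs
    return dataset
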