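"""Ordered domain-architecture comparison and split-gene (fusion) detection.

A protein's architecture is its N-to-C ordered list of domain-family names;
repeats are kept distinct (three consecutive WD40 hits are ``WD40, WD40,
WD40``).  Architectures compare equal when their *class-mapped* name
sequences are identical as ordered lists — domain lengths are ignored, and a
clan-like equivalence map can merge related family names (the bundled map
joins the two zinc-finger RING families RING_2 and C3HC4_2, which profile
scans report interchangeably for the same structural domain).

A fused gene in one genome is detected by concatenation: if the architecture
of gene X in species 1 equals the concatenated architectures of two nearby
genes on one chromosome of species 2 (in either order), those genes are
reported as the split-gene pair.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .records import DomainHit, GenomeAnnotation, OrthologyGroups, warn

OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class Architecture:
    """N→C ordered domain-family names of one protein."""

    gene_id: str
    domains: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.domains)

    def mapped(self, eqmap: "EquivalenceMap") -> tuple[str, ...]:
        return tuple(eqmap[d] for d in self.domains)


class EquivalenceMap:
    """domain_name → class label; unmapped names map to themselves."""

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map = dict(mapping or {})

    def __getitem__(self, name: str) -> str:
        return self._map.get(name, name)

    @classmethod
    def identity(cls) -> "EquivalenceMap":
        return cls({})

    @classmethod
    def default(cls) -> "EquivalenceMap":
        return cls.from_tsv(Path(__file__).parent / "data" / "domain_classes.tsv")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EquivalenceMap":
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                name, label = row[0], row[1]
                mapping[name] = label
        return cls(mapping)


def build_architecture(hits: Sequence[DomainHit]) -> Architecture:
    """Resolve overlapping hits and order the survivors N→C.

    Between two hits overlapping by more than half of the shorter hit, only
    the higher-scoring one survives; on a score tie the hit with the lower
    start survives.  The rule is applied pairwise over all input hits.
    """
    if not hits:
        raise ValueError("no hits supplied")
    gene_ids = {h.gene_id for h in hits}
    if len(gene_ids) != 1:
        raise ValueError(f"hits span multiple genes: {sorted(gene_ids)}")
    survivors = []
    for h in hits:
        beaten = False
        for other in hits:
            if other is h:
                continue
            if h.overlap(other) > OVERLAP_FRACTION * min(h.length, other.length):
                if other.score > h.score or (
                    other.score == h.score
                    and (other.start, other.end) < (h.start, h.end)
                ):
                    beaten = True
                    break
        if not beaten:
            survivors.append(h)
    survivors.sort(key=lambda h: (h.start, h.end, h.domain_name))
    return Architecture(
        gene_id=gene_ids.pop(), domains=tuple(h.domain_name for h in survivors)
    )


def build_architectures(hits: Iterable[DomainHit]) -> dict[str, Architecture]:
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    return {g: build_architecture(hs) for g, hs in sorted(by_gene.items())}


def architectures_equal(
    arch_a: Architecture,
    arch_b: Architecture,
    eqmap: EquivalenceMap | None = None,
) -> bool:
    """True iff the class-mapped domain sequences are identical ordered lists."""
    eqmap = eqmap or EquivalenceMap.identity()
    return arch_a.mapped(eqmap) == arch_b.mapped(eqmap)


def agreement_statistic(
    groups: OrthologyGroups,
    architectures: Mapping[str, Architecture],
    species_a: str,
    species_b: str,
    eqmap: EquivalenceMap | None = None,
) -> float:
    """Fraction of grouped proteins with an architecture-identical
    cross-species group-mate.

    The denominator is every protein of the two species appearing in any
    group; the numerator counts those with at least one group-mate in the
    *other* species whose architecture compares equal.  Proteins without a
    domain table entry never count as matching.
    """
    eqmap = eqmap or EquivalenceMap.default()
    denominator = 0
    numerator = 0
    for sp, other_sp in ((species_a, species_b), (species_b, species_a)):
        for gene in sorted(
            gid for s, gid in groups.members() if s == sp
        ):
            denominator += 1
            arch = architectures.get(gene)
            if arch is None:
                continue
            for mate in groups.mates(sp, gene, target_species=other_sp):
                mate_arch = architectures.get(mate)
                if mate_arch is not None and architectures_equal(
                    arch, mate_arch, eqmap
                ):
                    numerator += 1
                    break
    if denominator == 0:
        raise ValueError("no proteins of the two species appear in groups")
    return numerator / denominator


def detect_fusion(
    gene_x: str,
    target_species: str,
    annotation: GenomeAnnotation,
    architectures: Mapping[str, Architecture],
    eqmap: EquivalenceMap | None = None,
    max_gap: int = 1,
) -> list[tuple[str, str]]:
    """Find split-gene partners of *gene_x* in *target_species*.

    Returns rank-ordered pairs ``(g1, g2)`` of genes on one chromosome of
    the target species with ``rank(g2) - rank(g1) <= max_gap`` whose
    concatenated architectures (in either order) equal the architecture of
    *gene_x* under the equivalence map.
    """
    eqmap = eqmap or EquivalenceMap.default()
    arch_x = architectures.get(gene_x)
    if arch_x is None:
        warn(f"{gene_x} has no architecture; fusion scan skipped")
        return []
    target = arch_x.mapped(eqmap)
    hits: list[tuple[str, str]] = []
    for chrom in annotation.chromosomes(target_species):
        genes = annotation.chromosome_genes(target_species, chrom)
        for i, g1 in enumerate(genes):
            for j in range(i + 1, min(i + max_gap + 1, len(genes))):
                g2 = genes[j]
                a1 = architectures.get(g1)
                a2 = architectures.get(g2)
                if a1 is None or a2 is None:
                    continue
                m1, m2 = a1.mapped(eqmap), a2.mapped(eqmap)
                if m1 + m2 == target or m2 + m1 == target:
                    hits.append((g1, g2))
    return hits
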