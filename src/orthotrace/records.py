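"""Core in-memory containers shared by every pipeline stage.

Gene order is represented as a per-chromosome 0-based rank (a gene-count
coordinate, not base pairs): the synteny window is defined in *genes*, so
rank is the native unit.  Orthogroups are partitions of ``(species, gene_id)``
pairs; a gene belongs to at most one group per prediction method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

#: canonical tissue labels: leaves, flower & pollen, shoots & stems, roots
CANONICAL_TISSUES = ("LE", "F&P", "S&S", "RO")

STRANDS = ("+", "-", "unknown")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: identity, protein sequence and genomic position."""

    gene_id: str
    species: str
    protein_seq: str = ""
    chromosome: str = ""
    rank: int = -1
    strand: str = "unknown"
    cds_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def protein_length(self) -> int:
        return len(self.protein_seq)


@dataclass(frozen=True)
class DomainHit:
    """A single domain-family hit on a protein (1-based inclusive aa coords)."""

    gene_id: str
    domain_name: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start},{self.end}] for {self.gene_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


class GenomeAnnotation:
    """Gene order per (species, chromosome): rank-indexed gene id lists.

    Ranks are compacted to a gap-free ``0..n-1`` sequence per chromosome while
    preserving the original order, so neighbourhood queries are pure list
    arithmetic.
    """

    def __init__(self, orders: Mapping[str, Mapping[str, Sequence[str]]]):
        self._orders: dict[str, dict[str, list[str]]] = {
            sp: {chrom: list(genes) for chrom, genes in chroms.items()}
            for sp, chroms in orders.items()
        }
        self._index: dict[str, tuple[str, str, int]] = {}
        for sp, chroms in self._orders.items():
            for chrom, genes in chroms.items():
                for rank, gid in enumerate(genes):
                    if gid in self._index:
                        raise ValueError(f"duplicate gene id {gid} in annotation")
                    self._index[gid] = (sp, chrom, rank)

    @property
    def species(self) -> list[str]:
        return sorted(self._orders)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self._index)

    def genes(self, species: str | None = None) -> Iterator[str]:
        for sp, chroms in sorted(self._orders.items()):
            if species is not None and sp != species:
                continue
            for chrom in sorted(chroms):
                yield from chroms[chrom]

    def chromosomes(self, species: str) -> list[str]:
        return sorted(self._orders[species])

    def chromosome_genes(self, species: str, chromosome: str) -> list[str]:
        return list(self._orders[species][chromosome])

    def locate(self, gene_id: str) -> tuple[str, str, int]:
        """Return ``(species, chromosome, rank)`` of a gene."""
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id} not in annotation") from None

    def neighbourhood(self, gene_id: str, w: int) -> list[str]:
        """Up to *w* genes either side of *gene_id* on its chromosome,
        focal gene excluded, truncated at chromosome ends."""
        if w < 1:
            raise ValueError("window half-width must be >= 1")
        sp, chrom, rank = self.locate(gene_id)
        genes = self._orders[sp][chrom]
        lo = max(0, rank - w)
        return genes[lo:rank] + genes[rank + 1 : rank + 1 + w]

    def as_rows(self) -> Iterator[tuple[str, str, str, int, str]]:
        for sp in sorted(self._orders):
            for chrom in sorted(self._orders[sp]):
                for rank, gid in enumerate(self._orders[sp][chrom]):
                    yield gid, sp, chrom, rank, "unknown"


Member = tuple[str, str]  # (species, gene_id)


class OrthologyGroups:
    """One prediction method's partition of genes into orthogroups.

    Every group has at least two members and a gene appears in at most one
    group; singleton inputs are dropped by the constructor.
    """

    def __init__(self, method_id: str, groups: Iterable[Iterable[Member]]):
        self.method_id = method_id
        cleaned: list[frozenset[Member]] = []
        for g in groups:
            fs = frozenset((str(sp), str(gid)) for sp, gid in g)
            if len(fs) >= 2:
                cleaned.append(fs)
        # deterministic order: by sorted member list
        cleaned.sort(key=lambda fs: sorted(fs))
        self.groups: list[frozenset[Member]] = cleaned
        self._by_member: dict[Member, int] = {}
        for i, fs in enumerate(cleaned):
            for m in fs:
                if m in self._by_member:
                    raise ValueError(
                        f"gene {m[1]} ({m[0]}) in more than one group of {method_id}"
                    )
                self._by_member[m] = i

    def __len__(self) -> int:
        return len(self.groups)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologyGroups):
            return NotImplemented
        return set(self.groups) == set(other.groups)

    def __hash__(self):  # pragma: no cover - not used as dict key
        return hash(frozenset(self.groups))

    def group_of(self, species: str, gene_id: str) -> frozenset[Member] | None:
        i = self._by_member.get((species, gene_id))
        return None if i is None else self.groups[i]

    def mates(
        self, species: str, gene_id: str, target_species: str | None = None
    ) -> set[str]:
        """Group-mates of a gene, optionally restricted to one species.

        The focal gene itself is never returned.
        """
        g = self.group_of(species, gene_id)
        if g is None:
            return set()
        return {
            gid
            for sp, gid in g
            if (sp, gid) != (species, gene_id)
            and (target_species is None or sp == target_species)
        }

    def members(self) -> set[Member]:
        return set(self._by_member)


@dataclass(frozen=True)
class ExpressionProfile:
    """Per-gene expression across the canonical tissues, with platform tag."""

    gene_id: str
    platform: str  # {microarray, rnaseq}
    values: tuple[float, ...]
    tissues: tuple[str, ...] = CANONICAL_TISSUES

    def __post_init__(self) -> None:
        if len(self.values) != len(self.tissues):
            raise ValueError("values/tissues length mismatch")
        if any(v < 0 for v in self.values):
            raise ValueError(f"negative expression for {self.gene_id}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.tissues, self.values))


@dataclass
class FactorEntry:
    """One curated translocation factor: name, compartment and bait genes."""

    factor_name: str
    compartment: str
    baits: list[Member] = field(default_factory=list)
    literature_only: bool = False

    def __post_init__(self) -> None:
        if not self.baits:
            raise ValueError(f"factor {self.factor_name} has no baits")


class FactorInventory:
    """The curated factor list (unique factor names, >=1 bait each)."""

    def __init__(self, entries: Iterable[FactorEntry]):
        self.entries = list(entries)
        names = [e.factor_name for e in self.entries]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate factor names: {', '.join(dup)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FactorEntry]:
        return iter(self.entries)

    def compartments(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.compartment] = out.get(e.compartment, 0) + 1
        return dict(sorted(out.items()))


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=3)
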