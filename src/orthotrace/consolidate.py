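"""Map factor baits into each method's orthogroups and combine the methods.

For each curated factor, the orthologue set in a target species under one
method is the union, over the factor's baits, of the bait's group-mates in
that species.  Baits never count as their own orthologues in their own
species.  The consensus set is the per-species union across methods, and a
factor *agrees* between methods when all methods yield identical sets for
every target species.  Three headline statistics summarise a consolidated
inventory: the between-method overlap fraction, the fraction of factors with
no orthologue in a species under any method, and the fraction with more than
one consensus (co-)orthologue in a species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import FactorInventory, Member, OrthologyGroups


@dataclass
class FactorRecord:
    """Per-factor orthologue sets, per method and consolidated."""

    factor_name: str
    compartment: str
    baits: list[Member]
    missing_baits: list[Member] = field(default_factory=list)
    per_method_sets: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)
    consensus_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    agreement: bool = True
    literature_only: bool = False

    def consensus(self, species: str) -> frozenset[str]:
        return self.consensus_sets.get(species, frozenset())

    def method_set(self, method: str, species: str) -> frozenset[str]:
        return self.per_method_sets.get(method, {}).get(species, frozenset())


def map_factors_to_groups(
    inventory: FactorInventory,
    groups_by_method: Mapping[str, OrthologyGroups],
    target_species: Sequence[str],
) -> list[FactorRecord]:
    """Resolve every factor's baits against every method's orthogroups.

    A bait absent from a method's gene universe is recorded in
    ``missing_baits`` (once per factor) and the factor is still processed
    with its remaining baits; a factor whose baits sit in no group gets
    empty sets everywhere.
    """
    if not groups_by_method:
        raise ValueError("at least one method's groups are required")
    records: list[FactorRecord] = []
    universes = {
        m: groups.members() for m, groups in groups_by_method.items()
    }
    all_members: set[Member] = set().union(*universes.values())
    for entry in inventory:
        bait_ids_by_species: dict[str, set[str]] = {}
        for sp, gid in entry.baits:
            bait_ids_by_species.setdefault(sp, set()).add(gid)
        rec = FactorRecord(
            factor_name=entry.factor_name,
            compartment=entry.compartment,
            baits=list(entry.baits),
            literature_only=entry.literature_only,
        )
        rec.missing_baits = sorted(
            b for b in entry.baits if b not in all_members
        )
        for method, groups in sorted(groups_by_method.items()):
            per_species: dict[str, frozenset[str]] = {}
            for sp in target_species:
                own_baits = bait_ids_by_species.get(sp, set())
                hits: set[str] = set()
                for bait_sp, bait_id in entry.baits:
                    hits |= groups.mates(bait_sp, bait_id, target_species=sp)
                per_species[sp] = frozenset(hits - own_baits)
            rec.per_method_sets[method] = per_species
        for sp in target_species:
            rec.consensus_sets[sp] = frozenset().union(
                *(rec.per_method_sets[m][sp] for m in rec.per_method_sets)
            )
        rec.agreement = all(
            len({rec.per_method_sets[m][sp] for m in rec.per_method_sets}) == 1
            for sp in target_species
        )
        records.append(rec)
    return records


def overlap_statistic(records: Sequence[FactorRecord]) -> float:
    """Fraction of factors on which all methods yield identical sets."""
    if not records:
        raise ValueError("no factor records")
    n_methods = {len(r.per_method_sets) for r in records}
    if n_methods and max(n_methods) < 2:
        raise ValueError("overlap requires at least two methods")
    return sum(r.agreement for r in records) / len(records)


def missing_statistic(records: Sequence[FactorRecord], species: str) -> float:
    """Fraction of factors with no orthologue in *species* under any method."""
    if not records:
        raise ValueError("no factor records")
    empty = sum(
        all(not r.method_set(m, species) for m in r.per_method_sets)
        for r in records
    )
    return empty / len(records)


def multiplicity_statistic(records: Sequence[FactorRecord], species: str) -> float:
    """Fraction of factors with >1 consensus (co-)orthologue in *species*."""
    if not records:
        raise ValueError("no factor records")
    multi = sum(len(r.consensus(species)) > 1 for r in records)
    return multi / len(records)


def jaccard_overlap_statistic(
    records: Sequence[FactorRecord], species: str
) -> float:
    """Mean per-gene Jaccard similarity between the two methods' sets.

    A softer alternative to the exact set-equality overlap; factors empty
    under both methods count as fully agreeing (Jaccard 1).
    """
    if not records:
        raise ValueError("no factor records")
    total = 0.0
    for r in records:
        methods = sorted(r.per_method_sets)
        if len(methods) < 2:
            raise ValueError("Jaccard overlap requires two methods")
        a, b = (r.method_set(m, species) for m in methods[:2])
        union = a | b
        total += 1.0 if not union else len(a & b) / len(union)
    return total / len(records)


def orthologue_counts(
    records: Sequence[FactorRecord], species: str
) -> dict[str, int]:
    """Consensus orthologue totals for one species.

    ``distinct_genes`` counts each gene once even if several factors share
    it; ``assignments`` counts factor-gene pairs.
    """
    genes: set[str] = set()
    assignments = 0
    for r in records:
        s = r.consensus(species)
        genes |= s
        assignments += len(s)
    return {"distinct_genes": len(genes), "assignments": assignments}
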