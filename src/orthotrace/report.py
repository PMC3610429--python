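"""Evidence integration, factor categorisation and the pipeline driver.

Per factor, candidate cross-species pairings are resolved by a cascade:

1. **consensus** — a single gene on each side is assigned outright;
2. **architecture** — a candidate pair whose domain architectures compare
   equal, uniquely among all candidates touching either gene, is assigned
   (a gene whose architecture instead matches the concatenation of two
   neighbouring genes is reported as a fusion, one row per partner);
3. **synteny** — remaining candidates go through the windowed
   shared-synteny matching; dominant pairs carry the ``'+'`` flag;
4. **expression** — still-open candidates go through expression-profile
   matching; dominant pairs carry ``'#'``;
5. anything left is reported honestly as unresolved with its candidates.

Factors are also binned into the inventory categories used for colour-coded
overview figures (equal counts in both species, more/fewer in species B,
absent from all plants, plant-only, absent from species B).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import consolidate as cons
from .consolidate import FactorRecord
from .domains import Architecture, EquivalenceMap, architectures_equal, detect_fusion
from .evidence import (
    DEFAULT_MARGIN,
    DEFAULT_R_MIN,
    assign_by_expression,
    expression_correlation,
)
from .records import (
    ExpressionProfile,
    FactorInventory,
    GenomeAnnotation,
    OrthologyGroups,
)
from .synteny import DEFAULT_WINDOW, assign_by_synteny, score_candidates

CATEGORIES = (
    "equal",
    "more_in_B",
    "fewer_in_B",
    "absent_in_plants",
    "plant_only",
    "absent_in_B",
)


@dataclass
class AssignmentRow:
    factor_name: str
    gene_a: str | None
    gene_b: str | None
    evidence_flags: frozenset[str] = frozenset()
    unresolved: bool = False
    fusion_id: str | None = None
    candidates: tuple[tuple[str, str], ...] = ()

    def sort_key(self):
        return (self.factor_name, self.gene_a or "~", self.gene_b or "~")


def integrate_evidence(
    record: FactorRecord,
    species_a: str,
    species_b: str,
    architectures: Mapping[str, Architecture] | None = None,
    eqmap: EquivalenceMap | None = None,
    annotation: GenomeAnnotation | None = None,
    synteny_scores: Mapping[tuple[str, str], int] | None = None,
    correlations: Mapping[tuple[str, str], float | None] | None = None,
    max_gap: int = 1,
    r_min: float = DEFAULT_R_MIN,
    margin: float = DEFAULT_MARGIN,
) -> list[AssignmentRow]:
    """Resolve one factor's species-A/species-B pairing by the evidence cascade.

    Side A is the factor's baits in species A plus its consensus
    co-orthologues there; side B is the consensus set in species B.
    ``synteny_scores`` and ``correlations`` are lookups over the full
    candidate product; each cascade stage re-matches only the still-open
    candidates.
    """
    eqmap = eqmap or EquivalenceMap.default()
    architectures = architectures or {}
    bait_ids_a = {gid for sp, gid in record.baits if sp == species_a}
    side_a = sorted(bait_ids_a | set(record.consensus(species_a)))
    side_b = sorted(record.consensus(species_b))
    rows: list[AssignmentRow] = []

    if not side_a or not side_b:
        rows.append(
            AssignmentRow(record.factor_name, None, None, unresolved=True)
        )
        return rows

    # stage 1: unambiguous consensus
    if len(side_a) == 1 and len(side_b) == 1:
        rows.append(
            AssignmentRow(
                record.factor_name,
                side_a[0],
                side_b[0],
                evidence_flags=frozenset({"consensus"}),
            )
        )
        return rows

    open_a = list(side_a)
    open_b = list(side_b)

    # stage 2: architecture-unique matches, then fusion scan
    if architectures:
        equal_pairs = [
            (a, b)
            for a in open_a
            for b in open_b
            if a in architectures
            and b in architectures
            and architectures_equal(architectures[a], architectures[b], eqmap)
        ]
        for a, b in sorted(equal_pairs):
            if a not in open_a or b not in open_b:
                continue
            competing = [
                p for p in equal_pairs if p != (a, b) and (p[0] == a or p[1] == b)
            ]
            if competing:
                continue
            rows.append(
                AssignmentRow(
                    record.factor_name,
                    a,
                    b,
                    evidence_flags=frozenset({"architecture"}),
                )
            )
            open_a.remove(a)
            open_b.remove(b)
        if annotation is not None:
            for a in list(open_a):
                if a not in architectures:
                    continue
                fusions = detect_fusion(
                    a, species_b, annotation, architectures, eqmap, max_gap
                )
                fusions = [
                    (g1, g2)
                    for g1, g2 in fusions
                    if g1 in open_b and g2 in open_b
                ] or fusions
                if not fusions:
                    continue
                g1, g2 = fusions[0]
                fid = f"{record.factor_name}:{a}"
                for partner in (g1, g2):
                    rows.append(
                        AssignmentRow(
                            record.factor_name,
                            a,
                            partner,
                            evidence_flags=frozenset({"architecture"}),
                            fusion_id=fid,
                        )
                    )
                open_a.remove(a)
                for partner in (g1, g2):
                    if partner in open_b:
                        open_b.remove(partner)

    # stage 3: shared synteny
    if synteny_scores is not None and open_a and open_b:
        candidates = [(a, b) for a in open_a for b in open_b]
        lookup = {p: int(synteny_scores.get(p, 0)) for p in candidates}
        for (a, b), flagged in assign_by_synteny(candidates, lookup):
            if flagged:
                rows.append(
                    AssignmentRow(
                        record.factor_name, a, b, evidence_flags=frozenset({"+"})
                    )
                )
                open_a.remove(a)
                open_b.remove(b)

    # stage 4: expression profiles
    if correlations is not None and open_a and open_b:
        candidates = [(a, b) for a in open_a for b in open_b]
        lookup = {p: correlations.get(p) for p in candidates}
        for (a, b), flagged in assign_by_expression(
            candidates, lookup, r_min=r_min, margin=margin
        ):
            if flagged:
                rows.append(
                    AssignmentRow(
                        record.factor_name, a, b, evidence_flags=frozenset({"#"})
                    )
                )
                open_a.remove(a)
                open_b.remove(b)

    # stage 5: honest leftovers
    if open_a or open_b:
        rows.append(
            AssignmentRow(
                record.factor_name,
                None,
                None,
                unresolved=True,
                candidates=tuple((a, b) for a in open_a for b in open_b),
            )
        )
    return sorted(rows, key=AssignmentRow.sort_key)


def categorize(
    count_a: int,
    count_b: int,
    found_in_any_plant: bool,
    found_in_b: bool,
    bait_species: Sequence[str],
    plant_species: Sequence[str] = ("at",),
) -> str:
    """Deterministic inventory category for one factor.

    Precedence: no plant orthologue at all dominates; a factor whose baits
    are all from plant species is plant-only; absence from species B comes
    next; otherwise the species counts decide.
    """
    if not found_in_any_plant:
        return "absent_in_plants"
    if all(sp in plant_species for sp in bait_species):
        return "plant_only"
    if not found_in_b:
        return "absent_in_B"
    if count_a == count_b:
        return "equal"
    return "more_in_B" if count_b > count_a else "fewer_in_B"


def categorize_record(
    record: FactorRecord,
    species_a: str,
    species_b: str,
    plant_species: Sequence[str] | None = None,
) -> str:
    plant = tuple(plant_species or (species_a, species_b))
    bait_ids_a = {gid for sp, gid in record.baits if sp == species_a}
    count_a = len(bait_ids_a | set(record.consensus(species_a)))
    count_b = len(record.consensus(species_b))
    found_any_plant = count_a > 0 or count_b > 0
    return categorize(
        count_a,
        count_b,
        found_any_plant,
        count_b > 0,
        bait_species=[sp for sp, _ in record.baits],
        plant_species=plant,
    )


# ------------------------------------------------------------------ driver


@dataclass
class PipelineInputs:
    """Everything one consolidation run consumes, already parsed."""

    inventory: FactorInventory
    groups_by_method: Mapping[str, OrthologyGroups]
    species_a: str
    species_b: str
    annotation: GenomeAnnotation | None = None
    architectures: Mapping[str, Architecture] | None = None
    expression: Mapping[str, Mapping[str, ExpressionProfile]] | None = None
    protein_lengths: Mapping[str, int] | None = None
    eqmap: EquivalenceMap | None = None
    w: int = DEFAULT_WINDOW
    r_min: float = DEFAULT_R_MIN
    margin: float = DEFAULT_MARGIN
    max_gap: int = 1
    seed: int | None = None


@dataclass
class PipelineResult:
    records: list[FactorRecord]
    rows: list[AssignmentRow]
    categories: dict[str, str]
    statistics: dict[str, object]

    def assigned_pairs(self, flags: set[str] | None = None) -> list[tuple[str, str]]:
        out = []
        for row in self.rows:
            if row.unresolved or row.gene_a is None or row.gene_b is None:
                continue
            if flags is None or row.evidence_flags & flags:
                out.append((row.gene_a, row.gene_b))
        return sorted(set(out))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write(
                "factor_name\tgene_a\tgene_b\tevidence\tfusion_id\tunresolved\tcandidates\n"
            )
            for r in sorted(self.rows, key=AssignmentRow.sort_key):
                flags = ",".join(sorted(r.evidence_flags))
                cands = ";".join(f"{a}/{b}" for a, b in r.candidates)
                fh.write(
                    f"{r.factor_name}\t{r.gene_a or '-'}\t{r.gene_b or '-'}\t"
                    f"{flags or '-'}\t{r.fusion_id or '-'}\t"
                    f"{str(r.unresolved).lower()}\t{cands or '-'}\n"
                )
        with open(outdir / "categories.tsv", "w") as fh:
            fh.write("factor_name\tcategory\n")
            for name in sorted(self.categories):
                fh.write(f"{name}\t{self.categories[name]}\n")
        with open(outdir / "statistics.json", "w") as fh:
            json.dump(self.statistics, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(inputs: PipelineInputs) -> PipelineResult:
    """Consolidate, gather evidence, integrate and summarise one dataset."""
    sp_a, sp_b = inputs.species_a, inputs.species_b
    records = cons.map_factors_to_groups(
        inputs.inventory, inputs.groups_by_method, [sp_a, sp_b]
    )
    eqmap = inputs.eqmap or EquivalenceMap.default()
    rows: list[AssignmentRow] = []
    for record in records:
        bait_ids_a = {gid for sp, gid in record.baits if sp == sp_a}
        side_a = sorted(bait_ids_a | set(record.consensus(sp_a)))
        side_b = sorted(record.consensus(sp_b))
        candidates = [(a, b) for a in side_a for b in side_b]
        syn_scores: dict[tuple[str, str], int] | None = None
        if inputs.annotation is not None and candidates:
            present = [
                (a, b)
                for a, b in candidates
                if a in inputs.annotation and b in inputs.annotation
            ]
            scored = score_candidates(
                present,
                inputs.annotation,
                inputs.groups_by_method,
                w=inputs.w,
            )
            syn_scores = {p: s.total for p, s in scored.items()}
        corrs: dict[tuple[str, str], float | None] | None = None
        if inputs.expression is not None and candidates:
            expr_a = inputs.expression.get(sp_a, {})
            expr_b = inputs.expression.get(sp_b, {})
            corrs = {}
            for a, b in candidates:
                if a in expr_a and b in expr_b:
                    corrs[(a, b)] = expression_correlation(expr_a[a], expr_b[b])
        rows.extend(
            integrate_evidence(
                record,
                sp_a,
                sp_b,
                architectures=inputs.architectures,
                eqmap=eqmap,
                annotation=inputs.annotation,
                synteny_scores=syn_scores,
                correlations=corrs,
                max_gap=inputs.max_gap,
                r_min=inputs.r_min,
                margin=inputs.margin,
            )
        )
    categories = {
        r.factor_name: categorize_record(r, sp_a, sp_b) for r in records
    }
    stats: dict[str, object] = {
        "n_factors": len(records),
        "category_counts": {
            c: sum(v == c for v in categories.values()) for c in CATEGORIES
        },
        "missing_fraction": cons.missing_statistic(records, sp_b),
        "multiplicity_fraction": cons.multiplicity_statistic(records, sp_b),
        "counts_a": cons.orthologue_counts(records, sp_a),
        "counts_b": cons.orthologue_counts(records, sp_b),
        "n_unresolved": sum(r.unresolved for r in rows),
        "seed": inputs.seed,
    }
    if len(inputs.groups_by_method) >= 2:
        stats["overlap_fraction"] = cons.overlap_statistic(records)
    if inputs.protein_lengths:
        from .evidence import length_fit

        pairs = []
        for row in rows:
            if row.unresolved or row.gene_a is None or row.gene_b is None:
                continue
            la = inputs.protein_lengths.get(row.gene_a)
            lb = inputs.protein_lengths.get(row.gene_b)
            if la and lb:
                pairs.append((float(la), float(lb)))
        if pairs:
            fit = length_fit(pairs)
            stats["length_fit"] = {
                "a": fit.a,
                "n": fit.n,
                "residual_rms": fit.residual_rms,
            }
    return PipelineResult(
        records=records, rows=rows, categories=categories, statistics=stats
    )
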