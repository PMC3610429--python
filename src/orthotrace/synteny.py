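"""Windowed shared-synteny scoring and score-based co-orthologue pairing.

For a candidate cross-species gene pair, each prediction method contributes
the number of genes in the window around gene A (up to *w* genes up- and
downstream, default 7, truncated at chromosome ends) that have at least one
group-mate inside the window around gene B.  Counts are symmetrised as the
minimum of the two directions, and the total score sums the methods.  A
candidate pair earns the ``'+'`` synteny flag only when its total is
positive and strictly exceeds every competing candidate sharing either
endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

from .records import GenomeAnnotation, OrthologyGroups

DEFAULT_WINDOW = 7

Pair = tuple[tuple[str, str], tuple[str, str]]  # ((spA, geneA), (spB, geneB))


@dataclass
class SyntenyScore:
    pair: Pair
    per_method: dict[str, int] = field(default_factory=dict)
    directional: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_method.values())


def window(gene_id: str, annotation: GenomeAnnotation, w: int = DEFAULT_WINDOW) -> list[str]:
    """Up to *w* genes either side of the focal gene (excluded), same
    chromosome, truncated at the ends."""
    return annotation.neighbourhood(gene_id, w)


def _directional_count(
    win_a: Sequence[str],
    win_b: Sequence[str],
    sp_a: str,
    sp_b: str,
    groups: OrthologyGroups,
    count_unit: str,
) -> int:
    win_b_set = set(win_b)
    if count_unit == "genes":
        return sum(
            1
            for g in win_a
            if groups.mates(sp_a, g, target_species=sp_b) & win_b_set
        )
    if count_unit == "pairs":
        return sum(
            len(groups.mates(sp_a, g, target_species=sp_b) & win_b_set)
            for g in win_a
        )
    raise ValueError("count_unit must be 'genes' or 'pairs'")


def syntenic_score(
    gene_a: str,
    gene_b: str,
    annotation: GenomeAnnotation,
    groups_by_method: Mapping[str, OrthologyGroups],
    w: int = DEFAULT_WINDOW,
    count_unit: str = "genes",
) -> SyntenyScore:
    """Accumulated shared-synteny score for one candidate pair.

    Per method, the two directional window counts are computed and
    symmetrised as their minimum; the total sums over methods.  With
    ``count_unit='pairs'`` every co-grouped window pair is counted instead
    of each window-A gene at most once.
    """
    sp_a, _, _ = annotation.locate(gene_a)
    sp_b, _, _ = annotation.locate(gene_b)
    win_a = window(gene_a, annotation, w)
    win_b = window(gene_b, annotation, w)
    score = SyntenyScore(pair=((sp_a, gene_a), (sp_b, gene_b)))
    for method, groups in sorted(groups_by_method.items()):
        ab = _directional_count(win_a, win_b, sp_a, sp_b, groups, count_unit)
        ba = _directional_count(win_b, win_a, sp_b, sp_a, groups, count_unit)
        score.directional[method] = (ab, ba)
        score.per_method[method] = min(ab, ba)
    return score


def score_candidates(
    candidate_pairs: Sequence[tuple[str, str]],
    annotation: GenomeAnnotation,
    groups_by_method: Mapping[str, OrthologyGroups],
    w: int = DEFAULT_WINDOW,
    count_unit: str = "genes",
) -> dict[tuple[str, str], SyntenyScore]:
    return {
        (a, b): syntenic_score(a, b, annotation, groups_by_method, w, count_unit)
        for a, b in candidate_pairs
    }


def assign_by_synteny(
    candidate_pairs: Sequence[tuple[str, str]],
    scores: Mapping[tuple[str, str], int],
    optimal: bool = False,
) -> list[tuple[tuple[str, str], bool]]:
    """Greedy maximum-total-score matching over a factor's candidate pairs.

    Candidates are taken in descending score (lexicographic tie-break) and
    accepted when neither endpoint is already matched.  A matched pair is
    flagged ``'+'`` only if its score is positive *and* strictly exceeds the
    score of every other candidate sharing either of its endpoints; ties
    yield a match without a flag.  ``optimal=True`` replaces the greedy
    order with exhaustive search for the maximum-total-score matching
    (candidate sets at factor scale are tiny).
    """
    order = sorted(
        candidate_pairs, key=lambda p: (-scores.get(p, 0), p)
    )
    if optimal:
        matching = _optimal_matching(candidate_pairs, scores)
    else:
        matching = []
        used_a: set[str] = set()
        used_b: set[str] = set()
        for a, b in order:
            if a in used_a or b in used_b:
                continue
            used_a.add(a)
            used_b.add(b)
            matching.append((a, b))
    out = []
    for a, b in matching:
        s = scores.get((a, b), 0)
        competitors = [
            scores.get(p, 0)
            for p in candidate_pairs
            if p != (a, b) and (p[0] == a or p[1] == b)
        ]
        flagged = s > 0 and all(s > c for c in competitors)
        out.append(((a, b), flagged))
    return sorted(out)


def _optimal_matching(
    candidate_pairs: Sequence[tuple[str, str]],
    scores: Mapping[tuple[str, str], int],
) -> list[tuple[str, str]]:
    genes_a = sorted({a for a, _ in candidate_pairs})
    genes_b = sorted({b for _, b in candidate_pairs})
    pair_set = set(candidate_pairs)
    swap = len(genes_b) < len(genes_a)
    left, right = (genes_b, genes_a) if swap else (genes_a, genes_b)
    best: tuple[float, int, list[tuple[str, str]]] = (-1.0, -1, [])
    for perm in permutations(right, len(left)):
        matching = []
        for l, r in zip(left, perm):
            pair = (r, l) if swap else (l, r)
            if pair in pair_set:
                matching.append(pair)
        total = float(sum(scores.get(p, 0) for p in matching))
        # prefer larger matchings on equal score
        if (total, len(matching)) > (best[0], best[1]):
            best = (total, len(matching), sorted(matching))
    return best[2]
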