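"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from first principles (plain loops,
exhaustive enumeration) and never calls the code paths it checks.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_oracle(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Smith-Waterman with affine gaps (Gotoh), explicit O(nm) recurrences.

    A gap of length k costs ``gap_open + (k-1)*gap_extend``.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)
    F = np.full((n + 1, m + 1), -np.inf)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + _BLOSUM62[a[i - 1]][b[j - 1]], E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


def union_find_groups(pairs: list[tuple[str, str]]) -> set[frozenset[str]]:
    """Connected components of a pair list via a hand-rolled union-find."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return {frozenset(c) for c in comps.values() if len(c) >= 2}


def synteny_count_oracle(
    window_a: list[str],
    window_b: list[str],
    sp_a: str,
    sp_b: str,
    group_list: list[set[tuple[str, str]]],
) -> int:
    """Window-A genes with >=1 co-grouped partner in window B, by scanning
    every (window-A gene, window-B gene, group) triple."""
    count = 0
    for ga in window_a:
        hit = False
        for gb in window_b:
            for group in group_list:
                if (sp_a, ga) in group and (sp_b, gb) in group:
                    hit = True
        if hit:
            count += 1
    return count


def rbh_groups_oracle(
    nodes: list[tuple[str, str]], edges: dict[frozenset, float]
) -> set[frozenset]:
    """Literal enumeration of the seed + inparalog definition.

    Seeds: cross-species pairs that are mutually best (ties broken to the
    lexicographically smallest partner).  Inparalogs: same-species genes
    scoring >= the seed score against a seed member.  Overlapping clusters
    merge transitively.
    """

    def w(u, v):
        return edges.get(frozenset((u, v)))

    def best(u, sp):
        cand = [(v, w(u, v)) for v in nodes if v[0] == sp and w(u, v) is not None]
        if not cand:
            return None
        top = max(s for _, s in cand)
        return min(v for v, s in cand if s == top), top

    clusters: list[set] = []
    for u, v in combinations(nodes, 2):
        if u[0] == v[0]:
            continue
        bu = best(u, v[0])
        bv = best(v, u[0])
        if not bu or not bv or bu[0] != v or bv[0] != u:
            continue
        seed_score = bu[1]
        cluster = {u, v}
        for member in (u, v):
            for x in nodes:
                if x[0] == member[0] and x != member:
                    s = w(x, member)
                    if s is not None and s >= seed_score:
                        cluster.add(x)
        clusters.append(cluster)
    merged = True
    while merged:
        merged = False
        for i, j in combinations(range(len(clusters)), 2):
            if clusters[i] & clusters[j]:
                clusters[i] |= clusters[j]
                del clusters[j]
                merged = True
                break
    return {frozenset(c) for c in clusters}


def optimal_matching_score(
    candidates: list[tuple[str, str]], scores: dict[tuple[str, str], int]
) -> int:
    """Maximum total score over all matchings, by exhaustive enumeration."""
    genes_a = sorted({a for a, _ in candidates})
    best = 0
    for r in range(1, len(genes_a) + 1):
        for subset in combinations(genes_a, r):
            bs = {b for a, b in candidates}
            for perm in permutations(sorted(bs), r):
                total = sum(
                    scores.get((a, b), 0)
                    for a, b in zip(subset, perm)
                    if (a, b) in candidates
                )
                best = max(best, total)
    return best


def fusion_pairs_oracle(
    target: tuple[str, ...],
    chrom_genes: list[str],
    archs: dict[str, tuple[str, ...]],
    max_gap: int,
) -> list[tuple[str, str]]:
    """All rank-ordered pairs within the gap whose concatenated architectures
    (either order) equal the target, scanned exhaustively."""
    out = []
    for i, g1 in enumerate(chrom_genes):
        for j, g2 in enumerate(chrom_genes):
            if j <= i or j - i > max_gap:
                continue
            if g1 not in archs or g2 not in archs:
                continue
            if archs[g1] + archs[g2] == target or archs[g2] + archs[g1] == target:
                out.append((g1, g2))
    return out


def overlap_resolution_oracle(hits: list) -> list:
    """Pairwise domain-hit tournament applied literally to every pair."""
    survivors = []
    for h in hits:
        ok = True
        for o in hits:
            if o is h:
                continue
            ov = max(0, min(h.end, o.end) - max(h.start, o.start) + 1)
            if ov > 0.5 * min(h.end - h.start + 1, o.end - o.start + 1):
                if (o.score, -o.start, -o.end) > (h.score, -h.start, -h.end):
                    ok = False
        if ok:
            survivors.append(h)
    return sorted(survivors, key=lambda h: (h.start, h.end, h.domain_name))
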