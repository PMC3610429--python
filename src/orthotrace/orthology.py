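"""Built-in orthogroup inference engines at desk scale.

Two deliberately simple surrogates for the external clustering tools stand
behind the pipeline so it runs end to end without downloads:

* **RBH + inparalogs** — seed orthologues are mutually best-scoring
  cross-species pairs; same-species genes scoring at least the seed score
  against a seed member join as inparalogs; overlapping seed clusters merge.
* **Markov-flow clustering (MCL)** — the similarity graph is turned into a
  column-stochastic matrix and iterated through expansion (self
  multiplication) and inflation (elementwise power + column renormalisation)
  until convergence; groups are the connected components of the thresholded
  limit.

Both are labelled surrogates: the consolidation stage accepts externally
produced group files interchangeably, so real-tool outputs can be
substituted.  Pairwise similarity is a Smith-Waterman local-alignment score
(BLOSUM62, affine gaps) normalised by the shorter sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import Member, OrthologyGroups, warn

# ------------------------------------------------------------- scoring


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring parameters (fixed defaults, versioned with the code)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0  # cost of a length-1 gap
    gap_extend: float = 1.0  # additional cost per extra gapped position


DEFAULT_SCORING = Scoring()


def make_aligner(scoring: Scoring = DEFAULT_SCORING) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _sanitize(seq: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def score_pair(
    seq_a: str,
    seq_b: str,
    scoring: Scoring = DEFAULT_SCORING,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Symmetric local-alignment similarity, normalised by min(lenA, lenB).

    Residues outside the substitution-matrix alphabet are treated as ``X``.
    Empty sequences score 0 (with a warning); a pair with no
    positive-scoring local alignment scores 0.
    """
    if not seq_a or not seq_b:
        warn("score_pair called with an empty sequence; score 0")
        return 0.0
    if aligner is None:
        aligner = make_aligner(scoring)
    alphabet = str(aligner.substitution_matrix.alphabet)
    raw = aligner.score(_sanitize(seq_a, alphabet), _sanitize(seq_b, alphabet))
    return max(0.0, float(raw)) / min(len(seq_a), len(seq_b))


def _shared_kmers(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return True  # too short to prescreen; align anyway
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def build_similarity_graph(
    sequences: Mapping[Member, str],
    scoring: Scoring = DEFAULT_SCORING,
    min_score: float = 1.0,
    kmer_prefilter: int | None = 4,
) -> nx.Graph:
    """All-vs-all similarity graph over ``(species, gene_id) -> protein``.

    Edges below ``min_score`` (normalised units) are dropped.  An exact
    shared-k-mer prescreen skips alignment of pairs without any common
    ``k``-mer (such pairs cannot reach a meaningful normalised score);
    set ``kmer_prefilter=None`` to align every pair.
    """
    aligner = make_aligner(scoring)
    graph: nx.Graph = nx.Graph()
    nodes = sorted(sequences)
    graph.add_nodes_from(nodes)
    for a, b in combinations(nodes, 2):
        sa, sb = sequences[a], sequences[b]
        if kmer_prefilter and not _shared_kmers(sa, sb, kmer_prefilter):
            continue
        s = score_pair(sa, sb, scoring, aligner=aligner)
        if s >= min_score:
            graph.add_edge(a, b, weight=s)
    return graph


# ------------------------------------------------------------- RBH engine


def _best_hit(graph: nx.Graph, node: Member, target_sp: str) -> tuple[Member, float] | None:
    cands = [
        (nbr, float(d["weight"]))
        for nbr, d in graph[node].items()
        if nbr[0] == target_sp
    ]
    if not cands:
        return None
    top = max(s for _, s in cands)
    # ties broken lexicographically on (species, gene_id) for determinism
    return min(n for n, s in cands if s == top), top


def infer_rbh_groups(graph: nx.Graph, method_id: str = "rbh") -> OrthologyGroups:
    """Reciprocal-best-hit seeds + inparalog attachment + overlap merging.

    A same-species gene joins a seed cluster when its similarity to a seed
    member is at least the seed pair's own score (ties included).  Clusters
    sharing a member are merged transitively.
    """
    species = sorted({sp for sp, _ in graph.nodes})
    if len(species) < 2:
        raise ValueError("similarity graph must span at least 2 species")
    uf = nx.utils.UnionFind()
    members: set[Member] = set()
    for sp_a, sp_b in combinations(species, 2):
        for a in sorted(n for n in graph.nodes if n[0] == sp_a):
            hit = _best_hit(graph, a, sp_b)
            if hit is None:
                continue
            b, seed_score = hit
            back = _best_hit(graph, b, sp_a)
            if back is None or back[0] != a:
                continue
            uf.union(a, b)
            members.update((a, b))
            for seed_member in (a, b):
                for nbr, d in graph[seed_member].items():
                    if nbr[0] == seed_member[0] and float(d["weight"]) >= seed_score:
                        uf.union(seed_member, nbr)
                        members.add(nbr)
    clusters: dict[Member, set[Member]] = {}
    for m in sorted(members):
        clusters.setdefault(uf[m], set()).add(m)
    return OrthologyGroups(method_id, clusters.values())


# ------------------------------------------------------------- MCL engine


def infer_mcl_groups(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    threshold: float = 1e-8,
    method_id: str = "mcl",
    on_iteration: Callable[[np.ndarray], None] | None = None,
) -> OrthologyGroups:
    """Markov-flow clustering of the similarity graph.

    Self-loops (weight = max incident edge weight, or 1 for isolated nodes)
    stabilise the flow; after every expansion/inflation step each column is
    verified to sum to 1 within 1e-9.  The final partition is the set of
    connected components of the limit matrix thresholded at ``threshold``,
    singletons dropped.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes: Sequence[Member] = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return OrthologyGroups(method_id, [])
    idx = {node: i for i, node in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    for i in range(n):
        incident = A[i].max()
        A[i, i] = incident if incident > 0 else 1.0
    M = A / A.sum(axis=0)
    converged = False
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0)
        colsum_err = np.abs(inflated.sum(axis=0) - 1.0).max()
        if colsum_err > 1e-9:
            raise AssertionError(
                f"column-stochasticity violated: max |colsum-1| = {colsum_err:g}"
            )
        if on_iteration is not None:
            on_iteration(inflated)
        diff = float(np.abs(inflated - M).max())
        M = inflated
        if diff < tol:
            converged = True
            break
    if not converged:
        warn(f"MCL did not converge within {max_iter} iterations; "
             "returning current partition")
    keep = M > threshold
    comp_graph: nx.Graph = nx.Graph()
    comp_graph.add_nodes_from(nodes)
    rows, cols = np.nonzero(keep)
    for i, j in zip(rows, cols):
        if i != j:
            comp_graph.add_edge(nodes[i], nodes[j])
    return OrthologyGroups(method_id, nx.connected_components(comp_graph))


def infer_groups(
    sequences: Mapping[Member, str],
    method: str,
    scoring: Scoring = DEFAULT_SCORING,
    min_score: float = 1.0,
    **mcl_kwargs,
) -> dict[str, OrthologyGroups]:
    """Convenience wrapper: build the graph once, run one or both engines."""
    if method not in ("rbh", "mcl", "both"):
        raise ValueError("method must be rbh, mcl or both")
    graph = build_similarity_graph(sequences, scoring=scoring, min_score=min_score)
    out: dict[str, OrthologyGroups] = {}
    if method in ("rbh", "both"):
        out["rbh"] = infer_rbh_groups(graph)
    if method in ("mcl", "both"):
        out["mcl"] = infer_mcl_groups(graph, **mcl_kwargs)
    return out
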