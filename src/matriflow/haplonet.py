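"""Weighted median-joining haplotype network and matriline assignment.

The network is built on a weighted Hamming metric in which transversions
count ``tv_weight`` times a transition (default 8:1), with the
median-joining relaxation parameter epsilon (default 35).  A
maximum-parsimony post-processing step keeps only nodes and edges that
occur in at least one minimum-length Steiner tree connecting the observed
haplotypes, and every shortest tree is enumerated (capped) so that
ambiguous satellite connections can be resolved by majority vote over
trees.  Satellites are finally grouped into matrilines named A, B, C...
after the most frequent haplotypes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import Alignment, HaplotypeTable

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def weighted_distance(h1: str, h2: str, tv_weight: int = 8) -> int:
    """Transition/transversion-weighted Hamming distance."""
    if len(h1) != len(h2):
        raise ValueError("sequences differ in length")
    score = 0
    for a, b in zip(h1, h2):
        if a != b:
            score += 1 if is_transition(a, b) else tv_weight
    return score


def hamming(h1: str, h2: str) -> int:
    if len(h1) != len(h2):
        raise ValueError("sequences differ in length")
    return sum(a != b for a, b in zip(h1, h2))


# ------------------------------------------------------------ MJ network


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def _merge_levels(D: np.ndarray) -> np.ndarray:
    """For each node pair, the Kruskal level at which they join.

    Distinct weights are processed whole levels at a time so that tied
    edges are treated symmetrically; L[u, v] is the smallest weight level
    whose completion puts u and v in one component.
    """
    m = D.shape[0]
    L = np.full((m, m), np.inf)
    np.fill_diagonal(L, 0.0)
    uf = _UnionFind(m)
    iu, ju = np.triu_indices(m, 1)
    order = np.unique(D[iu, ju])
    unresolved = {(i, j) for i, j in zip(iu.tolist(), ju.tolist())}
    for d in order:
        for i, j in zip(iu.tolist(), ju.tolist()):
            if D[i, j] == d:
                uf.union(i, j)
        done = [
            (i, j) for (i, j) in unresolved if uf.find(i) == uf.find(j)
        ]
        for i, j in done:
            L[i, j] = L[j, i] = d
            unresolved.discard((i, j))
        if not unresolved:
            break
    return L


def _relaxed_msn_edges(D: np.ndarray, epsilon: float) -> list[tuple[int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    At epsilon 0 this is the minimum spanning network (union of all
    minimum spanning trees); larger epsilon admits connections up to
    epsilon heavier than the level at which two clusters first join.
    """
    L = _merge_levels(D)
    m = D.shape[0]
    return [
        (i, j)
        for i in range(m)
        for j in range(i + 1, m)
        if D[i, j] <= L[i, j] + epsilon
    ]


def _positionwise_median(a: str, b: str, c: str) -> str | None:
    """Majority consensus of three sequences; None if any site is 3-way."""
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            return None
    return "".join(out)


def median_joining(
    tbl: HaplotypeTable,
    epsilon: float = 35,
    tv_weight: int = 8,
    max_iter: int = 10,
) -> nx.Graph:
    """Bandelt-style median-joining network of a haplotype table.

    Observed haplotypes are nodes ``H01``...; inferred median vectors are
    ``M1``...  Median vectors are generated from connected triplets by
    position-wise consensus, admitted when their Steiner (connection)
    cost is within epsilon of the best candidate, and the construction is
    iterated to fixation (capped at ``max_iter`` rounds, logged if hit).
    Median vectors left with degree <= 2 are deleted as obsolete.
    """
    obs_seqs = list(tbl.seqs)
    totals = tbl.totals
    seqs = list(obs_seqs)
    known = set(seqs)

    for it in range(max_iter):
        m = len(seqs)
        if m < 2:
            break
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = weighted_distance(
                    seqs[i], seqs[j], tv_weight
                )
        edges = _relaxed_msn_edges(D, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(m)}
        for i, j in edges:
            adj[i].add(j)
            adj[j].add(i)

        # candidate medians from triplets sharing at least two links
        candidates: dict[str, float] = {}
        for u in range(m):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                for trip in ((u, v, w),):
                    a, b, c = (seqs[t] for t in trip)
                    med = _positionwise_median(a, b, c)
                    if med is None or med in known:
                        continue
                    cost = sum(
                        weighted_distance(med, s, tv_weight) for s in (a, b, c)
                    )
                    if med not in candidates or cost < candidates[med]:
                        candidates[med] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = sorted(
            s for s, cost in candidates.items() if cost <= lam + epsilon
        )
        if not new:
            break
        seqs.extend(new)
        known.update(new)
    else:
        logger.info("median-joining hit iteration cap (%d)", max_iter)

    # prune obsolete median vectors (degree <= 2 after rebuilding)
    while True:
        m = len(seqs)
        D = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                D[i, j] = D[j, i] = weighted_distance(
                    seqs[i], seqs[j], tv_weight
                )
        edges = _relaxed_msn_edges(D, epsilon) if m > 1 else []
        deg = np.zeros(m, dtype=int)
        for i, j in edges:
            deg[i] += 1
            deg[j] += 1
        n_obs = len(obs_seqs)
        drop = [i for i in range(n_obs, m) if deg[i] <= 2]
        if not drop:
            break
        seqs = [s for i, s in enumerate(seqs) if i not in set(drop)]

    net = nx.Graph(epsilon=epsilon, tv_weight=tv_weight)
    names = []
    for i, s in enumerate(seqs):
        if i < len(obs_seqs):
            name = f"H{i + 1:02d}"
            net.add_node(
                name, seq=s, observed=True, count=int(totals[i])
            )
        else:
            name = f"M{i - len(obs_seqs) + 1}"
            net.add_node(name, seq=s, observed=False, count=0)
        names.append(name)
    for i, j in edges:
        net.add_edge(
            names[i],
            names[j],
            weight=float(D[i, j]),
            bp=hamming(seqs[i], seqs[j]),
        )
    # guarantee: the network always contains the epsilon-MSN of the
    # observed haplotypes (a median detour must not be costlier than
    # the direct connection it replaces)
    n_obs = len(obs_seqs)
    if n_obs > 1:
        D_obs = np.zeros((n_obs, n_obs))
        for i in range(n_obs):
            for j in range(i + 1, n_obs):
                D_obs[i, j] = D_obs[j, i] = weighted_distance(
                    obs_seqs[i], obs_seqs[j], tv_weight
                )
        for i, j in _relaxed_msn_edges(D_obs, epsilon):
            u, v = names[i], names[j]
            if net.has_edge(u, v):
                continue
            try:
                w = nx.shortest_path_length(net, u, v, weight="weight")
            except nx.NetworkXNoPath:
                w = np.inf
            if w > D_obs[i, j] + 1e-9:
                net.add_edge(
                    u,
                    v,
                    weight=float(D_obs[i, j]),
                    bp=hamming(obs_seqs[i], obs_seqs[j]),
                )
    return net


# --------------------------------------------------- maximum parsimony


def _component_shortest_trees(
    G: nx.Graph, terminals: list, medians: list, max_trees: int
) -> list[frozenset]:
    """All minimum-weight Steiner trees of one connected component.

    Enumerates median-vector subsets (medians are the only optional
    nodes); for each subset the spanning trees of the induced subgraph
    are walked in increasing weight via networkx's SpanningTreeIterator.
    """
    if len(terminals) == 1 and not medians:
        return [frozenset()]
    best_w = np.inf
    best: list[frozenset] = []
    if len(medians) > 16:
        logger.warning(
            "%d median vectors: Steiner enumeration restricted to the "
            "full node set",
            len(medians),
        )
        subsets = [tuple(medians)]
    else:
        subsets = [
            s
            for r in range(len(medians) + 1)
            for s in itertools.combinations(medians, r)
        ]
    for S in subsets:
        nodes = terminals + list(S)
        H = G.subgraph(nodes)
        if H.number_of_nodes() != len(nodes) or not nx.is_connected(H):
            continue
        try:
            mst_w = sum(
                d["weight"] for _, _, d in nx.minimum_spanning_edges(H)
            )
        except nx.NetworkXException:
            continue
        if mst_w > best_w + 1e-9:
            continue
        for T in nx.SpanningTreeIterator(H, weight="weight"):
            w = sum(d["weight"] for _, _, d in T.edges(data=True))
            if w > best_w + 1e-9 and best:
                break
            if w < best_w - 1e-9:
                best_w = w
                best = []
            if abs(w - best_w) <= 1e-9:
                best.append(
                    frozenset(
                        tuple(sorted(e)) for e in T.edges()
                    )
                )
            if len(best) >= max_trees:
                logger.warning("shortest-tree enumeration capped at %d", max_trees)
                return sorted(best, key=sorted)
    return sorted(best, key=sorted)


def mp_prune(net: nx.Graph, max_trees: int = 10_000) -> nx.Graph:
    """Maximum-parsimony post-processing of a haplotype network.

    Keeps exactly the nodes and edges used by at least one minimum-length
    Steiner tree over the observed haplotypes.  The enumerated shortest
    trees (forests, for disconnected inputs) are stored on the result as
    ``graph['shortest_trees']``; observed haplotypes are never removed.
    """
    comps = [list(c) for c in nx.connected_components(net)]
    per_comp: list[list[frozenset]] = []
    for comp in comps:
        terms = sorted(n for n in comp if net.nodes[n].get("observed", True))
        meds = sorted(n for n in comp if not net.nodes[n].get("observed", True))
        trees = _component_shortest_trees(net, terms, meds, max_trees)
        per_comp.append(trees if trees else [frozenset()])

    forests: list[frozenset] = []
    for combo in itertools.product(*per_comp):
        forests.append(frozenset().union(*combo))
        if len(forests) >= max_trees:
            logger.warning("forest enumeration capped at %d", max_trees)
            break

    used_edges = set().union(*forests) if forests else set()
    pruned = nx.Graph(**net.graph)
    for n, d in net.nodes(data=True):
        if d.get("observed", True) or any(n in e for e in used_edges):
            pruned.add_node(n, **d)
    for u, v in used_edges:
        pruned.add_edge(u, v, **net.edges[u, v])
    pruned.graph["shortest_trees"] = forests
    return pruned


# --------------------------------------------------- matriline grouping


@dataclass
class MatrilineAssignment:
    """Haplotype -> matriline map anchored on the most frequent haplotypes."""

    main_haplotypes: list[str]
    letters: dict[str, str]              # main node -> 'A', 'B', ...
    assignment: dict[str, str | None]    # haplotype node -> letter or None
    votes: dict[str, dict[str, int]] = field(default_factory=dict)

    def matriline_of(self, hap_node: str) -> str | None:
        return self.assignment.get(hap_node)


def _mains_on_path(path: list, mains: set) -> int:
    return sum(1 for n in path[1:-1] if n in mains)


def assign_matrilines(net: nx.Graph, k_main: int = 3) -> MatrilineAssignment:
    """Assign every observed haplotype to a matriline A, B, C...

    The ``k_main`` most frequent observed haplotypes anchor the
    matrilines (letters by decreasing frequency).  Each satellite is
    assigned, within every enumerated shortest tree, to the main
    haplotype it reaches without passing through another main; across
    trees the most frequent connection wins, ties broken by smaller mean
    path weight, then larger main-haplotype frequency, then node name.
    """
    observed = [
        (n, d["count"]) for n, d in net.nodes(data=True) if d.get("observed", True)
    ]
    if len(observed) < k_main:
        raise ValueError(f"need at least {k_main} observed haplotypes")
    observed.sort(key=lambda t: (-t[1], t[0]))
    mains = [n for n, _ in observed[:k_main]]
    main_set = set(mains)
    letters = {m: chr(ord("A") + i) for i, m in enumerate(mains)}
    counts = dict(observed)

    forests = net.graph.get("shortest_trees")
    if forests is None:
        forests = mp_prune(net).graph["shortest_trees"]

    votes: dict[str, dict[str, int]] = {}
    weights: dict[str, dict[str, list[float]]] = {}
    for forest in forests:
        T = nx.Graph()
        T.add_nodes_from(net.nodes(data=True))
        for u, v in forest:
            T.add_edge(u, v, **net.edges[u, v])
        for s, _ in observed:
            if s in main_set:
                continue
            best = None
            for m in mains:
                if not nx.has_path(T, s, m):
                    continue
                path = nx.shortest_path(T, s, m, weight="weight")
                if _mains_on_path(path, main_set):
                    continue  # reaches m only through another main
                w = nx.path_weight(T, path, weight="weight")
                key = (w, -counts[m], m)
                if best is None or key < best[0]:
                    best = (key, m, w)
            if best is not None:
                _, m, w = best
                votes.setdefault(s, {}).setdefault(m, 0)
                votes[s][m] += 1
                weights.setdefault(s, {}).setdefault(m, []).append(w)

    assignment: dict[str, str | None] = {m: letters[m] for m in mains}
    for s, _ in observed:
        if s in main_set:
            continue
        if s not in votes:
            warnings.warn(
                f"haplotype {s} connects to no main haplotype; left unassigned"
            )
            assignment[s] = None
            continue
        ranked = sorted(
            votes[s].items(),
            key=lambda kv: (
                -kv[1],
                float(np.mean(weights[s][kv[0]])),
                -counts[kv[0]],
                kv[0],
            ),
        )
        assignment[s] = letters[ranked[0][0]]
    return MatrilineAssignment(
        main_haplotypes=mains,
        letters=letters,
        assignment=assignment,
        votes=votes,
    )


def label_individuals(
    aln: Alignment, tbl: HaplotypeTable, assign: MatrilineAssignment
) -> list[dict]:
    """Per-individual (id, cohort, haplotype, matriline, deme) records."""
    node_of_seq = {s: f"H{i + 1:02d}" for i, s in enumerate(tbl.seqs)}
    out = []
    for i, c, s in zip(aln.ids, aln.cohorts, aln.seqs):
        node = node_of_seq[s]
        mat = assign.matriline_of(node)
        out.append(
            {
                "id": i,
                "cohort": c,
                "haplotype": node,
                "matriline": mat,
                "deme": f"{c}{mat}" if mat else None,
            }
        )
    return out
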