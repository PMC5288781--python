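"""Oceanographic connectivity networks: percolation pruning and community structure.

The island connectivity matrix is symmetrized into a weighted undirected
graph, weak edges are removed up to the percolation threshold (the largest
cutoff that still leaves the network connected), and communities are found
with Newman's leading-eigenvector method: recursive bisection by the sign of
the dominant eigenvector of the modularity matrix, followed by the
Kernighan-Lin style fine-tuning passes of the original method and a final
multiway refinement.  Clustering strength is the weighted modularity

    Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)

and its significance is assessed by permuting the observed edge weights onto
uniformly chosen node pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix

_EPS = 1e-12


@dataclass
class ConnectivityGraph:
    """Weighted undirected island graph (no self-loops)."""

    labels: list[str]
    W: np.ndarray  # symmetric weight matrix, zero diagonal
    symmetrization: str = "mean"

    def __post_init__(self) -> None:
        if np.any(self.W < 0):
            raise ValueError("edge weights must be non-negative")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, 1)))

    def edges(self) -> list[tuple[str, str, float]]:
        i, j = np.nonzero(np.triu(self.W, 1))
        return [(self.labels[a], self.labels[b], float(self.W[a, b])) for a, b in zip(i, j)]


@dataclass
class Partition:
    membership: dict[str, int]
    modularity: float
    threshold: float | None = None
    details: dict = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.membership.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


@dataclass
class PermutationTestResult:
    observed_Q: float
    n_permutations: int
    p_value: float
    seed: int


def build_graph(matrix: ConnectivityMatrix, symmetrization: str = "mean") -> ConnectivityGraph:
    """Symmetrize a directed probability matrix into an undirected graph."""
    P = np.array(matrix.P, dtype=float)
    off = ~np.eye(len(matrix.labels), dtype=bool)
    if np.any(P[off][~np.isnan(P[off])] < 0):
        raise ValueError("negative connectivity entries")
    P = np.nan_to_num(P, nan=0.0)
    np.fill_diagonal(P, 0.0)
    if symmetrization == "mean":
        W = (P + P.T) / 2.0
    elif symmetrization == "max":
        W = np.maximum(P, P.T)
    elif symmetrization == "min":
        W = np.minimum(P, P.T)
    else:
        raise ValueError(f"unknown symmetrization {symmetrization!r}")
    return ConnectivityGraph(labels=list(matrix.labels), W=W, symmetrization=symmetrization)


def _connected(W: np.ndarray) -> bool:
    n = len(W)
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        v = stack.pop()
        for w in np.nonzero(W[v])[0]:
            if not seen[w]:
                seen[w] = True
                stack.append(w)
    return bool(seen.all())


def _components(W: np.ndarray) -> list[list[int]]:
    n = len(W)
    seen = np.zeros(n, dtype=bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        comp = [s]
        seen[s] = True
        stack = [s]
        while stack:
            v = stack.pop()
            for w in np.nonzero(W[v])[0]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
                    comp.append(w)
        comps.append(sorted(comp))
    return comps


def percolation_threshold(graph: ConnectivityGraph) -> float:
    """Largest weight tau such that keeping edges with weight >= tau stays connected."""
    if len(graph.labels) <= 1:
        return 0.0
    if not _connected(graph.W):
        comps = _components(graph.W)
        names = [[graph.labels[i] for i in c] for c in comps]
        raise ValueError(f"graph is disconnected even with all edges: components {names}")
    weights = np.unique(graph.W[np.triu(np.ones_like(graph.W, dtype=bool), 1) & (graph.W > 0)])
    best = weights[0]
    for tau in weights:
        if _connected(np.where(graph.W >= tau, graph.W, 0.0)):
            best = tau
        else:
            break
    return float(best)


def prune(graph: ConnectivityGraph, tau: float, rule: str = "ge") -> ConnectivityGraph:
    """Drop edges below (``rule='ge'``) or up to (``rule='gt'``) the threshold."""
    if rule == "ge":
        W = np.where(graph.W >= tau, graph.W, 0.0)
    elif rule == "gt":
        W = np.where(graph.W > tau, graph.W, 0.0)
    else:
        raise ValueError(f"unknown prune rule {rule!r}")
    return ConnectivityGraph(labels=graph.labels, W=W, symmetrization=graph.symmetrization)


def modularity(W: np.ndarray, membership: np.ndarray) -> float:
    """Weighted Newman-Girvan modularity of a labelled partition."""
    m2 = W.sum()
    if m2 == 0:
        return 0.0
    k = W.sum(axis=1)
    membership = np.asarray(membership)
    same = membership[:, None] == membership[None, :]
    return float(((W - np.outer(k, k) / m2)[same]).sum() / m2)


def _kl_refine_sign(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan-Lin fine-tuning of a bisection sign vector (Newman's variant).

    Repeated passes: every vertex is moved once (best move first, even if it
    worsens the score); the best state seen during the pass is kept.
    """
    best = s.copy()
    bestval = best @ Bg @ best
    n = len(s)
    while True:
        cur = best.copy()
        curval = bestval
        moved = np.zeros(n, dtype=bool)
        passbest = bestval
        passstate = best.copy()
        for _ in range(n):
            gains = -4 * cur * (Bg @ cur) + 4 * np.diag(Bg)
            gains[moved] = -np.inf
            v = int(np.argmax(gains))
            cur[v] = -cur[v]
            curval += gains[v]
            moved[v] = True
            if curval > passbest + _EPS:
                passbest = curval
                passstate = cur.copy()
        if passbest > bestval + _EPS:
            bestval = passbest
            best = passstate
        else:
            return best


def _multiway_refine(W: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """KL-style passes moving single vertices between (or out of) communities."""
    n = len(W)
    best = np.asarray(membership).copy()
    bestQ = modularity(W, best)
    while True:
        cur = best.copy()
        moved: set[int] = set()
        passbest = bestQ
        passstate = best.copy()
        for _ in range(n):
            cand = []
            targets = sorted(set(cur)) + [max(cur) + 1]
            for v in range(n):
                if v in moved:
                    continue
                for c in targets:
                    if c == cur[v]:
                        continue
                    trial = cur.copy()
                    trial[v] = c
                    cand.append((modularity(W, trial), v, c))
            if not cand:
                break
            q, v, c = max(cand)
            cur[v] = c
            moved.add(v)
            if q > passbest + _EPS:
                passbest = q
                passstate = cur.copy()
        if passbest > bestQ + _EPS:
            bestQ = passbest
            best = passstate
        else:
            return best


def leading_eigenvector(graph: ConnectivityGraph, n_seed_vectors: int = 3) -> Partition:
    """Community detection by recursive spectral bisection of the modularity matrix.

    Each community is split by the sign pattern of the dominant eigenvector of
    its generalized modularity matrix (zero components join the positive
    side); candidate splits are also seeded from the next leading eigenvectors,
    each refined with Kernighan-Lin passes, and a split is accepted only if it
    increases Q.  A final multiway refinement (also restarted from the
    all-singletons partition) polishes the result.  A graph with no edges
    yields singleton communities with Q = 0.
    """
    W = graph.W
    n = len(W)
    m2 = W.sum()
    if n == 0:
        return Partition(membership={}, modularity=0.0)
    if m2 == 0:
        return Partition(
            membership={lab: i for i, lab in enumerate(graph.labels)}, modularity=0.0
        )
    k = W.sum(axis=1)
    B = W - np.outer(k, k) / m2

    def try_split(idx: list[int]) -> np.ndarray | None:
        if len(idx) < 2:
            return None
        sub = B[np.ix_(idx, idx)].copy()
        sub[np.diag_indices(len(idx))] -= B[np.ix_(idx, idx)].sum(axis=1)
        evals, evecs = np.linalg.eigh(sub)
        if evals[-1] <= _EPS:
            return None
        best_s = None
        best_val = -np.inf
        for j in range(1, min(n_seed_vectors, len(idx)) + 1):
            s = np.where(evecs[:, -j] >= 0, 1.0, -1.0)
            s = _kl_refine_sign(sub, s)
            val = s @ sub @ s
            if val > best_val:
                best_val = val
                best_s = s
        if best_val / (4 * m2) <= _EPS or abs(best_s.sum()) == len(best_s):
            return None
        return best_s

    queue = [list(range(n))]
    final = []
    while queue:
        idx = queue.pop()
        s = try_split(idx)
        if s is None:
            final.append(idx)
        else:
            queue.append([idx[i] for i in range(len(idx)) if s[i] > 0])
            queue.append([idx[i] for i in range(len(idx)) if s[i] < 0])
    membership = np.zeros(n, dtype=int)
    for ci, comm in enumerate(final):
        membership[comm] = ci

    candidates = [_multiway_refine(W, membership), _multiway_refine(W, np.arange(n))]
    membership = max(candidates, key=lambda m: modularity(W, m))
    # renumber communities in order of first appearance
    remap: dict[int, int] = {}
    for c in membership:
        remap.setdefault(int(c), len(remap))
    membership = np.array([remap[int(c)] for c in membership])
    return Partition(
        membership={lab: int(c) for lab, c in zip(graph.labels, membership)},
        modularity=modularity(W, membership),
    )


def cluster_islands(
    matrix: ConnectivityMatrix,
    symmetrization: str = "mean",
    prune_graph: bool = True,
    prune_rule: str = "ge",
) -> Partition:
    """Full pipeline: symmetrize, percolation-prune, leading-eigenvector cluster."""
    graph = build_graph(matrix, symmetrization=symmetrization)
    tau = None
    if prune_graph:
        tau = percolation_threshold(graph)
        graph = prune(graph, tau, rule=prune_rule)
    part = leading_eigenvector(graph)
    part.threshold = tau
    part.details = {
        "symmetrization": symmetrization,
        "pruned": prune_graph,
        "prune_rule": prune_rule if prune_graph else None,
        "n_edges": graph.n_edges,
    }
    return part


def cluster_significance(
    graph: ConnectivityGraph,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutation test of clustering strength.

    The null places the observed multiset of edge weights on uniformly chosen
    distinct node pairs (weights preserved, topology randomized); the p-value
    uses the add-one estimator p = (1 + #{Q* >= Q}) / (n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    observed = leading_eigenvector(graph).modularity
    n = len(graph.labels)
    iu = np.triu_indices(n, 1)
    weights = graph.W[iu]
    weights = weights[weights > 0]
    n_pairs = len(iu[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        pick = rng.choice(n_pairs, size=len(weights), replace=False)
        Wp = np.zeros((n, n))
        Wp[iu[0][pick], iu[1][pick]] = weights
        Wp = Wp + Wp.T
        gp = ConnectivityGraph(labels=graph.labels, W=Wp, symmetrization=graph.symmetrization)
        if leading_eigenvector(gp).modularity >= observed - _EPS:
            exceed += 1
    p = (1 + exceed) / (n_permutations + 1)
    return PermutationTestResult(
        observed_Q=observed, n_permutations=n_permutations, p_value=p, seed=seed
    )
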