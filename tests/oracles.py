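"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: tree topologies are
enumerated exhaustively and scored by least squares, collinear chains are
found by subset enumeration, and molecular weight is summed from a
hand-entered residue mass table.
"""

from __future__ import annotations

import itertools

import numpy as np

# ---------------------------------------------------------------------------
# Exhaustive unrooted-topology oracle


def enumerate_topologies(n_leaves: int):
    """All unrooted binary topologies over leaves 0..n-1 as edge lists."""
    assert n_leaves >= 3
    base_internal = n_leaves  # internal node ids start at n_leaves
    start = [(base_internal, 0), (base_internal, 1), (base_internal, 2)]
    results = []

    def grow(edges, next_leaf, next_internal):
        if next_leaf == n_leaves:
            results.append(list(edges))
            return
        for k in range(len(edges)):
            u, v = edges[k]
            w = next_internal
            rest = edges[:k] + edges[k + 1 :]
            grow(
                rest + [(u, w), (w, v), (w, next_leaf)],
                next_leaf + 1,
                next_internal + 1,
            )

    grow(start, 3, base_internal + 1)
    return results


def _adjacency(edges):
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    return adj


def _leaf_paths(edges, n_leaves):
    """Edge-index path between every leaf pair, by DFS."""
    adj = _adjacency(edges)
    paths = {}
    for a in range(n_leaves):
        stack = [(a, None, [])]
        seen = {a}
        while stack:
            node, _, path = stack.pop()
            if node < n_leaves and node != a:
                paths[(a, node)] = path
                continue
            for nxt, eidx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, node, path + [eidx]))
    return paths


def topology_bipartitions(edges, n_leaves):
    """Non-trivial leaf splits of a topology, as frozensets excluding leaf 0."""
    adj = _adjacency(edges)
    splits = set()
    for eidx, (u, v) in enumerate(edges):
        # leaves reachable from v without crossing edge eidx
        stack, seen, leaves = [v], {u, v}, set()
        while stack:
            node = stack.pop()
            if node < n_leaves:
                leaves.add(node)
            for nxt, e2 in adj[node]:
                if e2 != eidx and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        side = frozenset(leaves)
        if 0 in side:
            side = frozenset(range(n_leaves)) - side
        if 1 < len(side) < n_leaves - 1:
            splits.add(side)
    return splits


def ls_best_topology(dist: np.ndarray):
    """Bipartitions of the least-squares-best topology for a distance matrix.

    Every unrooted topology is scored by fitting branch lengths with
    unconstrained least squares to the leaf-pair path design matrix; for
    an additive matrix the generating topology is the unique zero-error
    fit.
    """
    n = dist.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([dist[a, b] for a, b in pairs])
    best_sse, best_edges = None, None
    for edges in enumerate_topologies(n):
        paths = _leaf_paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        for row, (a, b) in enumerate(pairs):
            for eidx in paths[(a, b)]:
                A[row, eidx] = 1.0
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        sse = float(((A @ x - d) ** 2).sum())
        if best_sse is None or sse < best_sse - 1e-12:
            best_sse, best_edges = sse, edges
    return topology_bipartitions(best_edges, n)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random topology with uniform branch lengths and its distances."""
    topologies = enumerate_topologies(n_leaves)
    edges = topologies[rng.integers(len(topologies))]
    lengths = rng.uniform(0.1, 1.0, size=len(edges))
    paths = _leaf_paths(edges, n_leaves)
    dist = np.zeros((n_leaves, n_leaves))
    for (a, b), path in paths.items():
        dist[a, b] = dist[b, a] = sum(lengths[e] for e in path)
    return edges, dist


# ---------------------------------------------------------------------------
# Brute-force monotone chain


def brute_force_chain(points, max_gap: int) -> int:
    """Longest monotone chain over (rank_a, rank_b) by subset enumeration.

    Both orientations (rank_b increasing or decreasing with rank_a) are
    considered; consecutive gaps on both axes must be within ``max_gap``.
    Exponential — keep n <= 12.
    """
    n = len(points)
    best = 0
    for mask in range(1, 1 << n):
        chosen = sorted(points[i] for i in range(n) if mask & (1 << i))
        for direction in (1, -1):
            ok = True
            for (a1, b1), (a2, b2) in zip(chosen, chosen[1:]):
                da, db = a2 - a1, direction * (b2 - b1)
                if not (0 < da <= max_gap and 0 < db <= max_gap):
                    ok = False
                    break
            if ok:
                best = max(best, len(chosen))
    return best


# ---------------------------------------------------------------------------
# Residue mass table (average masses, Da) — hand-entered

RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER = 18.0153


def mw_oracle_kda(sequence: str) -> float:
    return (sum(RESIDUE_MASS[r] for r in sequence) + WATER) / 1000.0
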