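"""Independent brute-force oracle for the detection graph-edit measure.

Enumerates sequences of elementary node operations (delete a false-positive
node, split a node, add a missing node) with Dijkstra over edit states and
returns the true minimum cost of transforming the predicted detection graph
into the reference graph.  Intended for instances with <= 5 cells per mask.
"""

import heapq
from itertools import combinations

import numpy as np

W_SPLIT, W_FN, W_FP = 5.0, 10.0, 1.0


def claims_from_masks(ref: np.ndarray, pred: np.ndarray) -> tuple[set, list]:
    """(reference ids, per-predicted-cell claimed reference sets).

    A predicted cell claims every reference cell of which it covers a
    strict majority — recomputed here directly from pixel counts.
    """
    ref_ids = {int(r) for r in np.unique(ref) if r > 0}
    claims = []
    for s in np.unique(pred):
        if s <= 0:
            continue
        claimed = set()
        for r in ref_ids:
            inter = int(((ref == r) & (pred == s)).sum())
            if 2 * inter > int((ref == r).sum()):
                claimed.add(r)
        claims.append(frozenset(claimed))
    return ref_ids, claims


def min_edit_cost(ref_ids: set, claims: list) -> float:
    """Dijkstra over multisets of claim-sets.

    Goal state: one singleton node per reference cell, no other nodes.
    Operations: delete an unclaiming node (cost 1), split a node's claim
    set into two non-empty parts (cost 5), add a node for a missing
    reference (cost 10).
    """
    goal = tuple(sorted((r,) for r in ref_ids))

    def key(nodes):
        return tuple(sorted(tuple(sorted(n)) for n in nodes))

    start = key([tuple(sorted(c)) for c in claims])
    dist = {start: 0.0}
    heap = [(0.0, start)]
    while heap:
        d, state = heapq.heappop(heap)
        if d > dist.get(state, np.inf):
            continue
        if state == goal:
            return d
        nodes = [tuple(n) for n in state]
        succs = []
        covered = set().union(*[set(n) for n in nodes]) if nodes else set()
        for i, n in enumerate(nodes):
            rest = nodes[:i] + nodes[i + 1 :]
            # deleting is legal for any node (refs it covered must then be
            # re-added); the search decides what is cheapest
            succs.append((W_FP, key(rest)))
            if len(n) >= 2:
                elems = list(n)
                for r in range(1, len(elems) // 2 + 1):
                    for part in combinations(elems, r):
                        a = tuple(sorted(part))
                        b = tuple(sorted(set(elems) - set(part)))
                        succs.append((W_SPLIT, key(rest + [a, b])))
        for r in ref_ids - covered:
            succs.append((W_FN, key(nodes + [(r,)])))
        for cost, nxt in succs:
            nd = d + cost
            if nd < dist.get(nxt, np.inf):
                dist[nxt] = nd
                heapq.heappush(heap, (nd, nxt))
    raise RuntimeError("goal unreachable")


def det_oracle(ref: np.ndarray, pred: np.ndarray) -> float:
    """DET via exhaustive search: 1 - min(cost, cost0)/cost0."""
    ref_ids, claims = claims_from_masks(ref, pred)
    if not ref_ids:
        return 1.0 if not (np.asarray(pred) > 0).any() else 0.0
    cost = min_edit_cost(ref_ids, claims)
    cost0 = W_FN * len(ref_ids)
    return 1.0 - min(cost, cost0) / cost0
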