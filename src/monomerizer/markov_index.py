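"""Selectivity-ordered search indexes for root residues.

Before any search, the frequency of every strict bond label is estimated on a
learning set of polymers of the target class. An index for a residue is then a
connected ordering of its line-graph nodes — a Markov-style chain of growing
sub-patterns — chosen to minimise the expected number of partial embeddings
the isomorphism search will keep alive:

    cost(order) = sum_k  prod_{j<=k} p(label_j)

where ``p`` is the smoothed label frequency. The product over a prefix is the
first-order (independence) estimate of how many partial matches survive after
``k`` nodes have been placed, so the rarest labels should come first. The
order affects speed only: search results are identical under any connected
order, which is the index's safety contract.

The optimal order is found by exact dynamic programming over connected prefix
sets (feasible up to 16 line-graph nodes); larger components fall back to a
greedy rarest-extension heuristic. Disconnected residues are indexed per
component, components concatenated rarest-first.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .molgraph import LineGraph, MolecularGraph, to_line_graph

__all__ = [
    "FrequencyModel",
    "MarkovIndex",
    "learn_frequencies",
    "build_index",
    "order_cost",
    "EXACT_DP_LIMIT",
]

EXACT_DP_LIMIT = 16


@dataclass
class FrequencyModel:
    """Smoothed frequencies of strict bond labels over a polymer corpus.

    Add-``smoothing`` pseudo-counts keep unseen labels searchable with maximal
    selectivity: an unseen label gets the smallest probability the model can
    assign, never zero.
    """

    counts: dict[tuple, int]
    total: int
    smoothing: float = 1.0

    def probability(self, label: tuple) -> float:
        denom = self.total + self.smoothing * (len(self.counts) + 1)
        return (self.counts.get(label, 0) + self.smoothing) / denom

    @classmethod
    def uniform(cls) -> "FrequencyModel":
        """A no-information model: every label equally (im)probable."""
        return cls(counts={}, total=0, smoothing=1.0)


def learn_frequencies(polymers: Sequence[MolecularGraph], smoothing: float = 1.0) -> FrequencyModel:
    """Count strict bond labels over the line graphs of a learning set."""
    if not polymers:
        raise ValueError(
            "empty learning set: supply representative polymers or use FrequencyModel.uniform()"
        )
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    counts: Counter = Counter()
    for g in polymers:
        if g.n_bonds == 0:
            continue
        lg = to_line_graph(g)
        counts.update(n.label_strict for n in lg.nodes)
    return FrequencyModel(counts=dict(counts), total=sum(counts.values()), smoothing=smoothing)


@dataclass
class MarkovIndex:
    """A residue's line graph plus the chosen node order and its cost.

    ``connectivity[k]`` lists the earlier positions adjacent to position ``k``
    (empty exactly when position ``k`` starts a new connected component)."""

    graph: MolecularGraph
    line_graph: Optional[LineGraph]
    order: tuple[int, ...]
    connectivity: tuple[tuple[int, ...], ...]
    expected_cost: float

    @property
    def n_nodes(self) -> int:
        return len(self.order)


def order_cost(labels: Sequence[tuple], order: Sequence[int], freq: FrequencyModel) -> float:
    """Expected surviving partial matches summed over prefixes of ``order``."""
    cost = 0.0
    prod = 1.0
    for node in order:
        prod *= freq.probability(labels[node])
        cost += prod
    return cost


def _connected_components(nodes: Sequence[int], adjacency: dict[int, frozenset[int]]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = []
        stack = [start]
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in adjacency[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _exact_order(comp: list[int], adjacency: dict[int, frozenset[int]],
                 p: dict[int, float]) -> tuple[list[int], float]:
    """Exact DP over connected prefix subsets; lexicographically smallest
    optimal order. Cost of a chain of prefix sets S_1 ⊂ ... ⊂ S_n is
    Σ Π_{j∈S_k} p_j, which depends only on the sets, so subsets are DP states."""
    n = len(comp)
    pos = {v: i for i, v in enumerate(comp)}
    adj_bits = [0] * n
    for v in comp:
        for w in adjacency[v]:
            if w in pos:
                adj_bits[pos[v]] |= 1 << pos[w]
    pvals = [p[v] for v in comp]
    full = (1 << n) - 1

    # product of p over each subset, by lowest-set-bit recurrence
    prod = [1.0] * (1 << n)
    for s in range(1, 1 << n):
        low = (s & -s).bit_length() - 1
        prod[s] = prod[s & (s - 1)] * pvals[low]

    # h[S] = minimal remaining cost to grow S to the full set
    h = [math.inf] * (1 << n)
    h[full] = 0.0
    order_states = sorted(range(1 << n), key=lambda s: bin(s).count("1"), reverse=True)
    reachable = [False] * (1 << n)
    reachable[0] = True
    # forward reachability: connected prefixes only
    for s in range(1, 1 << n):
        low_iter = s
        while low_iter:
            b = (low_iter & -low_iter).bit_length() - 1
            low_iter &= low_iter - 1
            prev = s & ~(1 << b)
            if reachable[prev] and (prev == 0 or (adj_bits[b] & prev)):
                reachable[s] = True
                break
    for s in order_states:
        if s == full or not reachable[s]:
            continue
        best = math.inf
        for b in range(n):
            if s & (1 << b):
                continue
            if s != 0 and not (adj_bits[b] & s):
                continue
            nxt = s | (1 << b)
            c = prod[nxt] + h[nxt]
            if c < best:
                best = c
        h[s] = best

    # reconstruct: at each step the smallest node index among optimal extensions
    order: list[int] = []
    s = 0
    while s != full:
        best_b, best_c = -1, math.inf
        for b in range(n):
            if s & (1 << b):
                continue
            if s != 0 and not (adj_bits[b] & s):
                continue
            nxt = s | (1 << b)
            c = prod[nxt] + h[nxt]
            if c < best_c:
                best_b, best_c = b, c
        order.append(comp[best_b])
        s |= 1 << best_b
    return order, h[0]


def _greedy_order(comp: list[int], adjacency: dict[int, frozenset[int]],
                  p: dict[int, float]) -> tuple[list[int], float]:
    """Rarest-first greedy extension for large components."""
    start = min(comp, key=lambda v: (p[v], v))
    order = [start]
    chosen = {start}
    frontier = set(adjacency[start]) & set(comp)
    while len(order) < len(comp):
        cand = min(frontier, key=lambda v: (p[v], v))
        order.append(cand)
        chosen.add(cand)
        frontier |= set(adjacency[cand]) & set(comp)
        frontier -= chosen
    cost = 0.0
    prod = 1.0
    for v in order:
        prod *= p[v]
        cost += prod
    return order, cost


def build_index(residue: Union[MolecularGraph, "object"], freq: FrequencyModel) -> MarkovIndex:
    """Build the selectivity-ordered index for a residue (or any query graph).

    Accepts a :class:`~monomerizer.residues.Residue` or a bare
    :class:`MolecularGraph`. Single-atom (bond-free) queries get an empty
    order; the search layer matches them directly on polymer atoms.
    """
    graph: MolecularGraph = getattr(residue, "graph", residue)
    if graph.n_bonds == 0:
        return MarkovIndex(graph=graph, line_graph=None, order=(), connectivity=(),
                           expected_cost=0.0)
    lg = to_line_graph(graph)
    p = {n.node_id: freq.probability(n.label_strict) for n in lg.nodes}
    comps = _connected_components([n.node_id for n in lg.nodes], lg.adjacency)
    ordered_comps: list[tuple[list[int], float]] = []
    for comp in comps:
        if len(comp) <= EXACT_DP_LIMIT:
            ordered_comps.append(_exact_order(comp, lg.adjacency, p))
        else:
            ordered_comps.append(_greedy_order(comp, lg.adjacency, p))
    # rarest component first: by the probability of its rarest node
    ordered_comps.sort(key=lambda oc: (min(p[v] for v in oc[0]), oc[0][0]))
    order: list[int] = []
    for comp_order, _ in ordered_comps:
        order.extend(comp_order)
    connectivity: list[tuple[int, ...]] = []
    for k, node in enumerate(order):
        earlier = tuple(j for j in range(k) if order[j] in lg.adjacency[node])
        connectivity.append(earlier)
    total_cost = order_cost([n.label_strict for n in lg.nodes], order, freq)
    return MarkovIndex(graph=graph, line_graph=lg, order=tuple(order),
                       connectivity=tuple(connectivity), expected_cost=total_cost)
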