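"""Refinement of a self-alignment into an ungapped multiple alignment of the
k repeats.

Each connected component of the right size in the self-alignment graph
contributes one column: its k residues, sorted by chain position, occupy the
k rows (repeat 1 is N-terminal).  Columns that would violate the sequence
order of any repeat are discarded so as to maximize the total alignment
length (an exact longest-chain dynamic program over dominance-sorted
columns).  The DeltaPosition refiner first repairs the graph so that all
surviving nodes sit on k-cycles, rewiring near-miss cycles that close at a
small sequence offset.  Refinement output has no gaps; gaps appear only
later, during Monte Carlo optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import RefinementError
from .params import RefineParams


@dataclass
class RepeatAlignment:
    """k x L matrix of trace positions; -1 marks a gap.

    Rows are repeats in chain order; within each row the non-gap positions
    are strictly increasing and rows occupy disjoint, ordered position
    ranges.
    """

    matrix: np.ndarray        # (k, L) int, -1 = gap
    provenance: str = ""

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=int)

    @property
    def n_repeats(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row_positions(self, r: int) -> np.ndarray:
        row = self.matrix[r]
        return row[row >= 0]

    def validate(self) -> None:
        """Raise ValueError on any violated invariant."""
        prev_max = -1
        seen: set[int] = set()
        for r in range(self.n_repeats):
            pos = self.row_positions(r)
            if len(pos) == 0:
                raise ValueError(f"row {r} is empty")
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"row {r} positions are not strictly increasing")
            if pos[0] <= prev_max:
                raise ValueError(f"row {r} overlaps or precedes row {r - 1}")
            if seen.intersection(pos.tolist()):
                raise ValueError("rows are not pairwise disjoint")
            seen.update(pos.tolist())
            prev_max = int(pos[-1])


def repeat_ranges(aln: RepeatAlignment) -> list:
    """[start, end] trace positions of each repeat (min/max non-gap)."""
    out = []
    for r in range(aln.n_repeats):
        pos = aln.row_positions(r)
        if len(pos) == 0:
            raise ValueError(f"repeat {r} has no aligned positions")
        out.append([int(pos[0]), int(pos[-1])])
    return out


def _columns_to_alignment(columns: list, k: int, provenance: str,
                          min_columns: int) -> RepeatAlignment:
    """Assemble sorted size-k components into a consistent alignment."""
    cols = [tuple(sorted(c)) for c in columns]
    cols.sort(key=lambda c: c[0])
    chosen = _max_consistent_columns(cols)
    chosen = _enforce_block_order(chosen)
    if len(chosen) < min_columns:
        raise RefinementError(
            f"only {len(chosen)} consistent columns (need >= {min_columns})"
        )
    matrix = np.array(chosen, dtype=int).T  # rows = repeats
    aln = RepeatAlignment(matrix, provenance=provenance)
    aln.validate()
    return aln


def _max_consistent_columns(cols: list) -> list:
    """Maximum-cardinality subset of columns that is strictly increasing in
    every row, by longest-chain DP over the dominance order.

    Columns are pre-sorted by first-row position; column b can follow a iff
    every row position of a is smaller than the corresponding one of b.
    """
    m = len(cols)
    if m == 0:
        return []
    best = [1] * m
    prev = [-1] * m
    for b in range(m):
        for a in range(b):
            if all(x < y for x, y in zip(cols[a], cols[b])) and best[a] + 1 > best[b]:
                best[b] = best[a] + 1
                prev[b] = a
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(cols[end])
        end = prev[end]
    return chain[::-1]


def _enforce_block_order(cols: list) -> list:
    """Drop columns until every repeat occupies a contiguous, ordered block.

    Chain consistency (each row strictly increasing) does not by itself stop
    row ranges from interleaving — e.g. columns (0,10),(6,9) keep both rows
    increasing while repeat 1 reaches into repeat 2's range.  Columns taking
    part in such interleaving are removed greedily, worst offender first.
    """
    cols = list(cols)
    while len(cols) > 1:
        arr = np.array(cols)            # (m, k)
        row_max = arr.max(axis=0)       # per repeat
        row_min = arr.min(axis=0)
        bad = row_max[:-1] >= row_min[1:]
        if not bad.any():
            break
        # count, per column, how often it realizes an offending extreme
        scores = np.zeros(len(cols), dtype=int)
        for r in np.flatnonzero(bad):
            scores[np.argmax(arr[:, r])] += 1
            scores[np.argmin(arr[:, r + 1])] += 1
        cols.pop(int(np.argmax(scores)))
    return cols


def refine_graph_component(
    graph: nx.DiGraph, k: int, params: RefineParams = RefineParams()
) -> RepeatAlignment:
    """Combine all size-k weakly-connected components into alignment columns."""
    if k < 2:
        raise RefinementError("order must be at least 2")
    comps = [c for c in nx.weakly_connected_components(graph) if len(c) == k]
    return _columns_to_alignment(comps, k, "GraphComponent", params.min_columns)


def refine_delta_position(
    graph: nx.DiGraph, k: int, params: RefineParams = RefineParams()
) -> RepeatAlignment:
    """Repair the graph until remaining nodes sit on k-cycles, then refine.

    Nodes whose k-fold composition is undefined are deleted; where f^k(i)
    lands a small sequence offset away from i (|offset| <= max_offset), the
    final edge of the walk is rewired to close the cycle at i.  Surviving
    k-cycles become columns, filtered for sequence consistency exactly as in
    the GraphComponent refiner.
    """
    if k < 2:
        raise RefinementError("order must be at least 2")
    succ = {u: v for u, v in graph.edges()}
    cycles: list[tuple] = []
    claimed: set[int] = set()
    for start in sorted(succ):
        if start in claimed:
            continue
        walk = [start]
        x = start
        broken = False
        for _ in range(k):
            if x not in succ:
                broken = True
                break
            x = succ[x]
            walk.append(x)
        if broken:
            continue
        end = walk[-1]
        if end == start or abs(end - start) <= params.max_offset:
            nodes = walk[:-1]  # k nodes; rewiring closes the cycle at start
            if len(set(nodes)) == k and not claimed.intersection(nodes):
                cycles.append(tuple(nodes))
                claimed.update(nodes)
    if not cycles:
        raise RefinementError("no k-cycles after repair")
    return _columns_to_alignment(cycles, k, "DeltaPosition", params.min_columns)


def refine(
    graph: nx.DiGraph,
    k: int,
    has_cp: bool,
    method: str = "auto",
    params: RefineParams = RefineParams(),
) -> RepeatAlignment:
    """Dispatch to the refiner matching the order detector family."""
    if method == "auto":
        method = "delta-position" if has_cp else "graph-component"
    if method == "delta-position":
        return refine_delta_position(graph, k, params)
    if method == "graph-component":
        return refine_graph_component(graph, k, params)
    raise ValueError(f"unknown refine method {method!r}")
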