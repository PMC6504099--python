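"""Order-of-symmetry detection: estimate the number of repeats k from the
self-alignment.

Three interchangeable detectors are provided.  GraphComponent treats the
self-alignment as a directed graph over aligned residues (an edge from each
residue to its image) and takes the most frequent connected-component size:
residues aligned across all k repeats form k-node paths (open symmetry) or
k-cycles (closed).  DeltaPosition composes the mapping k times and measures
the mean circular sequence displacement of f^k — zero for the true order of
a closed symmetry — with a small penalty on k so the smallest exact period
wins.  RotationAngle matches the rotation angle of the alignment transform
to 360/n.  The automatic rule uses DeltaPosition for closed (circularly
permuted) alignments and GraphComponent for open ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .params import OrderParams
from .selfalign import SelfAlignment


@dataclass
class OrderResult:
    order: int
    method: str
    confidence: float


def build_alignment_graph(aln: SelfAlignment) -> nx.DiGraph:
    """Directed graph with one node per aligned residue and one edge i -> f(i)
    per mapped pair."""
    g = nx.DiGraph()
    for i, j in aln.mapping.items():
        g.add_edge(i, j)
    return g


def order_graph_component(graph: nx.DiGraph, max_order: int = 8) -> OrderResult:
    """k = most frequent weakly-connected-component size in [2, max_order].

    Ties go to the larger size (more repeats only with equal evidence);
    confidence is the fraction of nodes lying in modal-size components.
    """
    if graph.number_of_nodes() == 0:
        return OrderResult(1, "GraphComponent", 0.0)
    sizes = [len(c) for c in nx.weakly_connected_components(graph)]
    eligible = [s for s in sizes if 2 <= s <= max_order]
    if not eligible:
        return OrderResult(1, "GraphComponent", 0.0)
    counts = Counter(eligible)
    top = max(counts.values())
    k = max(s for s, c in counts.items() if c == top)
    coverage = k * counts[k] / graph.number_of_nodes()
    return OrderResult(k, "GraphComponent", coverage)


def _compose(mapping: dict, k: int) -> dict:
    """f^k restricted to the positions where the composition is defined."""
    out = {}
    for start in mapping:
        x = start
        ok = True
        for _ in range(k):
            if x not in mapping:
                ok = False
                break
            x = mapping[x]
        if ok:
            out[start] = x
    return out


def order_delta_position(
    aln: SelfAlignment, max_order: int = 8, params: OrderParams = OrderParams()
) -> OrderResult:
    """Corrected-displacement order detector for closed symmetry.

    For each candidate k, delta_k is the mean circular sequence displacement
    of the k-fold composed mapping, min(|f^k(i) - i|, n - |f^k(i) - i|); the
    objective delta_k/n + alpha*k is minimized, the regularizer breaking ties
    in favour of the smallest exact period.  Returns k = 1 when the best
    displacement exceeds the significance ceiling or the composition is
    defined almost nowhere.
    """
    n = aln.n
    f = aln.mapping
    if len(f) < 2 * max_order:
        return OrderResult(1, "DeltaPosition", np.inf)
    best_k, best_score, best_delta = 1, np.inf, np.inf
    any_composed = False
    for k in range(1, max_order + 1):
        fk = _compose(f, k)
        if len(fk) < params.min_composition_coverage * len(f):
            continue
        if k > 1:
            any_composed = True
        diffs = np.array([abs(j - i) for i, j in fk.items()], dtype=float)
        delta = float(np.mean(np.minimum(diffs, n - diffs)))
        score = delta / n + params.alpha * k
        if score < best_score:
            best_k, best_score, best_delta = k, score, delta
    if not any_composed:
        return OrderResult(1, "DeltaPosition", np.inf)
    if best_k > 1 and best_delta / n > params.delta_ceiling:
        return OrderResult(1, "DeltaPosition", best_score)
    return OrderResult(best_k, "DeltaPosition", best_score)


def order_rotation_angle(
    aln: SelfAlignment, max_order: int = 8, params: OrderParams = OrderParams()
) -> OrderResult:
    """k = the n in 2..max_order whose ideal angle 360/n is nearest the
    rotation angle of the alignment transform."""
    theta = aln.transform.angle_deg()
    if theta <= params.min_angle:
        return OrderResult(1, "RotationAngle", np.inf)
    best_n, best_dev = 1, np.inf
    for k in range(2, max_order + 1):
        dev = abs(theta - 360.0 / k)
        if dev < best_dev:
            best_n, best_dev = k, dev
    if best_dev >= params.angle_tol:
        return OrderResult(1, "RotationAngle", best_dev)
    return OrderResult(best_n, "RotationAngle", best_dev)


def detect_order_auto(
    aln: SelfAlignment,
    max_order: int = 8,
    method: str = "auto",
    params: OrderParams = OrderParams(),
) -> OrderResult:
    """Dispatch: DeltaPosition for closed (circularly permuted) alignments,
    GraphComponent for open ones; ``method`` overrides the rule."""
    if method == "auto":
        method = "delta-position" if aln.has_cp else "graph-component"
    if method == "delta-position":
        return order_delta_position(aln, max_order, params)
    if method == "rotation-angle":
        return order_rotation_angle(aln, max_order, params)
    if method == "graph-component":
        return order_graph_component(build_alignment_graph(aln), max_order)
    raise ValueError(f"unknown order method {method!r}")
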