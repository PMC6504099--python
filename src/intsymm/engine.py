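"""The full symmetry-detection loop: per-level pipeline with three
significance checkpoints, recursion over repeats, and merging of levels.

One level runs self-alignment -> checkpoint 1 (self-alignment TM-score >=
0.4) -> order detection -> refinement -> checkpoint 2 (order > 1 and
successful refinement) -> Monte Carlo optimization -> checkpoint 3 (average
pairwise repeat TM-score >= 0.36) -> axis extraction.  Significant levels
recurse on the N-terminal repeat until a non-significant result, and the
per-level alignments are merged into one multiple alignment of all leaf
repeats.  A secondary-structure gate can demand a minimum number of SSEs in
the final asymmetric repeating unit (default 0, so simple repeat units such
as helical bundles are included).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import IntsymmError, RefinementError, TooShortError
from .geometry import (
    SymmetryAxis,
    axis_from_transform,
    classify_axis,
    combine_axes,
    detect_point_group,
)
from .optimize import (
    GAP,
    cell_average_distances,
    consensus_transform,
    optimize,
)
from .order import build_alignment_graph, detect_order_auto
from .params import EngineParams
from .refine import RepeatAlignment, refine, repeat_ranges
from .selfalign import SelfAlignment, self_align, tm_superpose
from .structure_io import CoordinateTrace, Structure, assign_secondary_structure, extract_ca_trace


@dataclass
class LevelResult:
    significant: bool
    reason: str = ""
    order: int = 1
    label: str = "C1"
    self_alignment: SelfAlignment | None = None
    alignment: RepeatAlignment | None = None
    axis: SymmetryAxis | None = None
    tm_self: float = 0.0
    tm_avg: float = 0.0


@dataclass
class SymmetryResult:
    """Merged multi-level symmetry annotation for one chain."""

    source_id: str
    significant: bool
    levels: list = field(default_factory=list)   # of LevelResult (significant only)
    total_order: int = 1
    overall_label: str = "C1"
    alignment: RepeatAlignment | None = None     # leaf repeats, root positions
    trace: CoordinateTrace | None = None
    tm_self: float = 0.0
    tm_avg: float = 0.0
    rmsd: float = 0.0
    coverage: float = 0.0
    reason: str = ""
    point_group: str | None = None
    seed: int = 0

    def repeat_ranges(self) -> list:
        if self.alignment is None:
            return []
        return repeat_ranges(self.alignment)


def average_pairwise_tm(aln: RepeatAlignment, trace: CoordinateTrace) -> float:
    """Mean TM-score over all unordered repeat pairs, each superimposed
    independently and normalized by the longer repeat; pairs with fewer than
    3 common aligned positions are skipped."""
    k = aln.n_repeats
    if k < 2:
        return 0.0
    scores = []
    lengths = [(aln.matrix[r] != GAP).sum() for r in range(k)]
    for a, b in itertools.combinations(range(k), 2):
        both = (aln.matrix[a] != GAP) & (aln.matrix[b] != GAP)
        if both.sum() < 3:
            continue
        P = trace.coords[aln.matrix[a][both]]
        Q = trace.coords[aln.matrix[b][both]]
        norm = int(max(lengths[a], lengths[b]))
        tm, _ = tm_superpose(P, Q, norm)
        scores.append(tm)
    return float(np.mean(scores)) if scores else 0.0


def run_level(
    trace: CoordinateTrace,
    params: EngineParams = EngineParams(),
    rng: np.random.Generator | None = None,
    level: int = 0,
) -> LevelResult:
    """One pass of the pipeline on a (sub)trace, with the three checkpoints."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    try:
        aln = self_align(trace, params.scoring)
    except TooShortError:
        return LevelResult(False, reason="trace too short")
    if aln.tm_score < params.tm_threshold:
        return LevelResult(False, reason="self-alignment TM below threshold",
                           tm_self=aln.tm_score, self_alignment=aln)

    order = detect_order_auto(
        aln, params.order.max_order, params.order_method, params.order
    )
    if order.order < 2:
        return LevelResult(False, reason="symmetry order one",
                           tm_self=aln.tm_score, self_alignment=aln)
    try:
        refined = refine(
            build_alignment_graph(aln), order.order, aln.has_cp,
            params.refine_method, params.refine,
        )
    except RefinementError as exc:
        return LevelResult(False, reason=f"refinement failed: {exc}",
                           tm_self=aln.tm_score, self_alignment=aln)

    final = optimize(refined, trace, params.mc, rng) if params.optimize else refined
    tm_avg = average_pairwise_tm(final, trace)
    if tm_avg < params.avg_tm_threshold:
        return LevelResult(False, reason="average pairwise repeat TM below threshold",
                           tm_self=aln.tm_score, tm_avg=tm_avg, self_alignment=aln)

    T = consensus_transform(final.matrix, trace.coords)
    axis = axis_from_transform(T, level=level)
    axis.repeat_pairs = [(r, r + 1) for r in range(final.n_repeats - 1)]
    label = classify_axis(axis, order.order, aln.has_cp, params.geometry,
                          params.order.max_order)
    return LevelResult(
        True, order=order.order, label=label, self_alignment=aln,
        alignment=final, axis=axis, tm_self=aln.tm_score, tm_avg=tm_avg,
    )


def _to_root(matrix: np.ndarray, index_map: np.ndarray) -> np.ndarray:
    """Translate sub-trace positions to root positions (gaps preserved)."""
    out = matrix.copy()
    sel = out != GAP
    out[sel] = index_map[out[sel]]
    return out


def _merge(parent: np.ndarray, child: np.ndarray) -> np.ndarray:
    """Merge a child alignment (over parent row 0 positions, in root
    coordinates) into the parent: leaf repeat r of parent repeat p occupies
    row p * k_child + r."""
    n_par, _ = parent.shape
    k_child, L_child = child.shape
    rows = []
    for p in range(n_par):
        pos_map = {
            int(parent[0, c]): int(parent[p, c])
            for c in range(parent.shape[1])
            if parent[0, c] != GAP and parent[p, c] != GAP
        }
        for r in range(k_child):
            row = np.full(L_child, GAP, dtype=int)
            for c in range(L_child):
                v = child[r, c]
                if v != GAP and v in pos_map:
                    row[c] = pos_map[v]
            rows.append(row)
    merged = np.array(rows, dtype=int)
    keep = (merged != GAP).any(axis=0)
    return merged[:, keep]


def _result_rmsd(matrix: np.ndarray, coords: np.ndarray) -> float:
    from .optimize import superposed_cells

    cells = superposed_cells(matrix, coords)
    diff = cells[:, None, :, :] - cells[None, :, :, :]
    d2 = np.sum(diff * diff, axis=-1)
    k = matrix.shape[0]
    iu = np.triu_indices(k, 1)
    vals = d2[iu[0], iu[1], :]
    vals = vals[np.isfinite(vals)]
    return float(np.sqrt(vals.mean())) if len(vals) else 0.0


def run_cesymm(
    structure_or_trace: Structure | CoordinateTrace,
    params: EngineParams = EngineParams(),
) -> SymmetryResult:
    """Recursive symmetry detection on one chain.

    Repeats found at each level are fed back into the pipeline (the
    N-terminal repeat is the representative) until a level is
    non-significant; level alignments are merged into one alignment of all
    leaf repeats, the per-level axes are combined into the overall label,
    and a point group is perceived from the leaf repeats when every level is
    closed.
    """
    if isinstance(structure_or_trace, CoordinateTrace):
        trace = structure_or_trace
        source_id = "trace"
    else:
        trace = extract_ca_trace(structure_or_trace)
        source_id = structure_or_trace.source_id
    rng = np.random.default_rng(params.seed)

    levels: list[LevelResult] = []
    leaf_matrix: np.ndarray | None = None
    index_map = np.arange(len(trace))
    sub = trace
    reason = ""
    while True:
        if params.symm_levels and len(levels) >= params.symm_levels:
            break
        res = run_level(sub, params, rng, level=len(levels) + 1)
        if not res.significant:
            reason = res.reason
            break
        root_matrix = _to_root(res.alignment.matrix, index_map)
        res.alignment = RepeatAlignment(root_matrix, res.alignment.provenance)
        # recompute the axis in root coordinates (identical values: sub-trace
        # coordinates are root coordinates)
        levels.append(res)
        leaf_matrix = root_matrix if leaf_matrix is None else _merge(leaf_matrix, root_matrix)
        rep0 = np.sort(root_matrix[0][root_matrix[0] != GAP])
        if len(rep0) < 2 * params.scoring.window:
            reason = "repeat too short to recurse"
            break
        index_map = rep0
        sub = trace.subtrace(rep0)

    if not levels:
        return SymmetryResult(
            source_id, False, reason=reason, trace=trace, seed=params.seed,
            tm_self=0.0,
        )

    final = RepeatAlignment(leaf_matrix, provenance="merged")
    # secondary-structure gate on the final asymmetric repeating unit
    if params.min_sse > 0:
        rep0 = np.sort(leaf_matrix[0][leaf_matrix[0] != GAP])
        if len(rep0) >= 5:
            sse = assign_secondary_structure(trace.subtrace(rep0), params.min_sse_len)
            n_sse = sse.count
        else:
            n_sse = 0
        if n_sse < params.min_sse:
            return SymmetryResult(
                source_id, False, reason="repeat has too few SSEs",
                trace=trace, seed=params.seed, tm_self=levels[0].tm_self,
            )

    total_order = int(np.prod([lv.order for lv in levels]))
    overall = combine_axes([(lv.label, lv.axis) for lv in levels], params.geometry)

    point_group = None
    if all(lv.label.startswith("C") for lv in levels):
        cols_full = np.all(final.matrix != GAP, axis=0)
        if cols_full.sum() >= 3 and final.n_repeats >= 2:
            reps = [trace.coords[final.matrix[r][cols_full]] for r in range(final.n_repeats)]
            try:
                pg = detect_point_group(
                    reps, params.geometry.rmsd_threshold, params.geometry.grid_deg
                )
                point_group = pg.label
            except (ValueError, IntsymmError):
                point_group = None

    ranges = repeat_ranges(final)
    covered = sum(e - s + 1 for s, e in ranges)
    tm_avg = average_pairwise_tm(final, trace)
    return SymmetryResult(
        source_id,
        True,
        levels=levels,
        total_order=total_order,
        overall_label=overall,
        alignment=final,
        trace=trace,
        tm_self=levels[0].tm_self,
        tm_avg=tm_avg,
        rmsd=_result_rmsd(final.matrix, trace.coords),
        coverage=covered / len(trace),
        point_group=point_group,
        seed=params.seed,
    )


def result_to_dict(result: SymmetryResult, params: EngineParams | None = None) -> dict:
    """JSON-ready summary of a symmetry result."""
    levels = [
        {
            "label": lv.label,
            "order": lv.order,
            "angle_deg": round(lv.axis.theta_deg, 3) if lv.axis else None,
            "screw_A": round(lv.axis.screw_t, 3) if lv.axis else None,
            "axis_point": [round(float(x), 3) for x in lv.axis.point] if lv.axis else None,
            "axis_dir": [round(float(x), 4) for x in lv.axis.direction] if lv.axis else None,
            "repeat_ranges": repeat_ranges(lv.alignment) if lv.alignment else [],
        }
        for lv in result.levels
    ]
    out = {
        "id": result.source_id,
        "significant": result.significant,
        "levels": levels,
        "overall_label": result.overall_label,
        "total_order": result.total_order,
        "point_group": result.point_group,
        "tm_self": round(result.tm_self, 4),
        "tm_avg_pairwise": round(result.tm_avg, 4),
        "rmsd": round(result.rmsd, 4),
        "coverage": round(result.coverage, 4),
        "reason": result.reason,
        "seed": result.seed,
    }
    if params is not None:
        out["parameters"] = {
            "tm_threshold": params.tm_threshold,
            "avg_tm_threshold": params.avg_tm_threshold,
            "min_sse": params.min_sse,
            "max_order": params.order.max_order,
            "order_method": params.order_method,
            "refine_method": params.refine_method,
            "optimize": params.optimize,
            "d_c": params.mc.d_c,
            "rmsd_point_group": params.geometry.rmsd_threshold,
            "symm_levels": params.symm_levels,
        }
    return out
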