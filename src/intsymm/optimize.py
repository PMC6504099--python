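"""Monte Carlo refinement of the multiple repeat alignment.

The alignment is a k x L matrix of trace positions (rows are repeats,
columns equivalent positions; gaps allowed from here on).  Four moves —
expand, shrink, shift, insert-gap — modify the matrix under the constraint
that every row stays in chain order and rows remain disjoint.  Shrink and
insert-gap are biased toward the worst-scoring column/cell through a
geometric distribution over the distance ranking.  The score

    S = sum_ij [ C / (1 + (d_ij/d0)^2) - A ] - G * n_gaps

uses the average distance d_ij from each aligned residue to its equivalents
after a symmetry-constrained superposition (one consensus repeat-to-repeat
transform applied by powers), with A chosen so a position scores exactly
zero at the distance cutoff d_c.  Worsening moves are accepted with a
probability that shrinks with the score drop and with the iteration count;
the best alignment ever visited is returned, so optimization can only
improve the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform, superimpose
from .params import McParams, ScoringParams, d0_from_length
from .refine import RepeatAlignment
from .structure_io import CoordinateTrace

GAP = -1


# ---------------------------------------------------------------------------
# symmetry-constrained superposition and scoring
# ---------------------------------------------------------------------------

def consensus_transform(matrix: np.ndarray, coords: np.ndarray) -> RigidTransform:
    """One transform mapping each repeat onto the next, fit jointly over all
    consecutive row pairs of the alignment."""
    k = matrix.shape[0]
    P, Q = [], []
    for r in range(k - 1):
        both = (matrix[r] != GAP) & (matrix[r + 1] != GAP)
        P.append(coords[matrix[r][both]])
        Q.append(coords[matrix[r + 1][both]])
    P = np.concatenate(P) if P else np.zeros((0, 3))
    Q = np.concatenate(Q) if Q else np.zeros((0, 3))
    if len(P) < 3:
        return RigidTransform.identity()
    try:
        T, _ = superimpose(P, Q)
    except Exception:
        return RigidTransform.identity()
    return T


def superposed_cells(matrix: np.ndarray, coords: np.ndarray,
                     transform: RigidTransform | None = None) -> np.ndarray:
    """(k, L, 3) cell coordinates in the frame of repeat 0: repeat r is
    transformed by the -r power of the consensus transform.  Gaps are NaN."""
    if transform is None:
        transform = consensus_transform(matrix, coords)
    k, L = matrix.shape
    out = np.full((k, L, 3), np.nan)
    for r in range(k):
        inv = transform.power(-r)
        sel = matrix[r] != GAP
        if sel.any():
            out[r, sel] = inv.apply(coords[matrix[r][sel]])
    return out


def cell_average_distances(matrix: np.ndarray, coords: np.ndarray,
                           transform: RigidTransform | None = None) -> np.ndarray:
    """(k, L) matrix of d_ij: mean distance from each aligned residue to all
    its equivalents in the column, after superposition.  NaN for gap cells
    and for cells in columns with fewer than two aligned residues."""
    cells = superposed_cells(matrix, coords, transform)
    diff = cells[:, None, :, :] - cells[None, :, :, :]   # (k, k, L, 3)
    dist = np.sqrt(np.sum(diff * diff, axis=-1))          # (k, k, L)
    k = matrix.shape[0]
    dist[np.arange(k), np.arange(k), :] = np.nan
    counts = np.sum(np.isfinite(dist), axis=1)            # (k, L)
    sums = np.nansum(np.nan_to_num(dist, nan=0.0), axis=1)
    d = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    d[matrix == GAP] = np.nan
    return d


def column_average_distance(aln: RepeatAlignment, trace: CoordinateTrace,
                            i: int, j: int) -> float:
    """d_ij of one cell (repeat i, column j); NaN if undefined."""
    d = cell_average_distances(aln.matrix, trace.coords)
    return float(d[i, j])


def cell_score_term(d_ij, n_residues: int, params: McParams = McParams()):
    """Score contribution of one aligned position at average distance d_ij:
    C / (1 + (d_ij/d0)^2) - A, with A fixed by the condition that the term
    is zero at d_ij = d_c."""
    d0 = d0_from_length(n_residues)
    A = params.C / (1.0 + (params.d_c / d0) ** 2)
    return params.C / (1.0 + (np.asarray(d_ij, dtype=float) / d0) ** 2) - A


def score_matrix(matrix: np.ndarray, coords: np.ndarray, n_residues: int,
                 params: McParams,
                 transform: RigidTransform | None = None) -> float:
    """The smoothed alignment score S (see module docstring)."""
    G = params.gap_penalty()
    d = cell_average_distances(matrix, coords, transform)
    aligned = np.isfinite(d)
    terms = cell_score_term(d[aligned], n_residues, params)
    n_gaps = matrix.size - int(aligned.sum())
    return float(terms.sum() - G * n_gaps)


def score_alignment(aln: RepeatAlignment, trace: CoordinateTrace,
                    params: McParams = McParams()) -> float:
    return score_matrix(aln.matrix, trace.coords, len(trace), params)


def acceptance_probability(delta_S: float, m: int, params: McParams, M: int) -> float:
    """p = 1 for improving moves; otherwise ((C + dS)/(C m)) (1 - m/M),
    clamped to [0, 1] — proportional to the score difference and decreasing
    with the iteration number."""
    if delta_S >= 0:
        return 1.0
    p = ((params.C + delta_S) / (params.C * m)) * (1.0 - m / M)
    return float(min(1.0, max(0.0, p)))


# ---------------------------------------------------------------------------
# moves
# ---------------------------------------------------------------------------

@dataclass
class Move:
    kind: str
    matrix: np.ndarray


def _row_bounds(matrix: np.ndarray, r: int, n: int) -> tuple[int, int]:
    """Open interval of positions available to row r (between its
    neighbouring repeats and the chain termini)."""
    lo = -1
    for q in range(r - 1, -1, -1):
        pos = matrix[q][matrix[q] != GAP]
        if len(pos):
            lo = int(pos.max())
            break
    hi = n
    for q in range(r + 1, matrix.shape[0]):
        pos = matrix[q][matrix[q] != GAP]
        if len(pos):
            hi = int(pos.min())
            break
    return lo, hi


def _geometric_rank(rng: np.random.Generator, n_ranks: int, p: float) -> int:
    r = int(rng.geometric(p)) - 1
    return min(r, n_ranks - 1)


def _blocks(row: np.ndarray) -> list:
    """Maximal runs of columns holding consecutive residues."""
    blocks = []
    cur: list[int] = []
    for c, v in enumerate(row):
        if v == GAP:
            if cur:
                blocks.append(cur)
            cur = []
        elif cur and v != row[cur[-1]] + 1:
            blocks.append(cur)
            cur = [c]
        else:
            cur.append(c)
    if cur:
        blocks.append(cur)
    return blocks


def _move_expand(matrix, n, rng, params):
    side = "left" if rng.random() < 0.5 else "right"
    k, L = matrix.shape
    col = np.full(k, GAP, dtype=int)
    for r in range(k):
        pos = matrix[r][matrix[r] != GAP]
        if len(pos) == 0:
            continue
        lo, hi = _row_bounds(matrix, r, n)
        if side == "left":
            cand = int(pos.min()) - 1
            if cand > lo and cand >= 0:
                col[r] = cand
        else:
            cand = int(pos.max()) + 1
            if cand < hi and cand < n:
                col[r] = cand
    if (col != GAP).sum() < 2:
        return None
    if side == "left":
        new = np.concatenate([col[:, None], matrix], axis=1)
    else:
        new = np.concatenate([matrix, col[:, None]], axis=1)
    return Move("expand", new)


def _move_shrink(matrix, distances, rng, params):
    k, L = matrix.shape
    if L <= params.min_columns:
        return None
    counts = np.sum(np.isfinite(distances), axis=0)
    sums = np.nansum(np.nan_to_num(distances, nan=0.0), axis=0)
    col_d = np.where(counts > 0, sums / np.maximum(counts, 1), np.inf)  # undefined worst
    order = np.argsort(-col_d)
    c = order[_geometric_rank(rng, L, params.geometric_p)]
    new = np.delete(matrix, c, axis=1)
    if ((new != GAP).sum(axis=1) < 2).any():
        return None
    return Move("shrink", new)


def _move_shift(matrix, n, rng, params):
    k, L = matrix.shape
    r = int(rng.integers(k))
    blocks = _blocks(matrix[r])
    if not blocks:
        return None
    block = blocks[int(rng.integers(len(blocks)))]
    step = 1 if rng.random() < 0.5 else -1
    shifted = matrix[r, block] + step
    if shifted.min() < 0 or shifted.max() >= n:  # would collide with the gap
        return None                              # sentinel or leave the chain
    new = matrix.copy()
    new[r, block] = shifted
    lo, hi = _row_bounds(new, r, n)
    pos = new[r][new[r] != GAP]
    if pos.min() <= lo or pos.max() >= hi or np.any(np.diff(pos) <= 0):
        return None
    return Move("shift", new)


def _move_insert_gap(matrix, distances, rng, params):
    k, L = matrix.shape
    flat = distances.flatten()
    cells = np.flatnonzero(np.isfinite(flat))
    if len(cells) == 0:
        return None
    order = cells[np.argsort(-flat[cells])]
    idx = order[_geometric_rank(rng, len(order), params.geometric_p)]
    r, c = divmod(int(idx), L)
    if (matrix[r] != GAP).sum() <= 2:
        return None
    new = matrix.copy()
    new[r, c] = GAP
    keep = (new != GAP).any(axis=0)
    new = new[:, keep]
    if new.shape[1] < params.min_columns:
        return None
    return Move("insert_gap", new)


def propose_move(matrix: np.ndarray, coords: np.ndarray, n: int,
                 rng: np.random.Generator, params: McParams,
                 distances: np.ndarray | None = None,
                 max_attempts: int = 40) -> Move | None:
    """Draw one feasible move; infeasible draws are resampled."""
    if distances is None or distances.shape != matrix.shape:
        distances = cell_average_distances(matrix, coords)
    kinds = ("expand", "shrink", "shift", "insert_gap")
    weights = np.asarray(params.move_weights, dtype=float)
    weights = weights / weights.sum()
    for _ in range(max_attempts):
        kind = kinds[int(rng.choice(4, p=weights))]
        if kind == "expand":
            move = _move_expand(matrix, n, rng, params)
        elif kind == "shrink":
            move = _move_shrink(matrix, distances, rng, params)
        elif kind == "shift":
            move = _move_shift(matrix, n, rng, params)
        else:
            move = _move_insert_gap(matrix, distances, rng, params)
        if move is not None:
            return move
    return None


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def optimize(aln: RepeatAlignment, trace: CoordinateTrace,
             params: McParams = McParams(),
             rng: np.random.Generator | int | None = 0,
             score_trace: list | None = None) -> RepeatAlignment:
    """Monte Carlo optimization of the repeat alignment.

    Runs at most M iterations (default 100x the trace length) and stops
    early after M/stall_divisor consecutive rejections.  Returns the
    best-scoring alignment visited; the result never scores below the input.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    coords = trace.coords
    n = len(trace)
    M = params.iterations(n)
    stall = max(1, M // params.stall_divisor)

    matrix = aln.matrix.copy()
    current = score_matrix(matrix, coords, n, params)
    best_score, best_matrix = current, matrix.copy()
    distances = cell_average_distances(matrix, coords)
    rejects = 0

    for m in range(1, M + 1):
        move = propose_move(matrix, coords, n, rng, params, distances)
        if move is None:
            rejects += 1
            if rejects >= stall:
                break
            continue
        new_score = score_matrix(move.matrix, coords, n, params)
        p = acceptance_probability(new_score - current, m, params, M)
        if p >= 1.0 or rng.random() < p:
            matrix = move.matrix
            current = new_score
            distances = cell_average_distances(matrix, coords)
            rejects = 0
            if current > best_score:
                best_score, best_matrix = current, matrix.copy()
        else:
            rejects += 1
        if score_trace is not None:
            score_trace.append(current)
        if rejects >= stall:
            break

    out = RepeatAlignment(best_matrix, provenance=aln.provenance + "+MC")
    out.validate()
    return out
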