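"""Monte Carlo optimization: the smoothed score, the acceptance schedule,
the four moves, and the optimization contract."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from intsymm.optimize import (
    GAP,
    Move,
    acceptance_probability,
    cell_average_distances,
    column_average_distance,
    optimize,
    propose_move,
    score_alignment,
    score_matrix,
    _move_expand,
)
from intsymm.order import build_alignment_graph
from intsymm.params import McParams, d0_from_length
from intsymm.refine import RepeatAlignment, refine
from intsymm.selfalign import self_align
from intsymm.structure_io import CoordinateTrace


def refined_alignment(fixture):
    _, _, trace = fixture
    aln = self_align(trace)
    from intsymm.order import detect_order_auto

    k = detect_order_auto(aln).order
    return refine(build_alignment_graph(aln), k, aln.has_cp), trace


class TestColumnDistances:
    def test_coincident_residues_have_zero_distance(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        d = cell_average_distances(aln.matrix, trace.coords)
        # noise-free fixture: every aligned residue coincides after the
        # symmetry-constrained superposition
        assert np.nanmax(d) < 1e-6

    def test_two_row_column_reports_pair_distance(self):
        # two straight segments 4 A apart after the identity transform
        base = np.stack([np.arange(10.0), np.zeros(10), np.zeros(10)], axis=1)
        coords = np.concatenate([base, base + np.array([20.0, 4.0, 0.0])])
        trace = CoordinateTrace(coords, list(range(20)))
        matrix = np.array([[0, 1, 2], [10, 11, 12]])
        d = cell_average_distances(matrix, trace.coords, transform=None)
        # consensus transform superimposes them exactly; force identity to
        # measure the raw 4 A offset
        from intsymm.geometry import RigidTransform

        d_raw = cell_average_distances(matrix, trace.coords,
                                       transform=RigidTransform.identity())
        offset = coords[10] - coords[0]
        expected = float(np.linalg.norm(offset))
        assert np.allclose(d_raw, expected)

    def test_three_row_column_matches_brute_force(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(0, 8, (30, 3))
        trace = CoordinateTrace(coords, list(range(30)))
        matrix = np.array([[0, 1], [10, 11], [20, 21]])
        from intsymm.geometry import RigidTransform

        d = cell_average_distances(matrix, coords, RigidTransform.identity())
        for i in range(3):
            for j in range(2):
                others = [matrix[r, j] for r in range(3) if r != i]
                expected = np.mean(
                    [np.linalg.norm(coords[matrix[i, j]] - coords[o]) for o in others]
                )
                assert d[i, j] == pytest.approx(expected, abs=1e-9)


class TestScore:
    def test_zero_at_distance_cutoff(self):
        """Analytic zero crossing: a position whose average distance equals
        d_c contributes exactly zero for any d0."""
        params = McParams(C=20.0, d_c=7.0)
        for L in (50, 100, 300):
            d0 = d0_from_length(L)
            A = params.C / (1.0 + (params.d_c / d0) ** 2)
            term = params.C / (1.0 + (params.d_c / d0) ** 2) - A
            assert term == 0.0

    def test_perfect_gapless_alignment_score(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        params = McParams()
        d0 = d0_from_length(len(trace))
        A = params.C / (1.0 + (params.d_c / d0) ** 2)
        N, L = aln.matrix.shape
        expected = N * L * (params.C - A)
        assert score_alignment(aln, trace, params) == pytest.approx(expected, rel=1e-6)

    def test_matches_independent_reimplementation(self, c4_fixture):
        """Smoothed alignment score against a from-scratch loop
        implementation with its own Procrustes superposition."""
        aln, trace = refined_alignment(c4_fixture)
        rng = np.random.default_rng(0)
        matrix = aln.matrix.copy()
        # introduce a few gaps to exercise the gap term
        for _ in range(5):
            r, c = rng.integers(matrix.shape[0]), rng.integers(matrix.shape[1])
            if (matrix[r] != GAP).sum() > 3:
                matrix[r, c] = GAP
        params = McParams()
        ours = score_matrix(matrix, trace.coords, len(trace), params)
        oracle = _score_oracle(matrix, trace.coords, len(trace), params)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_cell_term_strictly_decreasing_in_distance(self):
        params = McParams()
        d0 = d0_from_length(120)
        A = params.C / (1.0 + (params.d_c / d0) ** 2)
        d = np.linspace(0, 20, 200)
        terms = params.C / (1.0 + (d / d0) ** 2) - A
        assert np.all(np.diff(terms) < 0)


def _score_oracle(matrix, coords, n_res, params):
    """Independent reimplementation: plain loops + scipy Procrustes for the
    consensus transform."""
    k, L = matrix.shape
    P, Q = [], []
    for r in range(k - 1):
        for c in range(L):
            if matrix[r, c] != GAP and matrix[r + 1, c] != GAP:
                P.append(coords[matrix[r, c]])
                Q.append(coords[matrix[r + 1, c]])
    P, Q = np.array(P), np.array(Q)
    rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
    R = rot.as_matrix()
    t = Q.mean(0) - R @ P.mean(0)

    def power(m):
        Rm, tm = np.eye(3), np.zeros(3)
        for _ in range(m):
            tm = R @ tm + t
            Rm = R @ Rm
        return Rm, tm

    frames = []
    for r in range(k):
        Rm, tm = power(r)
        Rinv, tinv = Rm.T, -Rm.T @ tm
        frames.append((Rinv, tinv))
    d0 = 1.24 * np.cbrt(n_res - 15.0) - 1.8
    d0 = max(0.5, d0)
    A = params.C / (1.0 + (params.d_c / d0) ** 2)
    G = params.C / 2.0
    score = 0.0
    n_gaps = 0
    cells = np.full((k, L, 3), np.nan)
    for r in range(k):
        Rinv, tinv = frames[r]
        for c in range(L):
            if matrix[r, c] != GAP:
                cells[r, c] = Rinv @ coords[matrix[r, c]] + tinv
    for c in range(L):
        present = [r for r in range(k) if matrix[r, c] != GAP]
        for r in range(k):
            if matrix[r, c] == GAP:
                n_gaps += 1
            elif len(present) < 2:
                n_gaps += 1
            else:
                dij = np.mean(
                    [np.linalg.norm(cells[r, c] - cells[o, c]) for o in present if o != r]
                )
                score += params.C / (1.0 + (dij / d0) ** 2) - A
    return score - G * n_gaps


class TestAcceptance:
    def test_improving_moves_always_accepted(self):
        assert acceptance_probability(5.0, 10, McParams(), 1000) == 1.0

    def test_last_iteration_rejects_worsening_moves(self):
        assert acceptance_probability(-1.0, 1000, McParams(), 1000) == 0.0

    def test_probability_non_increasing_in_iteration(self):
        params = McParams()
        M = 500
        ps = [acceptance_probability(-1.0, m, params, M) for m in range(1, M + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)


class TestMoves:
    def test_shrink_prefers_worst_column(self, c3_fixture):
        """The worst-distance column is the modal shrink choice with the
        geometric rank weight of about one half."""
        aln, trace = refined_alignment(c3_fixture)
        matrix = aln.matrix.copy()
        # corrupt one column far beyond d_c by pointing a row at a linker
        from intsymm.optimize import _move_shrink

        distances = cell_average_distances(matrix, trace.coords).copy()
        distances[:, 5] = 50.0
        rng = np.random.default_rng(0)
        hits = 0
        draws = 10_000
        for _ in range(draws):
            mv = _move_shrink(matrix, distances, rng, McParams())
            if mv.matrix.shape[1] == matrix.shape[1] - 1:
                # which column was deleted?
                for c in range(matrix.shape[1]):
                    if not np.array_equal(np.delete(matrix, c, axis=1), mv.matrix):
                        continue
                    if c == 5:
                        hits += 1
                    break
        assert hits / draws == pytest.approx(0.5, abs=0.03)

    def test_expand_infeasible_when_no_row_can_extend(self):
        # all repeats flush against termini/neighbours: nothing to grab
        matrix = np.array([[0, 1, 2], [3, 4, 5]])
        coords = np.zeros((6, 3))
        rng = np.random.default_rng(0)
        assert _move_expand(matrix, 6, rng, McParams()) is None

    def test_random_moves_preserve_invariants(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        rng = np.random.default_rng(42)
        matrix = aln.matrix.copy()
        for _ in range(2000):
            mv = propose_move(matrix, trace.coords, len(trace), rng, McParams())
            if mv is None:
                continue
            RepeatAlignment(mv.matrix).validate()
            matrix = mv.matrix


class TestOptimize:
    def test_cannot_degrade_an_optimal_alignment(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        s0 = score_alignment(aln, trace)
        out = optimize(aln, trace, rng=0)
        assert score_alignment(out, trace) >= s0
        assert abs(out.n_columns - aln.n_columns) <= 4

    def test_truncated_alignment_recovers_length(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        L = aln.n_columns
        trunc = RepeatAlignment(aln.matrix[:, L // 4: L - L // 4])
        out = optimize(trunc, trace, rng=1)
        assert out.n_columns >= 0.9 * L

    def test_same_seed_same_trajectory(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        L = aln.n_columns
        trunc = RepeatAlignment(aln.matrix[:, L // 4: L - L // 4])
        t1, t2 = [], []
        a = optimize(trunc, trace, rng=3, score_trace=t1)
        b = optimize(trunc, trace, rng=3, score_trace=t2)
        assert t1 == t2
        assert np.array_equal(a.matrix, b.matrix)

    def test_seed_stability_of_best_score(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        L = aln.n_columns
        trunc = RepeatAlignment(aln.matrix[:, L // 4: L - L // 4])
        scores = [score_alignment(optimize(trunc, trace, rng=s), trace)
                  for s in range(3)]
        assert (max(scores) - min(scores)) / max(scores) < 0.05

    def test_infinite_gap_penalty_keeps_alignment_gapless(self, c3_fixture):
        aln, trace = refined_alignment(c3_fixture)
        params = McParams(G=1e9)
        out = optimize(aln, trace, params=params, rng=0)
        assert np.all(out.matrix != GAP)
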