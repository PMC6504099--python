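"""Full pipeline: per-level checkpoints, recursion, level merging and the
final symmetry annotation."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from intsymm.engine import average_pairwise_tm, result_to_dict, run_cesymm, run_level
from intsymm.optimize import GAP
from intsymm.params import EngineParams
from intsymm.refine import RepeatAlignment
from intsymm.selfalign import tm_superpose
from intsymm.structure_io import CoordinateTrace, extract_ca_trace
from intsymm.synthetic import GeneratorSpec, make_decoy, make_symmetric

from conftest import build


class TestRunLevel:
    def test_noise_free_c3_is_significant(self, c3_fixture):
        _, _, trace = c3_fixture
        res = run_level(trace)
        assert res.significant
        assert res.order == 3
        assert res.label == "C3"
        assert res.tm_avg >= 0.9

    def test_decoy_fails_at_checkpoint_one(self, decoy_trace):
        res = run_level(decoy_trace)
        assert not res.significant
        assert "self-alignment TM" in res.reason

    def test_corrupted_repeat_breaks_significance(self, c2_fixture):
        st, truth, trace = c2_fixture
        coords = trace.coords.copy()
        s, e = truth.repeat_ranges[1]
        decoy = extract_ca_trace(make_decoy(60, seed=9)).coords[: e - s + 1]
        coords[s:e + 1] = decoy - decoy.mean(0) + coords[s:e + 1].mean(0)
        res = run_level(CoordinateTrace(coords, list(trace.labels)))
        assert not res.significant


class TestRecursion:
    def test_c8_reaches_total_order_eight(self, c8_fixture):
        st, _, _ = c8_fixture
        r = run_cesymm(st)
        assert r.significant
        assert r.total_order == 8
        assert r.overall_label == "C8"

    def test_dihedral_fixture_combines_to_point_group(self, d2_fixture):
        st, _, _ = d2_fixture
        r = run_cesymm(st)
        assert r.significant
        assert r.total_order == 4
        assert [lv.order for lv in r.levels] == [2, 2]
        assert r.overall_label == "D2"
        assert r.point_group == "D2"

    def test_two_domains_with_independent_axes_stay_hierarchical(self):
        """Two internally 2-fold domains related by a parallel but offset
        2-fold: four repeats over two levels, no single point group."""
        st, truth, trace = build(n=2, seed=11)
        axis_offset = np.array([40.0, 4.0, 0.0])
        flip = Rotation.from_euler("z", 180, degrees=True).as_matrix()
        domB = (trace.coords - axis_offset) @ flip.T + axis_offset
        bridge_len = 3
        step = (domB[0] - trace.coords[-1]) / (bridge_len + 1)
        bridge = trace.coords[-1] + step * np.arange(1, bridge_len + 1)[:, None]
        coords = np.concatenate([trace.coords, bridge, domB])
        tr = CoordinateTrace(coords, [f"A{i}" for i in range(len(coords))])
        r = run_cesymm(tr)
        assert r.significant
        assert r.total_order == 4
        assert len(r.levels) == 2
        assert "/" in r.overall_label  # independent axes: hierarchical label

    def test_asymmetric_chain_reports_c1(self, decoy_trace):
        r = run_cesymm(decoy_trace)
        assert not r.significant
        assert r.total_order == 1
        assert r.levels == []

    def test_recursion_terminates_with_shrinking_repeats(self, c6_fixture):
        st, _, trace = c6_fixture
        r = run_cesymm(st)
        last = len(trace)
        for lv in r.levels:
            rep0 = lv.alignment.row_positions(0)
            assert len(rep0) < last
            last = len(rep0)


class TestAveragePairwiseTm:
    def test_identical_repeats_score_one(self, c4_fixture):
        st, _, trace = c4_fixture
        r = run_cesymm(st)
        assert average_pairwise_tm(r.alignment, trace) >= 0.9

    def test_two_rows_equal_single_pair_score(self):
        rng = np.random.default_rng(4)
        a = np.cumsum(rng.normal(0, 2, (20, 3)), axis=0)
        b = a @ Rotation.from_euler("x", 40, degrees=True).as_matrix().T + 30.0
        coords = np.concatenate([a, b])
        trace = CoordinateTrace(coords, list(range(40)))
        aln = RepeatAlignment(np.array([list(range(20)), list(range(20, 40))]))
        tm, _ = tm_superpose(a, b, 20)
        assert average_pairwise_tm(aln, trace) == pytest.approx(tm, abs=1e-9)

    def test_matches_pairwise_oracle_with_outlier(self):
        rng = np.random.default_rng(5)
        a = np.cumsum(rng.normal(0, 2, (15, 3)), axis=0)
        b = a + np.array([25.0, 0, 0]) + rng.normal(0, 0.5, a.shape)
        c = np.cumsum(rng.normal(0, 2, (15, 3)), axis=0) + np.array([0, 30.0, 0])
        coords = np.concatenate([a, b, c])
        trace = CoordinateTrace(coords, list(range(45)))
        aln = RepeatAlignment(
            np.array([list(range(15)), list(range(15, 30)), list(range(30, 45))])
        )
        expect = np.mean([
            tm_superpose(coords[list(r1)], coords[list(r2)], 15)[0]
            for r1, r2 in itertools.combinations(
                [range(15), range(15, 30), range(30, 45)], 2)
        ])
        assert average_pairwise_tm(aln, trace) == pytest.approx(expect, abs=1e-6)


class TestResultContract:
    def test_determinism_across_runs(self, c4_fixture):
        st, _, _ = c4_fixture
        params = EngineParams(seed=5)
        d1 = result_to_dict(run_cesymm(st, params))
        d2 = result_to_dict(run_cesymm(st, params))
        assert d1 == d2

    def test_raising_tm_threshold_never_creates_significance(self, c3_fixture):
        st, _, _ = c3_fixture
        lo = run_cesymm(st, EngineParams(tm_threshold=0.4))
        hi = run_cesymm(st, EngineParams(tm_threshold=0.99))
        assert lo.significant or not hi.significant
        assert not hi.significant  # 0.99 exceeds the fixture's self-TM

    def test_min_sse_gate_excludes_simple_repeats(self):
        st, _, _ = build(n=4, motif="helix", motif_len=14, seed=6,
                         arrangement="cyclic")
        included = run_cesymm(st, EngineParams())
        gated = run_cesymm(st, EngineParams(min_sse=2))
        if included.significant:  # single-helix repeat: 1 SSE
            assert not gated.significant

    def test_result_dict_schema(self, c4_fixture):
        st, _, _ = c4_fixture
        d = result_to_dict(run_cesymm(st), EngineParams())
        for key in ("id", "significant", "levels", "overall_label", "total_order",
                    "tm_self", "tm_avg_pairwise", "rmsd", "coverage", "seed",
                    "parameters"):
            assert key in d
        assert d["levels"][0]["repeat_ranges"]
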