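"""Strength aggregation, dominance, graph construction and current-flow
centralities (against a dense electrical-network oracle)."""

import math

import networkx as nx
import numpy as np
import pytest

from neurosym.augment import (
    descriptor_meta,
    product_stream,
    stage1_features,
)
from neurosym.hubs import (
    StrengthMatrix,
    accumulate_strengths,
    build_graph,
    centrality_table,
    current_flow_centralities,
    dominant_factor,
    vertex_strength,
)
from neurosym.scoring import (
    ChiSquareRecord,
    chi_square,
    nonneg_calibrate,
    scan_universe,
    score_all_for_strength,
)
from neurosym.augment import FeatureDescriptor
from tests.conftest import make_cohort


def _rec(chi2, roi1, roi2, band1="theta", band2="alpha", task1=1, task2=2,
         log=False):
    d = FeatureDescriptor(
        "product",
        product=(
            FeatureDescriptor("identity", roi1, band1, task1),
            FeatureDescriptor("identity", roi2, band2, task2),
        ),
        log=log,
    )
    return ChiSquareRecord(d, chi2)


class TestAccumulate:
    def test_pair_sum(self):
        m = accumulate_strengths(
            [_rec(10.0, 1, 2), _rec(20.0, 1, 2, log=True), _rec(5.0, 2, 1)],
            n_roi=3,
        )
        assert m.pair_strength(1, 2) == 35.0

    def test_matrix_symmetric_with_zero_diagonal(self):
        m = accumulate_strengths([_rec(7.0, 1, 3)], n_roi=4)
        M = m.matrix
        np.testing.assert_array_equal(M, M.T)
        np.testing.assert_array_equal(np.diag(M), 0.0)
        assert M[0, 2] == M[2, 0] == 7.0

    def test_records_without_roi_pair_skipped_and_counted(self):
        singleton = ChiSquareRecord(
            FeatureDescriptor("identity", 1, "theta", 1), 9.0
        )
        same_roi = _rec(4.0, 2, 2)
        m = accumulate_strengths([singleton, same_roi, _rec(1.0, 1, 2)], n_roi=3)
        assert m.skipped == 2
        assert m.matrix.sum() == 2.0  # only the valid pair, twice (symmetry)

    def test_order_invariance_and_additivity(self):
        recs = [_rec(float(i), 1 + i % 2, 3, task1=1 + i % 2) for i in range(6)]
        a = accumulate_strengths(recs, n_roi=4)
        b = accumulate_strengths(recs[::-1], n_roi=4)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(a._band_acc, b._band_acc)
        half1 = accumulate_strengths(recs[:3], n_roi=4)
        half2 = accumulate_strengths(recs[3:], n_roi=4)
        np.testing.assert_allclose(half1.matrix + half2.matrix, a.matrix)


@pytest.fixture(scope="module")
def two_band_toy():
    rng = np.random.default_rng(11)
    return make_cohort(
        rng.standard_normal((10, 4, 2, 2)),
        bands=("theta", "alpha"),
    )


class TestBlockPathOracle:
    """The vectorized block accumulator reproduces a transparent
    per-record group-by computed with the scalar chi-square."""

    def test_block_equals_record_path_and_group_by(self, two_band_toy):
        toy = two_band_toy
        stage1 = stage1_features(toy)
        y = toy.label_vector("anxiety")

        meta = descriptor_meta(stage1.descriptors, toy.bands, toy.tasks)
        fast = StrengthMatrix(4, toy.bands, toy.tasks, stage1_meta=meta)
        scan_universe(
            stage1.values, y, k=None, block_size=37, strength_sink=fast
        )

        slow = StrengthMatrix(4, toy.bands, toy.tasks)
        score_all_for_strength(
            lambda: product_stream(stage1, 37), y, slow
        )
        np.testing.assert_allclose(fast.matrix, slow.matrix, rtol=1e-9)
        np.testing.assert_allclose(fast._band_acc, slow._band_acc, rtol=1e-9)
        np.testing.assert_allclose(fast._task_acc, slow._task_acc, rtol=1e-9)
        np.testing.assert_allclose(fast._log_acc, slow._log_acc, rtol=1e-9)
        assert fast.skipped == slow.skipped
        assert fast.n_records == slow.n_records

        # independent group-by with the scalar statistic
        expected = np.zeros((4, 4))
        for block in product_stream(stage1, 1_000_000):
            for c, d in enumerate(block.descriptors):
                pair = d.roi_pair
                if pair is None:
                    continue
                col = block.values[:, c]
                plain = nonneg_calibrate(col) if col.min() < 0 else col
                chi = chi_square(plain, y)
                mn, mx = col.min(), col.max()
                logv = (
                    np.zeros_like(col)
                    if mx == mn
                    else np.log1p((col - mn) / (mx - mn))
                )
                chi += chi_square(logv, y)
                i, j = pair[0] - 1, pair[1] - 1
                expected[i, j] += chi
                expected[j, i] += chi
        np.testing.assert_allclose(fast.matrix, expected, rtol=1e-9)


class TestVertexAndDominance:
    def test_vertex_strength_sums_incident_pairs(self):
        m = accumulate_strengths([_rec(4.0, 1, 2), _rec(6.0, 1, 3)], n_roi=3)
        assert vertex_strength(m, 1) == 10.0
        assert vertex_strength(m, 2) == 4.0

    def test_isolated_roi_has_zero_strength(self):
        m = accumulate_strengths([_rec(4.0, 1, 2)], n_roi=5)
        assert vertex_strength(m, 5) == 0.0

    def test_handshake_identity(self):
        recs = [_rec(3.0, 1, 2), _rec(5.0, 2, 4), _rec(1.0, 3, 4)]
        m = accumulate_strengths(recs, n_roi=4)
        total = sum(vertex_strength(m, i) for i in range(1, 5))
        assert total == pytest.approx(2 * (3 + 5 + 1))

    def test_dominant_band_argmax(self):
        recs = [
            _rec(6.0, 1, 2, band1="theta", band2="theta"),
            _rec(15.0, 1, 2, band1="alpha", band2="alpha"),
            _rec(1.5, 1, 2, band1="beta", band2="beta"),
        ]
        m = accumulate_strengths(recs, n_roi=2,
                                 bands=("theta", "alpha", "beta"))
        assert dominant_factor(m, pair=(1, 2), factor="band") == "alpha"

    def test_single_record_pair_dominated_by_its_levels(self):
        m = accumulate_strengths(
            [_rec(2.0, 3, 1, band1="beta", band2="beta", task1=2, task2=2)],
            n_roi=3,
        )
        assert dominant_factor(m, pair=(1, 3), factor="band") == "beta"
        assert dominant_factor(m, pair=(1, 3), factor="task") == 2

    def test_tie_breaks_by_level_order(self):
        recs = [
            _rec(5.0, 1, 2, band1="beta", band2="beta"),
            _rec(5.0, 1, 2, band1="theta", band2="theta"),
        ]
        m = accumulate_strengths(recs, n_roi=2)
        assert dominant_factor(m, pair=(1, 2), factor="band") == "theta"

    def test_all_zero_accumulator_is_undetermined(self):
        m = StrengthMatrix(3)
        assert dominant_factor(m, pair=(1, 2), factor="band") is None

    def test_aggregated_levels_never_compete(self):
        agg = FeatureDescriptor("mean", 1, None, 1)
        conc = FeatureDescriptor("identity", 2, "beta", 1)
        rec = ChiSquareRecord(
            FeatureDescriptor("product", product=(agg, conc)), 10.0
        )
        m = accumulate_strengths([rec], n_roi=2)
        assert m.pair_strength(1, 2) == 10.0  # contributes to strength
        assert dominant_factor(m, pair=(1, 2), factor="band") == "beta"

    def test_vertex_dominance_sums_over_incident_pairs(self):
        recs = [
            _rec(5.0, 1, 2, band1="alpha", band2="alpha"),
            _rec(3.0, 1, 3, band1="beta", band2="beta"),
        ]
        m = accumulate_strengths(recs, n_roi=3)
        assert dominant_factor(m, vertex=1, factor="band") == "alpha"


class TestGraph:
    @pytest.fixture
    def strengths(self):
        return accumulate_strengths(
            [_rec(150.0, 1, 2), _rec(90.0, 2, 3), _rec(30.0, 3, 4)], n_roi=4
        )

    def test_edges_require_strength_above_threshold(self, strengths):
        G = build_graph(strengths, threshold=100.0)
        assert set(G.edges) == {(1, 2)}
        assert G[1][2]["weight"] == 150.0
        assert G.number_of_nodes() == 4

    def test_infinite_threshold_empty_graph(self, strengths):
        assert build_graph(strengths, threshold=math.inf).number_of_edges() == 0

    def test_zero_threshold_connects_all_positive_pairs(self, strengths):
        G = build_graph(strengths, threshold=0.0)
        assert set(G.edges) == {(1, 2), (2, 3), (3, 4)}

    def test_edge_count_monotone_in_threshold(self, strengths):
        counts = [
            build_graph(strengths, threshold=t).number_of_edges()
            for t in (0, 25, 80, 120, 1000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_vertex_sum_mode(self, strengths):
        # vertex strengths: 150, 240, 120, 30; edge iff endpoint sums exceed
        G = build_graph(strengths, threshold=300.0, mode="vertex_sum")
        assert set(G.edges) == {(1, 2), (2, 3)}


def oracle_centralities(G):
    """Dense electrical solve: closeness = 1 / sum of effective
    resistances; betweenness = pairwise current throughput (endpoints
    excluded) over (n-1)(n-2)/2."""
    nodes = list(G)
    n = len(nodes)
    W = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    L = np.diag(W.sum(1)) - W
    Tp = np.linalg.pinv(L)
    Reff = np.diag(Tp)[:, None] + np.diag(Tp)[None, :] - 2 * Tp
    close = 1.0 / Reff.sum(1)
    btw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            b = np.zeros(n)
            b[s], b[t] = 1.0, -1.0
            v = Tp @ b
            thr = 0.5 * (np.abs(v[:, None] - v[None, :]) * W).sum(1)
            thr[s] = thr[t] = 0.0
            btw += thr
    if n > 2:
        btw /= (n - 1) * (n - 2) / 2
    return dict(zip(nodes, close)), dict(zip(nodes, btw))


class TestCentralities:
    def test_path_graph_betweenness(self):
        m = accumulate_strengths(
            [_rec(10.0, 1, 2), _rec(10.0, 2, 3)], n_roi=3
        )
        scores = current_flow_centralities(build_graph(m, threshold=0.0))
        assert scores.betweenness[2] == pytest.approx(1.0)
        assert scores.betweenness[1] == pytest.approx(0.0, abs=1e-9)
        assert scores.betweenness[3] == pytest.approx(0.0, abs=1e-9)

    def test_triangle_symmetry(self):
        m = accumulate_strengths(
            [_rec(5.0, 1, 2), _rec(5.0, 2, 3), _rec(5.0, 1, 3)], n_roi=3
        )
        s = current_flow_centralities(build_graph(m, threshold=0.0))
        assert len({round(v, 12) for v in s.closeness.values()}) == 1
        assert len({round(v, 12) for v in s.betweenness.values()}) == 1

    def test_random_weighted_graph_matches_oracle(self):
        rng = np.random.default_rng(8)
        G = nx.gnp_random_graph(6, 0.8, seed=4)
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0.5, 5.0))
        assert nx.is_connected(G)
        scores = current_flow_centralities(G)
        close, btw = oracle_centralities(G)
        for v in G:
            assert scores.closeness[v] == pytest.approx(close[v], rel=1e-8)
            assert scores.betweenness[v] == pytest.approx(btw[v], abs=1e-8)

    def test_singleton_component_undefined(self):
        m = accumulate_strengths([_rec(10.0, 1, 2)], n_roi=3)
        scores = current_flow_centralities(build_graph(m, threshold=0.0))
        assert math.isnan(scores.closeness[3])
        assert math.isnan(scores.betweenness[3])
        assert scores.betweenness[1] == 0.0  # 2-vertex component convention

    def test_betweenness_bounded_unit_interval(self):
        rng = np.random.default_rng(3)
        G = nx.gnp_random_graph(7, 0.6, seed=9)
        for u, v in G.edges:
            G[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        scores = current_flow_centralities(G)
        vals = [v for v in scores.betweenness.values() if not math.isnan(v)]
        assert all(-1e-9 <= v <= 1 + 1e-9 for v in vals)

    def test_centrality_table_shape(self):
        m = accumulate_strengths(
            [_rec(10.0, 1, 2), _rec(8.0, 2, 3), _rec(6.0, 1, 3),
             _rec(2.0, 3, 4)],
            n_roi=4,
        )
        scores = current_flow_centralities(build_graph(m, threshold=0.0))
        table = centrality_table(scores, top=3)
        assert list(table.columns) == ["roi_id", "name", "closeness",
                                       "betweenness"]
        assert len(table) >= 3
        assert table["name"].iloc[0].split()[-1] in ("L", "R")
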