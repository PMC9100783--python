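"""Continuous chi-squared scoring: the worked example, its invariances,
exact top-k selection against a brute-force oracle, and the streaming
engine's consistency across its two surfaces."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurosym.augment import product_stream, stage1_features, universe_size
from neurosym.scoring import (
    chi_square,
    chi_square_components,
    materialize_positions,
    nonneg_calibrate,
    scan_universe,
    score_all_for_strength,
    select_top_k,
)
from tests.conftest import make_cohort


class TestChiSquare:
    def test_worked_example(self):
        """Three subjects with values (30, 20, 40) and labels (1, 0, 1)
        score exactly 5."""
        assert chi_square(np.array([30.0, 20.0, 40.0]), np.array([1, 0, 1])) == (
            pytest.approx(5.0)
        )

    def test_worked_example_expected_sums(self):
        c = chi_square_components(
            np.array([30.0, 20.0, 40.0]), np.array([1, 0, 1])
        )
        assert c["S_e0"] == 20.0
        assert c["S_e1"] == 70.0
        assert c["E_e0"] == pytest.approx(30.0)
        assert c["E_e1"] == pytest.approx(60.0)

    def test_doubled_values_double_the_score(self):
        assert chi_square(
            np.array([60.0, 40.0, 80.0]), np.array([1, 0, 1])
        ) == pytest.approx(10.0)

    def test_constant_values_score_zero(self):
        assert chi_square(np.full(6, 3.0), np.array([0, 1, 0, 1, 1, 0])) == 0.0

    def test_all_zero_values_score_zero(self):
        assert chi_square(np.zeros(4), np.array([0, 1, 0, 1])) == 0.0

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            chi_square(np.array([-1.0, 2.0]), np.array([0, 1]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            chi_square(np.array([1.0, 2.0]), np.array([1, 1]))

    @given(
        st.lists(st.floats(0, 100), min_size=4, max_size=12),
        st.floats(0.01, 50),
        st.randoms(use_true_random=False),
    )
    def test_scale_linearity_and_order_invariance(self, vals, a, rnd):
        x = np.array(vals)
        y = np.array([0, 1] * (len(vals) // 2) + [0] * (len(vals) % 2))
        base = chi_square(x, y)
        assert chi_square(a * x, y) == pytest.approx(a * base, rel=1e-9)
        perm = np.array(rnd.sample(range(len(x)), len(x)))
        assert chi_square(x[perm], y[perm]) == pytest.approx(base, rel=1e-9)

    def test_class_sums_are_additive(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        y = np.array([0, 1, 1, 0])
        c = chi_square_components(x, y)
        assert c["S_e0"] + c["S_e1"] == pytest.approx(x.sum())


class TestNonnegCalibrate:
    def test_min_max_rescale(self):
        np.testing.assert_allclose(
            nonneg_calibrate(np.array([-2.0, 0.0, 2.0])), [0.0, 0.5, 1.0]
        )

    def test_passthrough_for_nonnegative(self):
        x = np.array([30.0, 20.0, 40.0])
        np.testing.assert_array_equal(
            nonneg_calibrate(x, passthrough_nonnegative=True), x
        )

    def test_constant_maps_to_zero(self):
        np.testing.assert_array_equal(
            nonneg_calibrate(np.full(3, 5.0)), np.zeros(3)
        )


def _brute_force_records(stage1, labels, nonneg="auto"):
    """Materialize and score the whole universe the slow, obvious way."""
    out = []
    pos = 0
    for block in product_stream(stage1, 1_000_000):
        for c in range(block.width):
            col = block.values[:, c]
            plain = (
                nonneg_calibrate(col) if col.min() < 0 else col
            )
            out.append((chi_square(plain, labels), pos))
            pos += 1
            mn, mx = col.min(), col.max()
            logv = (
                np.zeros_like(col)
                if mx == mn
                else np.log1p((col - mn) / (mx - mn))
            )
            out.append((chi_square(logv, labels), pos))
            pos += 1
    return out


@pytest.fixture(scope="module")
def toy(toy_cohort):
    stage1 = stage1_features(toy_cohort)
    return stage1, toy_cohort.label_vector("anxiety")


class TestSelectTopK:

    @pytest.mark.parametrize("k", [1, 10, 137])
    def test_equals_brute_force_sort(self, toy, k):
        stage1, y = toy
        records = _brute_force_records(stage1, y)
        expected = sorted(records, key=lambda e: (-e[0], e[1]))[:k]
        sel = select_top_k(lambda: product_stream(stage1, 61), y, k=k)
        got = [(r.chi2, r.position) for r in sel.records]
        np.testing.assert_allclose(
            [g[0] for g in got], [e[0] for e in expected], rtol=1e-9
        )
        assert [g[1] for g in got] == [e[1] for e in expected]

    def test_saturation_returns_everything_sorted(self, tiny_cohort):
        stage1 = stage1_features(tiny_cohort)
        y = tiny_cohort.label_vector("anxiety")
        total = universe_size(len(stage1.descriptors))
        sel = select_top_k(
            lambda: product_stream(stage1, 50), y, k=total + 1000
        )
        assert len(sel.records) == total
        chis = [r.chi2 for r in sel.records]
        assert chis == sorted(chis, reverse=True)

    def test_tie_break_prefers_earlier_stream_position(self):
        # two identical columns -> identical chi2; the earlier wins rank 1
        vals = np.zeros((4, 1, 1, 1))
        vals[:, 0, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        ds = make_cohort(vals, bands=("theta",), tasks=(1,))
        stage1 = stage1_features(ds)
        y = ds.label_vector("anxiety")
        sel = select_top_k([stage1], y, k=5)
        positions = [r.position for r in sel.records]
        chis = np.array([r.chi2 for r in sel.records])
        for i in range(len(chis) - 1):
            if chis[i] == chis[i + 1]:
                assert positions[i] < positions[i + 1]

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_top_k([], np.array([0, 1]), k=3)

    def test_materialized_values_match_descriptors(self, toy):
        stage1, y = toy
        sel = select_top_k(lambda: product_stream(stage1, 61), y, k=20)
        assert sel.values.shape == (len(y), 20)
        frame = sel.to_frame()
        assert list(frame.columns) == ["rank", "chi2", "feature"]
        assert frame["rank"].tolist() == list(range(1, 21))


class TestScanUniverse:
    def test_matches_descriptor_surface(self, toy_cohort):
        stage1 = stage1_features(toy_cohort)
        y = toy_cohort.label_vector("anxiety")
        sel = select_top_k(lambda: product_stream(stage1, 61), y, k=40)
        (chi, pos), = scan_universe(stage1.values, y, k=40, block_size=61)
        np.testing.assert_allclose(chi, [r.chi2 for r in sel.records], rtol=1e-9)
        assert pos.tolist() == [r.position for r in sel.records]
        X = materialize_positions(stage1.values, pos)
        np.testing.assert_allclose(X, sel.values, rtol=1e-9)

    def test_block_size_does_not_change_result(self, tiny_cohort):
        """Blocking only regroups float summation; up to roundoff-level tie
        reordering the saturated ranking is identical."""
        stage1 = stage1_features(tiny_cohort)
        y = tiny_cohort.label_vector("anxiety")
        k = universe_size(len(stage1.descriptors))

        def canon(res):
            chi, pos = res
            groups = {}
            for c, p in zip(np.round(chi, 9), pos):
                groups.setdefault(float(c), set()).add(int(p))
            return groups

        ref = canon(scan_universe(stage1.values, y, k=k, block_size=7)[0])
        for bs in (1, 13, 10_000):
            got = canon(scan_universe(stage1.values, y, k=k, block_size=bs)[0])
            assert got == ref

    def test_multi_label_scan_equals_individual_scans(self, tiny_cohort):
        stage1 = stage1_features(tiny_cohort)
        y = tiny_cohort.label_vector("anxiety")
        k = universe_size(len(stage1.descriptors))
        rng = np.random.default_rng(0)
        Y = np.column_stack([y[rng.permutation(len(y))] for _ in range(4)])

        def canon(res):
            chi, pos = res
            groups = {}
            for c, p in zip(np.round(chi, 9), pos):
                groups.setdefault(float(c), set()).add(int(p))
            return groups

        multi = scan_universe(stage1.values, Y, k=k, block_size=19)
        for c in range(4):
            single = scan_universe(
                stage1.values, Y[:, c], k=k, block_size=19
            )[0]
            assert canon(multi[c]) == canon(single)

    def test_row_subset_scores_only_those_rows(self, toy_cohort):
        stage1 = stage1_features(toy_cohort)
        y = toy_cohort.label_vector("anxiety")
        rows = np.zeros(len(y), dtype=bool)
        rows[:20] = True
        sub = scan_universe(stage1.values, y, k=15, rows=rows, block_size=61)[0]
        direct = scan_universe(
            stage1.values[rows], y[rows], k=15, block_size=61
        )[0]
        np.testing.assert_allclose(sub[0], direct[0])
        np.testing.assert_array_equal(sub[1], direct[1])


class TestScoreAllForStrength:
    def test_emits_every_feature_once(self):
        ds = make_cohort(
            np.random.default_rng(5).standard_normal((6, 1, 1, 1)),
            bands=("theta",),
            tasks=(1,),
        )
        stage1 = stage1_features(ds)
        records = []
        n = score_all_for_strength(
            lambda: product_stream(stage1, 7),
            ds.label_vector("anxiety"),
            records.append,
        )
        assert n == len(records) == universe_size(len(stage1.descriptors)) == 506

    def test_records_match_brute_force(self, tiny_cohort):
        stage1 = stage1_features(tiny_cohort)
        y = tiny_cohort.label_vector("anxiety")
        records = []
        score_all_for_strength(
            lambda: product_stream(stage1, 23), y, records.append
        )
        brute = _brute_force_records(stage1, y)
        assert len(records) == len(brute)
        np.testing.assert_allclose(
            [r.chi2 for r in records], [b[0] for b in brute], rtol=1e-9
        )
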