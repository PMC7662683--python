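"""Frame transform, design matrices, splits and session I/O."""

import numpy as np
import pytest
from scipy import stats

from copgait.dataset import (
    ChannelSpec,
    build_design_matrix,
    build_windows,
    cop_to_pelvis_frame,
    read_session_csv,
    sample_contiguous_train,
    split_train_test,
    write_session_csv,
)
from copgait.series import CopSeries
from copgait.synthetic import GaitParams, ProtocolStep, simulate_session


class TestCopToPelvisFrame:
    def test_pelvis_at_origin_is_identity(self):
        t = np.arange(5) * 0.01
        cop = CopSeries(t=t, x=np.arange(5.0), y=-np.arange(5.0), frame="treadmill")
        out = cop_to_pelvis_frame(cop, np.zeros((5, 2)))
        np.testing.assert_array_equal(out.x, cop.x)
        np.testing.assert_array_equal(out.y, cop.y)
        assert out.frame == "pelvis"

    def test_translation_arithmetic(self):
        t = np.array([0.0])
        cop = CopSeries(t=t, x=[120.0], y=[40.0], frame="treadmill")
        out = cop_to_pelvis_frame(cop, np.array([[100.0, 50.0]]))
        assert (out.x[0], out.y[0]) == (20.0, -10.0)

    def test_sinusoidal_sway_is_negated(self):
        t = np.arange(100) * 0.01
        sway = 10 * np.sin(2 * np.pi * t)
        cop = CopSeries(t=t, x=np.full(100, 5.0), y=np.zeros(100), frame="treadmill")
        out = cop_to_pelvis_frame(cop, np.column_stack([sway, sway]))
        np.testing.assert_allclose(out.x, 5.0 - sway, atol=1e-12)
        np.testing.assert_allclose(out.y, -sway, atol=1e-12)

    def test_double_transform_rejected(self):
        t = np.array([0.0])
        cop = CopSeries(t=t, x=[1.0], y=[1.0], frame="pelvis")
        with pytest.raises(ValueError, match="already"):
            cop_to_pelvis_frame(cop, np.zeros((1, 2)))

    def test_length_mismatch_rejected(self):
        t = np.arange(3) * 0.01
        cop = CopSeries(t=t, x=np.zeros(3), y=np.zeros(3), frame="treadmill")
        with pytest.raises(ValueError, match="shape"):
            cop_to_pelvis_frame(cop, np.zeros((4, 2)))


class TestChannelSpec:
    @pytest.mark.parametrize(
        "components,imus,history,expected",
        [
            (("G", "A", "M"), tuple(range(2, 9)), 1, 63),
            (("G", "A"), tuple(range(2, 9)), 10, 420),
            (("G",), (2,), 1, 3),
        ],
    )
    def test_feature_counts(self, components, imus, history, expected):
        assert ChannelSpec(components, imus, history).n_features == expected

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            ChannelSpec(components=())
        with pytest.raises(ValueError):
            ChannelSpec(imus=())
        with pytest.raises(ValueError):
            ChannelSpec(history=0)


class TestDesignMatrix:
    def test_shapes_and_row_drop(self, walk_session):
        X, Y = build_design_matrix(walk_session, ChannelSpec(history=10))
        assert X.shape == (walk_session.n_samples - 9, 630)
        assert Y.shape == (walk_session.n_samples - 9, 2)
        X1, Y1 = build_design_matrix(walk_session, ChannelSpec(history=1))
        assert X1.shape == (walk_session.n_samples, 63)

    def test_subset_selects_matching_columns(self, walk_session):
        """IMU/component subsets are exactly column subsets of the full matrix."""
        full_spec = ChannelSpec(history=2)
        X_full, _ = build_design_matrix(walk_session, full_spec)
        sub_spec = ChannelSpec(imus=(3, 7), history=2)
        X_sub, _ = build_design_matrix(walk_session, sub_spec)
        # per-IMU block width = 9 channels × 2 lags
        blocks = {loc: i for i, loc in enumerate(full_spec.imus)}
        cols = np.concatenate(
            [np.arange(18) + 18 * blocks[loc] for loc in (3, 7)]
        )
        np.testing.assert_array_equal(X_sub, X_full[:, cols])

    def test_lag_ordering_newest_first(self, walk_session):
        spec = ChannelSpec(components=("G",), imus=(2,), history=3)
        X, Y = build_design_matrix(walk_session, spec)
        g = walk_session.imu[2].g
        k = 10  # row k corresponds to sample k + history − 1
        np.testing.assert_allclose(X[k, 0:3], [g[k + 2, 0], g[k + 1, 0], g[k, 0]])

    def test_windows_do_not_cross_step_boundaries(self, mixed_session):
        h = 10
        W, Y = build_windows(mixed_session, ChannelSpec(history=h))
        runs = mixed_session.step_runs()
        expected = sum((sl.stop - sl.start) - h + 1 for _, sl in runs)
        assert W.shape[0] == expected

    def test_treadmill_frame_rejected(self, walk_session):
        bad = walk_session.take(np.arange(100))
        bad.cop.frame = "treadmill"
        with pytest.raises(ValueError, match="pelvis"):
            build_design_matrix(bad, ChannelSpec())


class TestSplits:
    def test_half_split_arithmetic(self, mixed_session):
        train, test = split_train_test(mixed_session, 0.5)
        expected_train = sum(
            (sl.stop - sl.start) // 2 for _, sl in mixed_session.step_runs()
        )
        assert train.n_samples == expected_train
        assert train.n_samples + test.n_samples == mixed_session.n_samples
        # per-step: train indices precede test indices within every step
        for sid, sl in mixed_session.step_runs():
            tr_t = train.t[train.step_labels == sid]
            te_t = test.t[test.step_labels == sid]
            assert tr_t.max() < te_t.min()

    def test_extreme_fraction_keeps_test_nonempty(self, mixed_session):
        train, test = split_train_test(mixed_session, 0.999)
        assert test.n_samples >= len(mixed_session.step_runs())

    def test_short_step_rejected(self, walk_session):
        tiny = walk_session.take(np.arange(1))
        with pytest.raises(ValueError):
            split_train_test(tiny, 0.5)

    def test_contiguous_block_determinism_and_bounds(self, walk_session):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        tr1, te1 = sample_contiguous_train(walk_session, 10.0, rng1)
        tr2, te2 = sample_contiguous_train(walk_session, 10.0, rng2)
        np.testing.assert_array_equal(tr1.t, tr2.t)
        assert tr1.n_samples == 1000
        assert te1.n_samples == walk_session.n_samples - 1000
        with pytest.raises(ValueError, match="non-empty test"):
            sample_contiguous_train(walk_session, walk_session.duration_s, rng1)

    def test_block_starts_uniform(self):
        session = simulate_session(
            GaitParams(seed=4), [ProtocolStep(0.5, 0, 6.0, "walk")]
        )
        rng = np.random.default_rng(11)
        starts = []
        for _ in range(500):
            train, _ = sample_contiguous_train(session, 1.0, rng)
            starts.append(train.t[0])
        hi = session.duration_s - 1.0
        ks = stats.kstest(np.array(starts) / hi, "uniform")
        assert ks.pvalue > 0.01


def test_session_csv_round_trip_is_bit_exact(tmp_path, mixed_session):
    path = tmp_path / "session.csv"
    write_session_csv(path, mixed_session)
    back = read_session_csv(path)
    np.testing.assert_array_equal(back.t, mixed_session.t)
    np.testing.assert_array_equal(back.step_labels, mixed_session.step_labels)
    np.testing.assert_array_equal(back.cop.x, mixed_session.cop.x)
    np.testing.assert_array_equal(back.pelvis, mixed_session.pelvis)
    for loc in mixed_session.imu:
        np.testing.assert_array_equal(
            back.imu[loc].as_matrix(), mixed_session.imu[loc].as_matrix()
        )
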