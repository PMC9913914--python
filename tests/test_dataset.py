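"""Feature assembly, windowing arithmetic, splits and standardisation."""

import numpy as np
import pytest

from glucoforecast import (
    FeatureConfig,
    ValidationError,
    WindowSpec,
    apply_standardizer,
    assemble_feature_matrix,
    fit_standardizer,
    holdout_split,
    invert_standardizer,
    make_windows,
    operative_carbs_series,
    rolling_origin_splits,
)


class TestFeatureConfig:
    @pytest.mark.parametrize("name, channels", [
        ("C-01", ("cgm",)),
        ("C-02", ("cgm", "operative_carbs")),
        ("C-03", ("cgm", "operative_carbs", "active_insulin")),
    ])
    def test_presets(self, name, channels):
        assert FeatureConfig(name).channels == channels

    def test_unknown_name_rejected(self):
        with pytest.raises(ValidationError):
            FeatureConfig("C-99")

    def test_wrong_channels_rejected(self):
        with pytest.raises(ValidationError):
            FeatureConfig("C-01", ("cgm", "active_insulin"))


class TestAssembleFeatureMatrix:
    def test_univariate_equals_cgm(self, clean_record):
        matrix, target = assemble_feature_matrix(clean_record,
                                                 FeatureConfig("C-01"))
        assert matrix.shape == (clean_record.train_cgm.grid.n_samples, 1)
        assert np.array_equal(matrix[:, 0], clean_record.train_cgm.values)
        assert target is clean_record.train_cgm

    def test_carbs_channel_matches_recomputation(self, clean_record):
        matrix, _ = assemble_feature_matrix(clean_record, FeatureConfig("C-02"))
        expected = operative_carbs_series(clean_record.meals,
                                          clean_record.train_cgm.grid)
        assert np.allclose(matrix[:, 1], expected.values)

    def test_no_events_gives_zero_channels(self, clean_record):
        from glucoforecast import EventSeries
        bare = clean_record.with_(meals=EventSeries.empty("meal"),
                                  boluses=EventSeries.empty("bolus"))
        matrix, _ = assemble_feature_matrix(bare, FeatureConfig("C-03"))
        assert np.all(matrix[:, 1:] == 0)

    def test_unpreprocessed_record_rejected(self, small_record):
        with pytest.raises(ValidationError, match="impute"):
            assemble_feature_matrix(small_record, FeatureConfig("C-01"))


class TestMakeWindows:
    def test_training_block_arithmetic(self):
        """9288 rows at history 6, stride 6 yield 1548 examples."""
        n = 9288
        x, y, m = make_windows(np.arange(n, dtype=float),
                               np.arange(n, dtype=float), WindowSpec(6, 6))
        assert x.shape == (1548, 6, 1)
        assert y.shape == (1548, 6)

    def test_test_block_arithmetic(self):
        """2322 rows at history 6, stride 6 yield 387 walk-forward examples."""
        n = 2322
        x, _, m = make_windows(np.arange(n, dtype=float),
                               np.arange(n, dtype=float), WindowSpec(6, 6))
        assert x.shape == (387, 6, 1)
        # the final window's targets run past the series end and are masked
        assert not m[-1].any()

    def test_strict_tail_requires_full_horizon(self):
        x, y, _ = make_windows(np.arange(13.0), np.arange(13.0),
                               WindowSpec(6, 6), tail="strict")
        assert x.shape == (1, 6, 1)
        assert np.array_equal(y[0], np.arange(6.0, 12.0))

    def test_offsets_partition_rows_with_stride_eq_history(self):
        n, h = 60, 6
        x, y, _ = make_windows(np.arange(n, dtype=float),
                               np.arange(n, dtype=float),
                               WindowSpec(h, h), tail="strict")
        # inputs tile the prefix: row r appears in input slot (r//h, r%h)
        flat = x[:, :, 0].ravel()
        assert np.array_equal(flat, np.arange(len(x) * h, dtype=float))
        # each output block is the next input block
        assert np.array_equal(y[0], x[1, :, 0])

    def test_target_follows_history_immediately(self):
        x, y, _ = make_windows(np.arange(30.0), np.arange(30.0),
                               WindowSpec(6, 6, stride=1), tail="strict")
        for i in range(len(x)):
            assert y[i, 0] == x[i, -1, 0] + 1

    def test_imputed_targets_masked(self):
        from glucoforecast import Provenance
        prov = np.zeros(24, dtype=np.int8)
        prov[8] = Provenance.IMPUTED
        _, _, m = make_windows(np.arange(24.0), np.arange(24.0),
                               WindowSpec(6, 6), target_provenance=prov)
        assert not m[0, 2]          # row 8 = example 0, horizon step 2
        assert m.sum() == m.size - 1 - 6  # plus the masked final tail

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            make_windows(np.arange(5.0), np.arange(5.0), WindowSpec(6, 6))


class TestRollingOriginSplits:
    def test_study_scale_sizes(self):
        plan = rolling_origin_splits(11_611, 5)
        assert plan.val_size == 1935
        assert plan.train_sizes == (1936, 3871, 5806, 7741, 9676)

    def test_tiny_case_brute_force(self):
        plan = rolling_origin_splits(12, 2)
        assert plan.val_size == 4
        assert plan.train_sizes == (4, 8)

    @pytest.mark.parametrize("n, k", [(100, 5), (11_611, 5), (37, 3)])
    def test_telescoping_and_nesting(self, n, k):
        plan = rolling_origin_splits(n, k)
        for i in range(k - 1):
            assert plan.train_sizes[i] + plan.val_size == plan.train_sizes[i + 1]
        # successive training sets are supersets; validation follows training
        for i in range(k):
            tr, va = plan.split_indices(i)
            assert va[0] == tr[-1] + 1
            assert len(va) == plan.val_size

    def test_validation_blocks_stay_inside_series(self):
        plan = rolling_origin_splits(101, 4)
        tr, va = plan.split_indices(plan.k - 1)
        assert va[-1] < plan.n_total

    def test_too_small_series_rejected(self):
        with pytest.raises(ValidationError):
            rolling_origin_splits(4, 5)

    def test_no_window_bridges_train_validation_boundary(self):
        """Windows built per block never straddle the split boundary."""
        plan = rolling_origin_splits(120, 3)
        series = np.arange(120.0)
        spec = WindowSpec(6, 6)
        for i in range(plan.k):
            tr, va = plan.split_indices(i)
            x, y, _ = make_windows(series[tr], series[tr], spec, tail="strict")
            assert x.max() < tr[-1] + 1  # all inputs inside the training block
            assert y.max() <= tr[-1]


class TestStandardizer:
    def test_training_matrix_becomes_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        m = rng.normal([10, -4], [3, 0.5], size=(500, 2))
        state = fit_standardizer(m)
        z = apply_standardizer(state, m)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1, atol=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        m = rng.normal(100, 20, size=(200, 1))
        state = fit_standardizer(m)
        z = apply_standardizer(state, m)
        back = invert_standardizer(state, z[:, 0], channel=0)
        assert np.allclose(back, m[:, 0], atol=1e-9)

    def test_shifted_validation_mean_nonzero(self):
        rng = np.random.default_rng(2)
        train = rng.normal(100, 10, size=(300, 1))
        val = rng.normal(140, 10, size=(300, 1))  # regime shift
        state = fit_standardizer(train)
        z_val = apply_standardizer(state, val)
        assert abs(z_val.mean()) > 1.0

    def test_zero_variance_channel_rejected(self):
        m = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        with pytest.raises(ValidationError, match="variance"):
            fit_standardizer(m)

    def test_leakage_guard_fit_excludes_validation_rows(self):
        series = np.concatenate([np.arange(80.0), np.full(20, 1000.0)])[:, None]
        tr, va = holdout_split(100, 0.8)
        state = fit_standardizer(series[tr])
        assert state.mean[0] == np.arange(80.0).mean()  # val regime never seen
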