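"""Decoding engine: balancing, CV assignment, scoring, full subject runs."""

import numpy as np
import pytest

from eegdecode import (
    DecodingConfig,
    EpochedDataset,
    PatternMatrix,
    SubjectDecoder,
    SyntheticSpec,
    assign_cv_sets,
    balance_trials,
    block_average,
    cross_condition_decode,
    extract_patterns,
    fisher_z,
    generate_svr_dataset,
    generate_two_condition_dataset,
    pool_blocks,
    train_and_test,
)
from eegdecode.decoding import DecodingResult
from eegdecode.errors import ConfigurationError, DataError

from conftest import make_dataset


class StubFirstClass:
    """Backend stub that always predicts the first (lowest) class label."""

    n_fits = 0

    def fit(self, X, y):
        type(self).n_fits += 1
        self.first = np.min(y)
        return self

    def predict(self, X):
        return np.full(X.shape[0], self.first)


def _pm(vectors, labels):
    vectors = np.asarray(vectors, dtype=float)
    layout = tuple((i + 1, None) for i in range(vectors.shape[1]))
    return PatternMatrix(vectors=vectors, labels=np.asarray(labels),
                         feature_layout=layout)


class TestBalancing:
    @pytest.mark.parametrize(
        "counts,expected",
        [((30, 24), 24), ((50, 50), 50), ((40, 30, 20), 20)],
    )
    def test_min_rule(self, counts, expected, rng):
        pats = {
            c + 1: np.arange(n * 2, dtype=float).reshape(n, 2)
            for c, n in enumerate(counts)
        }
        out = balance_trials(pats, rng)
        assert all(v.shape[0] == expected for v in out.values())

    def test_already_balanced_unchanged(self, rng):
        pats = {1: np.ones((5, 2)), 2: np.zeros((5, 2))}
        out = balance_trials(pats, rng)
        np.testing.assert_array_equal(out[1], pats[1])

    def test_subsample_rows_come_from_source(self, rng):
        pats = {1: np.arange(20.0).reshape(10, 2), 2: np.zeros((4, 2))}
        out = balance_trials(pats, rng)
        src = {tuple(row) for row in pats[1]}
        assert all(tuple(row) in src for row in out[1])

    def test_empty_condition(self, rng):
        with pytest.raises(DataError):
            balance_trials({1: np.zeros((0, 2)), 2: np.ones((3, 2))}, rng)


class TestBlockAveragingAndPooling:
    def test_one_exemplar_per_run(self):
        ds = make_dataset(n_runs=4, n_conds=1, T=6, C=2, n_trials=5, seed=1)
        pat = extract_patterns(ds, 0, 6, "spatial")[1]
        avg = block_average(pat)
        assert avg.vectors.shape == (4, 2)
        expected = pat.vectors[pat.runs == 2].mean(axis=0)
        np.testing.assert_allclose(avg.vectors[1], expected)

    def test_single_trial_runs_identity(self):
        ds = make_dataset(n_runs=3, n_conds=1, n_trials=1, seed=2)
        pat = extract_patterns(ds, 0, 4, "spatial")[1]
        avg = block_average(pat)
        np.testing.assert_allclose(avg.vectors, pat.vectors)

    def test_constant_trials_average_to_constant(self):
        ds = EpochedDataset(data={(1, 1): np.full((6, 2, 8), 1.5)})
        avg = block_average(extract_patterns(ds, 0, 6, "spatial")[1])
        np.testing.assert_allclose(avg.vectors, 1.5)

    def test_pooling_keeps_all_trials_in_run_order(self):
        ds = make_dataset(n_runs=2, n_conds=1, n_trials=3, seed=3)
        pat = pool_blocks(extract_patterns(ds, 0, 4, "spatial")[1])
        assert pat.n_exemplars == 6
        np.testing.assert_array_equal(pat.runs, [1, 1, 1, 2, 2, 2])


class TestCvAssignment:
    @pytest.mark.parametrize(
        "n,k,per_set,n_excluded",
        [(95, 10, 9, 5), (100, 10, 10, 0), (10, 10, 1, 0), (11, 2, 5, 1)],
    )
    def test_floor_mod_arithmetic(self, n, k, per_set, n_excluded, rng):
        a = assign_cv_sets(n, k, rng)
        assert a.sets.shape == (k, per_set)
        assert a.excluded.size == n_excluded
        # partition: no index twice, sets + excluded cover everything
        all_idx = np.concatenate([a.sets.ravel(), a.excluded])
        assert np.array_equal(np.sort(all_idx), np.arange(n))

    def test_too_few_exemplars(self, rng):
        with pytest.raises(ConfigurationError, match="smaller k"):
            assign_cv_sets(5, 10, rng)


class TestTrainAndTest:
    def test_perfectly_separable(self):
        rng = np.random.default_rng(0)
        train = _pm(
            np.vstack([rng.normal(-10, 0.1, (20, 3)),
                       rng.normal(10, 0.1, (20, 3))]),
            np.repeat([0, 1], 20),
        )
        test = _pm(
            np.vstack([rng.normal(-10, 0.1, (10, 3)),
                       rng.normal(10, 0.1, (10, 3))]),
            np.repeat([0, 1], 10),
        )
        score, w = train_and_test(train, test, DecodingConfig())
        assert score == 100.0
        assert w is not None and w.shape == (3,)

    def test_uninformative_labels_near_chance(self):
        # labels independent of the data: accuracy ~50% for 2 balanced classes
        rng = np.random.default_rng(1)
        accs = []
        for rep in range(30):
            X = rng.normal(size=(80, 4))
            y = np.repeat([0, 1], 40)
            train = _pm(X[::2], y[::2])
            test = _pm(X[1::2], y[1::2])
            score, _ = train_and_test(test, train, DecodingConfig())
            accs.append(score)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50.0) < 3 * se + 1e-9

    def test_regression_perfect_prediction_capped(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - 1e-12))
        rng = np.random.default_rng(2)
        y = rng.uniform(-1, 1, 40)
        X = np.column_stack([y, y])  # labels perfectly encoded
        cfg = DecodingConfig(
            analysis_type="regression", discrimination_groups=[(1,)]
        )
        score, _ = train_and_test(_pm(X, y), _pm(X, y), cfg)
        assert score > 2.0  # Fisher-Z of r ~ 1, finite

    def test_regression_constant_prediction_scores_zero(self):
        cfg = DecodingConfig(
            analysis_type="regression", discrimination_groups=[(1,)]
        )
        rng = np.random.default_rng(3)
        # constant training labels force a constant predictor
        train = _pm(rng.normal(size=(20, 3)), np.zeros(20))
        test = _pm(rng.normal(size=(10, 3)), rng.uniform(size=10))
        score, _ = train_and_test(train, test, cfg)
        assert score == 0.0

    def test_stub_backend_scoring_oracle(self):
        # predict-first-class stub: accuracy must equal 100 x class share
        cfg = DecodingConfig(backend_factory=lambda c: StubFirstClass())
        rng = np.random.default_rng(4)
        train = _pm(rng.normal(size=(30, 2)), np.repeat([0, 1, 2], 10))
        test = _pm(rng.normal(size=(12, 2)), np.array([0] * 3 + [1] * 4 + [2] * 5))
        score, w = train_and_test(train, test, cfg)
        assert score == pytest.approx(100 * 3 / 12)
        assert w is None


class TestSubjectDecoder:
    def test_analysis_count_and_mean_identity(self, tiny_spec, tiny_config):
        ds = generate_two_condition_dataset(tiny_spec)
        res = SubjectDecoder(ds, tiny_config).fit()
        k, m = tiny_config.k_folds, tiny_config.m_repetitions
        assert res.per_analysis.shape == (4, m, k)
        np.testing.assert_array_equal(
            res.accuracy, res.per_analysis.reshape(4, -1).mean(axis=1)
        )
        assert np.all((res.per_analysis >= 0) & (res.per_analysis <= 100))

    def test_signal_windows_decode_noise_windows_do_not(self, tiny_spec,
                                                        tiny_config):
        ds = generate_two_condition_dataset(tiny_spec)  # signal 1.0, t 11-20
        res = SubjectDecoder(ds, tiny_config).fit()
        assert res.accuracy[:2].mean() < 70
        assert res.accuracy[2:].mean() > 85

    def test_determinism_under_fixed_seed(self, tiny_spec, tiny_config):
        ds = generate_two_condition_dataset(tiny_spec)
        cfg = tiny_config.replace(permute_labels=True)
        r1 = SubjectDecoder(ds, cfg).fit()
        r2 = SubjectDecoder(ds, cfg).fit()
        np.testing.assert_array_equal(r1.per_analysis, r2.per_analysis)
        np.testing.assert_array_equal(
            r1.permuted_per_analysis, r2.permuted_per_analysis
        )

    def test_permuted_labels_hover_at_chance(self):
        # enough trials that the small-sample below-chance bias of permuted
        # cross-validation is negligible against the Monte-Carlo error
        spec = SyntheticSpec(
            n_timepoints=80, n_channels=6, n_epochs=300, signal_value=0.0,
            signal_channels=(1,), signal_timepoints=(1, 80), rng_seed=31,
        )
        ds = generate_two_condition_dataset(spec)
        cfg = DecodingConfig(
            window_width_ms=10, step_ms=10, k_folds=3, m_repetitions=1,
            permute_labels=True, rng_seed=21,
        )
        res = SubjectDecoder(ds, cfg).fit()
        # windows are computed on independent data -> use them as MC units
        w_means = res.permuted_accuracy
        se = w_means.std(ddof=1) / np.sqrt(w_means.size)
        assert abs(w_means.mean() - 50.0) <= 3 * se + 1e-9

    def test_three_class_chance(self):
        spec = SyntheticSpec(
            n_timepoints=80, n_channels=6, n_epochs=120, signal_value=0.0,
            signal_channels=(1,), signal_timepoints=(1, 80), rng_seed=5,
        )
        from eegdecode import generate_multi_noise_dataset

        ds = generate_multi_noise_dataset(spec, 3)
        cfg = DecodingConfig(
            window_width_ms=10, step_ms=10, k_folds=3, m_repetitions=2,
            discrimination_groups=[(1, 2, 3)], rng_seed=8,
        )
        res = SubjectDecoder(ds, cfg).fit()
        assert res.chance_level == pytest.approx(100 / 3)
        w_means = res.accuracy  # 8 windows on independent data
        se = w_means.std(ddof=1) / np.sqrt(w_means.size)
        assert abs(w_means.mean() - 100 / 3) <= 3 * se + 1e-9

    def test_duplicating_exemplars_does_not_hurt(self, tiny_spec, tiny_config):
        ds = generate_two_condition_dataset(tiny_spec)
        doubled = EpochedDataset(
            data={k: np.concatenate([v, v], axis=2) for k, v in ds.data.items()},
            sampling_rate_hz=ds.sampling_rate_hz,
        )
        r1 = SubjectDecoder(ds, tiny_config).fit()
        r2 = SubjectDecoder(doubled, tiny_config).fit()
        # strong-signal windows: duplication must not reduce performance
        assert r2.accuracy[2:].mean() >= r1.accuracy[2:].mean() - 2.0

    def test_block_averaging_one_exemplar_per_run(self):
        spec = SyntheticSpec(
            n_timepoints=10, n_channels=4, n_epochs=60, n_runs=12,
            signal_value=2.0, signal_channels=(1, 2),
            signal_timepoints=(1, 10), rng_seed=3,
        )
        ds = generate_two_condition_dataset(spec)
        cfg = DecodingConfig(
            window_width_ms=10, step_ms=10, k_folds=3, m_repetitions=2,
            average_by_block=True, rng_seed=4,
        )
        res = SubjectDecoder(ds, cfg).fit()
        # 12 run-averaged exemplars per condition, k=3 -> sets of 4
        assert res.accuracy[0] > 90

    def test_result_round_trip(self, tiny_spec, tiny_config, tmp_path):
        ds = generate_two_condition_dataset(tiny_spec)
        res = SubjectDecoder(ds, tiny_config.replace(permute_labels=True)).fit()
        res.save(tmp_path / "r.npz")
        loaded = DecodingResult.load(tmp_path / "r.npz")
        np.testing.assert_array_equal(loaded.per_analysis, res.per_analysis)
        np.testing.assert_array_equal(
            loaded.feature_weights.per_channel, res.feature_weights.per_channel
        )
        assert loaded.config == res.config.replace(backend_factory=None)
        assert loaded.group == res.group


class TestRegressionPipeline:
    def test_label_information_confined_to_signal_windows(self):
        spec = SyntheticSpec(
            n_timepoints=20, n_channels=6, n_epochs=80,
            signal_channels=(1, 2, 3), signal_timepoints=(11, 20), rng_seed=6,
        )
        ds = generate_svr_dataset(spec, slope=3.0)
        cfg = DecodingConfig(
            analysis_type="regression", window_width_ms=10, step_ms=10,
            k_folds=4, m_repetitions=3, discrimination_groups=[(1,)],
            rng_seed=13,
        )
        res = SubjectDecoder(ds, cfg).fit()
        assert res.accuracy[1] > 0.5  # Fisher-Z, strong encoding
        assert abs(res.accuracy[0]) < 0.2

    def test_zero_slope_scores_near_zero(self):
        spec = SyntheticSpec(
            n_timepoints=10, n_channels=6, n_epochs=60, rng_seed=7,
            signal_channels=(1, 2, 3), signal_timepoints=(1, 10),
        )
        ds = generate_svr_dataset(spec, slope=0.0)
        cfg = DecodingConfig(
            analysis_type="regression", window_width_ms=10, step_ms=10,
            k_folds=4, m_repetitions=4, discrimination_groups=[(1,)],
            rng_seed=14,
        )
        res = SubjectDecoder(ds, cfg).fit()
        assert abs(res.accuracy[0]) < 0.3

    def test_constant_labels_degenerate_branch(self):
        ds = make_dataset(n_conds=1, n_trials=12, seed=8)
        ds.svr_labels = {(1, 1): np.zeros(12)}
        cfg = DecodingConfig(
            analysis_type="regression", window_width_ms=4, step_ms=4,
            k_folds=3, m_repetitions=1, discrimination_groups=[(1,)],
            rng_seed=15,
        )
        res = SubjectDecoder(ds, cfg).fit()
        assert np.all(res.per_analysis == 0.0)
        assert res.degenerate_scores > 0


class TestCrossCondition:
    def _two_context_dataset(self, swap_test=False, train_signal=1.5,
                             seed_offset=0):
        # conditions: 1 noise / 2 signal (context A), 3 noise / 4 signal (B)
        rng_seeds = [s + seed_offset for s in (11, 12, 13, 14)]
        spec = SyntheticSpec(
            n_timepoints=10, n_channels=6, n_epochs=40, signal_value=0.0,
            signal_channels=(1, 2, 3), signal_timepoints=(1, 10),
        )
        from eegdecode import generate_signal_dataset

        cells = {}
        values = [0.0, train_signal, 0.0, 1.5]
        if swap_test:
            values = [0.0, train_signal, 1.5, 0.0]
        for c, (seed, v) in enumerate(zip(rng_seeds, values), start=1):
            ds = generate_signal_dataset(
                spec.replace(signal_value=v, rng_seed=seed)
            )
            cells[(1, c)] = ds.data[(1, 1)]
        return EpochedDataset(data=cells)

    def _config(self):
        return DecodingConfig(
            analysis_type="cross_condition", window_width_ms=10, step_ms=10,
            m_repetitions=3, discrimination_groups=[(1, 2), (3, 4)],
            rng_seed=17,
        )

    def test_generalises_when_signal_matches(self):
        ds = self._two_context_dataset()
        res = SubjectDecoder(ds, self._config()).fit()
        assert res.per_analysis.shape == (1, 3, 1)
        assert res.accuracy[0] > 85

    def test_class_swap_flips_below_chance(self):
        acc_same = SubjectDecoder(
            self._two_context_dataset(), self._config()
        ).fit().accuracy[0]
        acc_swap = SubjectDecoder(
            self._two_context_dataset(swap_test=True), self._config()
        ).fit().accuracy[0]
        assert acc_swap < 15
        assert acc_same + acc_swap == pytest.approx(100, abs=15)

    def test_no_training_signal_means_chance(self):
        # a noise-trained classifier projects randomly onto the test signal,
        # so any single dataset can sit far from 50%; the mean over
        # independent dataset draws must be at chance
        accs = [
            SubjectDecoder(
                self._two_context_dataset(train_signal=0.0,
                                          seed_offset=100 * i),
                self._config(),
            ).fit().accuracy[0]
            for i in range(8)
        ]
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 50) <= 3 * se + 1e-9

    def test_overlapping_contexts_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            DecodingConfig(
                analysis_type="cross_condition",
                discrimination_groups=[(1, 2), (2, 3)],
            )
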