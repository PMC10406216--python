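import numpy as np
import pytest

from respco2.fcn import FCNSpec, build_model
from respco2.io import PhysioRecording, WaveformSeries
from respco2.train_eval import (EvalResult, TrainConfig, compare_methods,
                                evaluate_recording, kfold_split, mae, mape,
                                mse, n_chunks, pearson_r, results_frame,
                                run_crossval, summarize, train)


class TestKFold:
    def test_18_subjects_5_folds_sizes(self):
        split = kfold_split([f"s{i}" for i in range(18)], k=5, seed=0)
        sizes = sorted(len(split.test_subjects(f)) for f in range(5))
        assert sizes == [3, 3, 4, 4, 4]

    def test_deterministic_and_partition(self):
        ids = [f"s{i}" for i in range(11)]
        a = kfold_split(ids, k=4, seed=3)
        b = kfold_split(ids, k=4, seed=3)
        assert a.assignment == b.assignment
        seen = [s for f in range(4) for s in a.test_subjects(f)]
        assert sorted(seen) == sorted(ids)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            kfold_split(["a", "b"], k=5, seed=0)


class TestMetrics:
    def test_pearson_endpoints(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(a, a) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_pearson_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        n = 3
        num = n * (a * b).sum() - a.sum() * b.sum()
        den = np.sqrt(n * (a * a).sum() - a.sum() ** 2) * \
            np.sqrt(n * (b * b).sum() - b.sum() ** 2)
        assert pearson_r(a, b) == pytest.approx(num / den, abs=1e-12)

    def test_pearson_constant_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert np.isnan(pearson_r(np.ones(5), np.arange(5.0)))

    def test_mae_mape_hand_values(self):
        truth = np.array([1.0, 1.0])
        pred = np.array([0.9, 1.1])
        assert mae(pred, truth) == pytest.approx(0.1)
        assert mape(pred, truth) == pytest.approx(0.1)

    def test_scaling_properties(self):
        rng = np.random.default_rng(0)
        truth = 1.0 + 0.2 * rng.random(50)
        pred = truth + 0.1 * rng.standard_normal(50)
        assert mae(2 * pred, 2 * truth) == pytest.approx(2 * mae(pred, truth))
        assert mape(2 * pred, 2 * truth) == pytest.approx(mape(pred, truth))

    def test_mape_near_zero_truth_is_hard_error(self):
        with pytest.raises(ValueError, match="PETCO2"):
            mape(np.ones(3), np.array([1.0, 0.0, 1.0]))

    def test_perfect_and_zero(self):
        x = np.random.default_rng(1).standard_normal(20)
        assert mse(x, x) == 0.0
        assert mae(x, x) == 0.0


class TestTrain:
    def _recordings(self, n=3, dur_s=200.0, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            m = int(dur_s * 10)
            x = rng.standard_normal(m)
            y = -0.8 * x + 0.1 * rng.standard_normal(m)
            recs.append(PhysioRecording(f"s{i}", f"r{i}",
                                        WaveformSeries(x, 10.0),
                                        WaveformSeries(y, 10.0)))
        return recs

    def test_chunk_arithmetic(self):
        # a 10.8 min recording yields 7 full 90 s chunks; the tail is dropped
        assert n_chunks(10.8 * 60) == 7

    def test_empty_training_set(self):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(FCNSpec(depth="2L"), 0), [])

    def test_loss_decreases_over_epochs(self):
        passes = 0
        for seed in range(5):
            model = build_model(FCNSpec(depth="2L", epochs=15), seed=seed)
            model = train(model, self._recordings(seed=seed),
                          TrainConfig(shuffle_seed=seed))
            assert len(model.training_log) == 15
            passes += model.training_log[-1] < model.training_log[0]
        assert passes >= 4

    def test_chunked_method_runs_and_logs(self):
        model = build_model(FCNSpec(depth="2L", epochs=2), seed=0)
        model = train(model, self._recordings(dur_s=200.0),
                      TrainConfig(method="chunked"))
        assert len(model.training_log) == 2

    def test_chunked_too_short_recordings_rejected(self):
        model = build_model(FCNSpec(depth="2L", epochs=1), seed=0)
        with pytest.raises(ValueError, match="chunk"):
            train(model, self._recordings(dur_s=60.0), TrainConfig(method="chunked"))


class TestEvaluate:
    def _series(self, values, fs=10.0):
        return WaveformSeries(np.asarray(values, dtype=float), fs)

    def test_perfect_predictor(self, default_sim):
        from respco2.preprocess import lowpass, znormalize
        co2 = znormalize(lowpass(default_sim.recording.co2, 1.0))
        res = evaluate_recording("r", "perfect", co2, co2)
        assert res.r_co2 == pytest.approx(1.0)
        assert res.mse_co2 == 0.0
        assert res.r_petco2 == pytest.approx(1.0)
        assert res.mape_petco2 == 0.0

    def test_constant_predictor_records_missing(self, default_sim):
        from respco2.preprocess import lowpass, znormalize
        co2 = znormalize(lowpass(default_sim.recording.co2, 1.0))
        const = self._series(np.full(co2.n, 0.5), co2.fs)
        with pytest.warns(RuntimeWarning):
            res = evaluate_recording("r", "const", const, co2)
        assert np.isnan(res.r_co2)

    def test_summary_schema(self):
        results = [
            EvalResult("r1", "A", r_co2=0.9, mse_co2=0.1),
            EvalResult("r2", "A", r_co2=0.8, mse_co2=0.2),
            EvalResult("r1", "B", r_co2=0.5, mse_co2=0.4),
            EvalResult("r2", "B", r_co2=0.6, mse_co2=0.3),
        ]
        table = summarize(results)
        assert set(table.index) == {"A", "B"}
        assert ("r_co2", "mean") in table.columns
        assert ("r_co2", "std") in table.columns
        assert table.loc["A", ("r_co2", "mean")] == pytest.approx(0.85)


class TestCompare:
    def _results(self, values_by_method):
        out = []
        for method, values in values_by_method.items():
            for i, v in enumerate(values):
                out.append(EvalResult(f"rec{i}", method, r_co2=v))
        return out

    def test_identical_methods_not_significant(self):
        vals = list(np.random.default_rng(0).random(10))
        res = self._results({"A": vals, "B": vals, "C": vals})
        report = compare_methods(res, "r_co2", reference="A")
        assert report.attrs["omnibus_p"] == pytest.approx(1.0)
        assert (report.p_fdr > 0.9).all()
        assert not report.significant.any()

    def test_dominant_method_detected(self):
        rng = np.random.default_rng(1)
        res = self._results({
            "good": list(0.9 + 0.01 * rng.standard_normal(30)),
            "bad1": list(0.5 + 0.01 * rng.standard_normal(30)),
            "bad2": list(0.55 + 0.01 * rng.standard_normal(30)),
        })
        report = compare_methods(res, "r_co2", reference="good")
        assert report.attrs["omnibus_p"] < 0.05
        assert report.significant.all()

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(2)
        res = self._results({m: list(rng.random(8)) for m in "ABCD"})
        report = compare_methods(res, "r_co2", reference="A")
        assert (report.p_fdr >= report.p_raw - 1e-12).all()

    def test_too_few_recordings(self):
        res = self._results({"A": [0.1, 0.2], "B": [0.3, 0.4]})
        with pytest.raises(ValueError, match=">= 3"):
            compare_methods(res, "r_co2", reference="A")

    def test_missing_reference(self):
        res = self._results({"A": [0.1] * 5, "B": [0.2] * 5})
        with pytest.raises(ValueError, match="reference"):
            compare_methods(res, "r_co2", reference="Z")


class TestFoldIsolation:
    def test_perturbing_a_test_recording_leaves_its_fold_model_unchanged(
            self, small_processed_cohort):
        recs = [r.copy() for r in small_processed_cohort]
        spec = FCNSpec(depth="2L", epochs=2)
        base = results_frame(run_crossval(recs, spec, k=3, seed=0,
                                          include_lr=False))
        # perturb one recording's CO2; its own fold's model never saw it,
        # so the other recordings in that fold must score identically
        split = kfold_split([r.subject_id for r in recs], k=3, seed=0)
        victim = recs[0]
        fold = split.assignment[victim.subject_id]
        victim.co2.values = victim.co2.values + 0.5 * np.sin(
            np.arange(victim.co2.n) * 0.01)
        pert = results_frame(run_crossval(recs, spec, k=3, seed=0,
                                          include_lr=False))
        same_fold_others = [r.recording_id for r in recs[1:]
                            if split.assignment[r.subject_id] == fold]
        for rid in same_fold_others:
            a = base[base.recording_id == rid].iloc[0]
            b = pert[pert.recording_id == rid].iloc[0]
            assert a.r_co2 == b.r_co2
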