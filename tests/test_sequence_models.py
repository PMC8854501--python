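import numpy as np
import pytest

from tofcast.errors import ConfigError, InsufficientDataError, SeriesTooShortError, ShapeError
from tofcast.preprocessing import WindowSet, make_windows, scale_series, split_half
from tofcast.sequence_models import (
    MODEL_KINDS,
    ModelSpec,
    TrainedPredictor,
    _forward,
    _init_params,
    _loss_and_grads,
    baseline_persistence,
    forecast_test_half,
    load_predictor,
    predict_one_step,
    save_predictor,
    train_predictor,
)
from tofcast.evaluation import rmse_of_records

from conftest import FAST_SPEC, sigmoid_series


def constant_windows(c=0.5, n=40):
    inputs = np.full((n, 4), c)
    targets = np.full(n, c)
    return WindowSet(inputs=inputs, targets=targets)


@pytest.mark.parametrize("kind", MODEL_KINDS)
class TestGradientsAndTraining:
    def test_backprop_matches_numerical_gradient(self, kind):
        """Analytic BPTT gradients agree with central finite differences."""
        rng = np.random.default_rng(0)
        params = _init_params(kind, 5, rng)
        X = rng.uniform(0, 1, size=(3, 4))
        y = rng.uniform(0, 1, size=3)
        _, grads = _loss_and_grads(params, kind, X, y)
        eps = 1e-6
        for name, w in params.items():
            flat = w.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 7)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = _loss_and_grads(params, kind, X, y)
                flat[idx] = orig - eps
                lm, _ = _loss_and_grads(params, kind, X, y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[idx]
                assert ana == pytest.approx(num, abs=1e-7), f"{kind} {name}[{idx}]"

    def test_training_reduces_loss_and_is_deterministic(self, kind):
        series = sigmoid_series(n=80, noise=0.5, seed=2)
        split = split_half(series)
        windows = make_windows(scale_series(split.train))
        spec = ModelSpec(kind=kind, seed=11, **FAST_SPEC)
        a = train_predictor(windows, spec)
        b = train_predictor(windows, spec)
        assert a.training_loss_trace[-1] <= a.training_loss_trace[0]
        for k in a.parameters:
            np.testing.assert_array_equal(a.parameters[k], b.parameters[k])
        fa = forecast_test_half(a, split)
        fb = forecast_test_half(b, split)
        np.testing.assert_allclose(
            [r.predicted for r in fa], [r.predicted for r in fb], atol=1e-6
        )

    def test_constant_series_predicts_the_constant(self, kind):
        c = 0.5
        pred = train_predictor(constant_windows(c), ModelSpec(kind=kind, seed=3, **FAST_SPEC))
        assert predict_one_step(pred, [c, c, c, c]) == pytest.approx(c, abs=0.02)

    def test_beats_persistence_on_noiseless_recovery(self, kind):
        """One-step RMSE on the test half of a smooth sigmoid must undercut
        the previous-value baseline (default training spec)."""
        series = sigmoid_series(n=160, slope=9.0, end=93.0, noise=0.0, seed=0)
        split = split_half(series)
        windows = make_windows(scale_series(split.train))
        pred = train_predictor(windows, ModelSpec(kind=kind, seed=5))
        model_rmse = rmse_of_records(forecast_test_half(pred, split))
        naive_rmse = rmse_of_records(baseline_persistence(split))
        assert model_rmse < naive_rmse


class TestPredictOneStep:
    def test_purity(self, fast_gru_predictor):
        pred, _ = fast_gru_predictor
        lags = [0.1, 0.2, 0.3, 0.4]
        assert predict_one_step(pred, lags) == predict_one_step(pred, lags)

    def test_finite_on_zero_lags(self, fast_gru_predictor):
        pred, _ = fast_gru_predictor
        assert np.isfinite(predict_one_step(pred, [0.0, 0.0, 0.0, 0.0]))

    def test_wrong_lag_count(self, fast_gru_predictor):
        pred, _ = fast_gru_predictor
        with pytest.raises(ShapeError):
            predict_one_step(pred, [0.1, 0.2, 0.3])

    def test_untrained_predictor_rejected(self):
        empty = TrainedPredictor(spec=ModelSpec(), donor_id="x", parameters={})
        with pytest.raises(ConfigError):
            predict_one_step(empty, [0.1, 0.2, 0.3, 0.4])

    def test_empty_windows_rejected(self):
        w = WindowSet(inputs=np.empty((0, 4)), targets=np.empty(0))
        with pytest.raises(InsufficientDataError):
            train_predictor(w, ModelSpec(seed=1, **FAST_SPEC))


class TestForecastTestHalf:
    def test_record_count_no_missing(self, fast_gru_predictor):
        pred, split = fast_gru_predictor
        records = forecast_test_half(pred, split)
        assert len(records) == len(split.test)
        assert [r.t_index for r in records] == list(
            range(split.split_index, split.split_index + len(split.test))
        )

    def test_first_prediction_uses_last_train_lags(self, fast_gru_predictor):
        pred, split = fast_gru_predictor
        records = forecast_test_half(pred, split)
        lags = split.train.values[-4:] / 100.0
        expected = predict_one_step(pred, lags) * 100.0
        assert records[0].predicted == pytest.approx(expected, abs=1e-9)

    def test_missing_targets_are_skipped_and_lags_causally_filled(self, fast_gru_predictor):
        pred, split = fast_gru_predictor
        observed = split.test.observed.copy()
        observed[2] = False
        values = np.where(observed, split.test.values, np.nan)
        from tofcast.preprocessing import SplitSeries
        from tofcast.synthetic_cohort import TOFRSeries

        gappy = SplitSeries(
            train=split.train,
            test=TOFRSeries(values=values, observed=observed),
            split_index=split.split_index,
        )
        records = forecast_test_half(pred, gappy)
        assert len(records) == len(split.test) - 1
        assert split.split_index + 2 not in [r.t_index for r in records]

    def test_causality_future_perturbation_does_not_change_prediction(self, fast_gru_predictor):
        """Changing an observed value at index >= t must not move the
        prediction at t (the real-time contract)."""
        pred, split = fast_gru_predictor
        base = forecast_test_half(pred, split)
        t_probe = 5  # fifth test point
        from tofcast.preprocessing import SplitSeries
        from tofcast.synthetic_cohort import TOFRSeries

        perturbed_values = split.test.values.copy()
        perturbed_values[t_probe:] += 7.0
        perturbed = SplitSeries(
            train=split.train,
            test=TOFRSeries(values=perturbed_values, observed=split.test.observed),
            split_index=split.split_index,
        )
        after = forecast_test_half(pred, perturbed)
        assert after[t_probe].predicted == pytest.approx(base[t_probe].predicted, abs=1e-12)
        assert after[t_probe + 1].predicted != pytest.approx(base[t_probe + 1].predicted)


class TestPersistenceBaseline:
    def test_constant_series_rmse_zero(self):
        from tofcast.synthetic_cohort import TOFRSeries

        s = TOFRSeries(values=np.full(20, 95.0), observed=np.ones(20, dtype=bool))
        records = baseline_persistence(split_half(s))
        assert rmse_of_records(records) == 0.0

    def test_predicts_previous_value(self, noiseless_series):
        split = split_half(noiseless_series)
        records = baseline_persistence(split)
        assert records[-1].predicted == pytest.approx(noiseless_series.values[-2])

    def test_underpredicts_strictly_increasing_series(self):
        from tofcast.synthetic_cohort import TOFRSeries

        v = np.linspace(1, 90, 30)
        s = TOFRSeries(values=v, observed=np.ones(30, dtype=bool))
        for r in baseline_persistence(split_half(s)):
            assert r.predicted < r.observed


class TestSerialization:
    def test_bank_round_trip(self, fast_gru_predictor, tmp_path):
        from tofcast.sequence_models import load_predictor_bank, save_predictor_bank

        pred, split = fast_gru_predictor
        index = save_predictor_bank({"p001": pred}, tmp_path / "bank")
        assert index.name == "index.json"
        bank = load_predictor_bank(tmp_path / "bank")
        np.testing.assert_allclose(
            [r.predicted for r in forecast_test_half(bank["p001"], split)],
            [r.predicted for r in forecast_test_half(pred, split)],
        )

    def test_round_trip(self, fast_gru_predictor, tmp_path):
        pred, split = fast_gru_predictor
        path = tmp_path / f"{pred.donor_id}.{pred.spec.kind}.model.npz"
        save_predictor(pred, path)
        loaded = load_predictor(path)
        assert loaded.spec == pred.spec
        assert loaded.donor_id == pred.donor_id
        np.testing.assert_allclose(
            [r.predicted for r in forecast_test_half(loaded, split)],
            [r.predicted for r in forecast_test_half(pred, split)],
        )
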