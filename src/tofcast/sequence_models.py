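"""One-step-ahead recurrent predictors: simple RNN, GRU and LSTM.

Each model maps the four most recent (scaled) TOFR samples to the next one.
The networks are deliberately small — one recurrent layer feeding a linear
output head — because each patient contributes only ~60-114 training
patterns.  Cells, backpropagation through time and the Adam optimiser are
implemented directly in numpy (float64) so that training is exactly
reproducible from the spec's seed: identical (windows, spec) always yields
an identical predictor.

Cell equations (h = hidden state, x = scalar input per time step):

* RNN:   h' = tanh(x Wx + h Wh + b)
* GRU:   z = sig(x Wz + h Uz + bz); r = sig(x Wr + h Ur + br);
         c = tanh(x Wc + (r*h) Uc + bc); h' = (1-z)*h + z*c
* LSTM:  i,f,o = sig(gates); g = tanh(gate); c' = f*c + i*g; h' = o*tanh(c')
         (forget-gate bias initialised at 1)

Training minimises mean squared error with Adam; no validation split or
early stopping — with so few patterns a further split is noise, and a fixed
epoch count keeps runs deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Sequence

import numpy as np

from .errors import ConfigError, InsufficientDataError, SeriesTooShortError, ShapeError
from .preprocessing import SplitSeries, WindowSet, scale_values, unscale_values

__all__ = [
    "ModelSpec",
    "TrainedPredictor",
    "ForecastRecord",
    "train_predictor",
    "predict_one_step",
    "forecast_test_half",
    "baseline_persistence",
    "save_predictor",
    "load_predictor",
]

MODEL_KINDS = ("RNN", "GRU", "LSTM")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters for one predictor."""

    kind: str = "GRU"
    hidden_units: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if self.hidden_units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("hidden_units, epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")


@dataclass
class TrainedPredictor:
    """A fitted one-step predictor bound to its donor patient.

    Parameters are frozen after training: transfer to another patient reuses
    them as-is, never retraining.
    """

    spec: ModelSpec
    donor_id: str
    parameters: Dict[str, np.ndarray]
    training_loss_trace: List[float] = field(default_factory=list)
    window_size: int = 4


class ForecastRecord(NamedTuple):
    """One walk-forward prediction: sample index, observed and predicted TOFR
    (both on the unscaled 0-100 percent scale)."""

    t_index: int
    observed: float
    predicted: float


# ---------------------------------------------------------------------------
# parameter initialisation


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    a = rng.normal(size=(n, n))
    q, r = np.linalg.qr(a)
    return q * np.sign(np.diag(r))


def _init_params(kind: str, hidden: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    p: Dict[str, np.ndarray] = {}
    if kind == "RNN":
        gates = [""]
    elif kind == "GRU":
        gates = ["z", "r", "c"]
    else:  # LSTM
        gates = ["i", "f", "g", "o"]
    for g in gates:
        p[f"Wx{g}"] = _glorot(rng, N_FEATURES, hidden)
        p[f"Wh{g}"] = _orthogonal(rng, hidden)
        p[f"b{g}"] = np.zeros(hidden)
    if kind == "LSTM":
        p["bf"] = np.ones(hidden)  # standard forget-gate bias
    p["Wout"] = _glorot(rng, hidden, 1)
    p["bout"] = np.zeros(1)
    return p


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


#: Bound on the one-step increment the head can emit, in scaled units
#: (0.05 == 5 TOFR percentage points per 15-s step, well above the steepest
#: physiological recovery rate).
MAX_STEP = 0.05

#: Gradient-clipping threshold on the global gradient norm; standard
#: stabiliser for recurrent training on tiny datasets.
GRAD_CLIP = 1.0

#: Per-time-step input features fed to the recurrent cell: the (scaled) TOFR
#: level and its first difference within the window.  The level keeps the
#: model sensitive to where on the recovery curve it operates; the
#: difference carries the local trend, which generalises across the curve.
N_FEATURES = 2


def _featurize(X: np.ndarray) -> np.ndarray:
    """(B, T) lag windows -> (B, T, 2) of (level, within-window difference).

    The first step's difference is 0 (no earlier sample inside the window).
    """
    diff = np.diff(X, axis=1, prepend=X[:, :1])
    return np.stack([X, diff], axis=2)


# ---------------------------------------------------------------------------
# forward / backward passes (batch-first, X shape (B, T) of scalar inputs)


def _forward(params: Dict[str, np.ndarray], kind: str, X: np.ndarray):
    B, T = X.shape
    H = params["Wout"].shape[0]
    feats = _featurize(X)
    h = np.zeros((B, H))
    cache: Dict[str, list] = {"h": [h], "x": []}
    if kind == "LSTM":
        c = np.zeros((B, H))
        cache["c"] = [c]
    for t in range(T):
        x = feats[:, t, :]  # (B, N_FEATURES)
        cache["x"].append(x)
        if kind == "RNN":
            h = np.tanh(x @ params["Wx"] + h @ params["Wh"] + params["b"])
        elif kind == "GRU":
            z = _sigmoid(x @ params["Wxz"] + h @ params["Whz"] + params["bz"])
            r = _sigmoid(x @ params["Wxr"] + h @ params["Whr"] + params["br"])
            cand = np.tanh(x @ params["Wxc"] + (r * h) @ params["Whc"] + params["bc"])
            h = (1.0 - z) * h + z * cand
            cache.setdefault("z", []).append(z)
            cache.setdefault("r", []).append(r)
            cache.setdefault("cand", []).append(cand)
        else:  # LSTM
            i = _sigmoid(x @ params["Wxi"] + h @ params["Whi"] + params["bi"])
            f = _sigmoid(x @ params["Wxf"] + h @ params["Whf"] + params["bf"])
            g = np.tanh(x @ params["Wxg"] + h @ params["Whg"] + params["bg"])
            o = _sigmoid(x @ params["Wxo"] + h @ params["Who"] + params["bo"])
            c = f * cache["c"][-1] + i * g
            h = o * np.tanh(c)
            cache["c"].append(c)
            for name, val in (("i", i), ("f", f), ("g", g), ("o", o)):
                cache.setdefault(name, []).append(val)
        cache["h"].append(h)
    # Residual head: the network predicts a bounded increment from the most
    # recent lag, so an uninformative hidden state degrades toward
    # persistence instead of toward an arbitrary level.  The tanh bound
    # (+/- MAX_STEP, scaled units) reflects how fast TOFR can physically
    # change between 15-s stimulations.
    u = np.tanh((h @ params["Wout"] + params["bout"]).ravel())
    cache["u"] = u
    y = MAX_STEP * u + X[:, -1]  # (B,)
    return y, cache


def _backward(
    params: Dict[str, np.ndarray], kind: str, cache: Dict[str, list], dy: np.ndarray
) -> Dict[str, np.ndarray]:
    """Gradients of a scalar loss given dL/dy; mirrors :func:`_forward`."""
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    hs = cache["h"]
    T = len(cache["x"])
    h_last = hs[-1]
    du = (dy * MAX_STEP * (1.0 - cache["u"] ** 2)).reshape(-1, 1)  # (B, 1)
    grads["Wout"] = h_last.T @ du
    grads["bout"] = du.sum(axis=0)
    dh = du @ params["Wout"].T  # (B, H)
    if kind == "LSTM":
        dc = np.zeros_like(dh)
    for t in range(T - 1, -1, -1):
        x = cache["x"][t]
        h_prev = hs[t]
        if kind == "RNN":
            h_new = hs[t + 1]
            da = dh * (1.0 - h_new**2)
            grads["Wx"] += x.T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ params["Wh"].T
        elif kind == "GRU":
            z, r, cand = cache["z"][t], cache["r"][t], cache["cand"][t]
            dz = dh * (cand - h_prev)
            dcand = dh * z
            dh_prev = dh * (1.0 - z)
            dcand_pre = dcand * (1.0 - cand**2)
            grads["Wxc"] += x.T @ dcand_pre
            grads["Whc"] += (r * h_prev).T @ dcand_pre
            grads["bc"] += dcand_pre.sum(axis=0)
            drh = dcand_pre @ params["Whc"].T
            dr = drh * h_prev
            dh_prev += drh * r
            dr_pre = dr * r * (1.0 - r)
            grads["Wxr"] += x.T @ dr_pre
            grads["Whr"] += h_prev.T @ dr_pre
            grads["br"] += dr_pre.sum(axis=0)
            dh_prev += dr_pre @ params["Whr"].T
            dz_pre = dz * z * (1.0 - z)
            grads["Wxz"] += x.T @ dz_pre
            grads["Whz"] += h_prev.T @ dz_pre
            grads["bz"] += dz_pre.sum(axis=0)
            dh_prev += dz_pre @ params["Whz"].T
            dh = dh_prev
        else:  # LSTM
            i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
            c_new, c_prev = cache["c"][t + 1], cache["c"][t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_prev = dc * f
            dh_prev = np.zeros_like(dh)
            for name, dgate, act in (
                ("i", di, i),
                ("f", df, f),
                ("o", do, o),
            ):
                dpre = dgate * act * (1.0 - act)
                grads[f"Wx{name}"] += x.T @ dpre
                grads[f"Wh{name}"] += h_prev.T @ dpre
                grads[f"b{name}"] += dpre.sum(axis=0)
                dh_prev += dpre @ params[f"Wh{name}"].T
            dg_pre = dg * (1.0 - g**2)
            grads["Wxg"] += x.T @ dg_pre
            grads["Whg"] += h_prev.T @ dg_pre
            grads["bg"] += dg_pre.sum(axis=0)
            dh_prev += dg_pre @ params["Whg"].T
            dh, dc = dh_prev, dc_prev
    return grads


def _loss_and_grads(params, kind, X, y_true):
    """Mean-squared-error loss and its gradients; the unit used by Adam and
    by the numerical-gradient tests."""
    y_pred, cache = _forward(params, kind, X)
    err = y_pred - y_true
    loss = float(np.mean(err**2))
    dy = 2.0 * err / err.shape[0]
    return loss, _backward(params, kind, cache, dy)


# ---------------------------------------------------------------------------
# training


def train_predictor(windows: WindowSet, spec: ModelSpec, donor_id: str = "") -> TrainedPredictor:
    """Fit a one-step predictor on a patient's (scaled) training windows.

    Deterministic given (windows, spec): the spec seed drives both weight
    initialisation and the per-epoch shuffling.  Inputs are expected on the
    scaled [0, ~1.1] range (see :mod:`tofcast.preprocessing`).
    """
    spec.validate()
    if len(windows) == 0:
        raise InsufficientDataError("cannot train on an empty WindowSet")
    X = np.asarray(windows.inputs, dtype=float)
    y = np.asarray(windows.targets, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("training windows contain non-finite values")

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(spec.seed)))
    params = _init_params(spec.kind, spec.hidden_units, rng)

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(windows)
    trace: List[float] = []
    for _ in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            batch = order[start : start + spec.batch_size]
            loss, grads = _loss_and_grads(params, spec.kind, X[batch], y[batch])
            epoch_loss += loss * len(batch)
            gnorm = np.sqrt(sum(float(np.sum(g**2)) for g in grads.values()))
            if gnorm > GRAD_CLIP:
                scale = GRAD_CLIP / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            step += 1
            lr_t = spec.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                params[k] -= lr_t * m[k] / (np.sqrt(v[k]) + eps)
        trace.append(epoch_loss / n)
    return TrainedPredictor(
        spec=spec,
        donor_id=donor_id,
        parameters=params,
        training_loss_trace=trace,
        window_size=windows.window_size,
    )


# ---------------------------------------------------------------------------
# prediction


def _predict_batch(predictor: TrainedPredictor, lag_matrix: np.ndarray) -> np.ndarray:
    if not predictor.parameters:
        raise ConfigError("predictor has no trained parameters")
    X = np.asarray(lag_matrix, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"lag matrix must be 2-D, got shape {X.shape}")
    y, _ = _forward(predictor.parameters, predictor.spec.kind, X)
    return y


def predict_one_step(predictor: TrainedPredictor, lags: Sequence[float]) -> float:
    """Predict the next scaled TOFR value from a window of scaled lags.

    Pure function of (parameters, lags): repeated calls return identical
    outputs.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.ndim != 1 or lags.shape[0] != predictor.window_size:
        raise ShapeError(
            f"expected {predictor.window_size} lags, got array of shape {lags.shape}"
        )
    if not np.all(np.isfinite(lags)):
        raise ShapeError("lags must be finite")
    return float(_predict_batch(predictor, lags[None, :])[0])


def _causal_fill(values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Replace each missing value with the most recent observed one.

    Never looks forward in time — interpolation across a gap would use
    future samples, breaking the real-time contract.
    """
    filled = np.where(observed, values, np.nan)
    idx = np.where(observed, np.arange(len(values)), -1)
    idx = np.maximum.accumulate(idx)
    if idx[0] < 0:
        first = int(np.argmax(observed))
        idx[idx < 0] = first  # leading gap: nothing earlier exists
    return filled[idx]


def forecast_test_half(predictor: TrainedPredictor, split: SplitSeries) -> List[ForecastRecord]:
    """Walk-forward one-step predictions over the test half of a split series.

    For every test index whose target is observed, the input lags are the
    four most recent causally filled values ending one step earlier; lags may
    reach back into the training half for the first test points.  Each
    prediction re-anchors on observations (never on its own previous
    outputs), and results are returned on the unscaled 0-100 scale.
    """
    if len(split.test) < 1:
        raise SeriesTooShortError("test half is empty")
    w = predictor.window_size
    if split.split_index < w:
        raise SeriesTooShortError(
            f"training half must hold at least {w} samples to seed the first lags"
        )
    full_values = np.concatenate([split.train.values, split.test.values])
    full_observed = np.concatenate([split.train.observed, split.test.observed])
    filled = _causal_fill(full_values, full_observed)
    scaled = scale_values(filled)

    test_idx = np.arange(split.split_index, len(full_values))
    keep = full_observed[test_idx]
    targets_idx = test_idx[keep]
    lag_matrix = np.stack([scaled[t - w : t] for t in targets_idx])
    preds = unscale_values(_predict_batch(predictor, lag_matrix))
    return [
        ForecastRecord(t_index=int(t), observed=float(full_values[t]), predicted=float(p))
        for t, p in zip(targets_idx, preds)
    ]


def baseline_persistence(split: SplitSeries) -> List[ForecastRecord]:
    """Naive forecaster: predict the previous (causally filled) value.

    The internal sanity floor every recurrent model must beat on smooth
    recovery curves.
    """
    if len(split.test) < 1:
        raise SeriesTooShortError("test half is empty")
    full_values = np.concatenate([split.train.values, split.test.values])
    full_observed = np.concatenate([split.train.observed, split.test.observed])
    filled = _causal_fill(full_values, full_observed)
    test_idx = np.arange(split.split_index, len(full_values))
    keep = full_observed[test_idx]
    targets_idx = test_idx[keep]
    return [
        ForecastRecord(
            t_index=int(t), observed=float(full_values[t]), predicted=float(filled[t - 1])
        )
        for t in targets_idx
    ]


# ---------------------------------------------------------------------------
# serialization


def save_predictor(predictor: TrainedPredictor, path: str | Path) -> None:
    """Write a predictor's weights (npz) next to a JSON sidecar of its spec."""
    path = Path(path)
    np.savez(path, **predictor.parameters)
    meta = {
        "spec": predictor.spec.__dict__,
        "donor_id": predictor.donor_id,
        "training_loss_trace": predictor.training_loss_trace,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def save_predictor_bank(predictors: Dict[str, TrainedPredictor], directory: str | Path) -> Path:
    """Persist a cohort's predictors: one ``<donor>.<kind>.model.npz`` per
    patient plus an ``index.json`` mapping donor_id to file and spec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for donor_id, predictor in predictors.items():
        name = f"{donor_id}.{predictor.spec.kind}.model.npz"
        save_predictor(predictor, directory / name)
        index[donor_id] = {"file": name, "spec": predictor.spec.__dict__}
    index_path = directory / "index.json"
    index_path.write_text(json.dumps(index, indent=2))
    return index_path


def load_predictor_bank(directory: str | Path) -> Dict[str, TrainedPredictor]:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    return {donor: load_predictor(directory / meta["file"]) for donor, meta in index.items()}


def load_predictor(path: str | Path) -> TrainedPredictor:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else Path(str(path) + ".npz")
    data = np.load(npz_path)
    meta = json.loads(npz_path.with_suffix(npz_path.suffix + ".json").read_text())
    return TrainedPredictor(
        spec=ModelSpec(**meta["spec"]),
        donor_id=meta["donor_id"],
        parameters={k: data[k] for k in data.files},
        training_loss_trace=list(meta["training_loss_trace"]),
    )
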