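"""Regressors mapping raw-signal windows to the 2-D centre of pressure.

Two model families, presented statsmodels-style (a model object built from
data whose ``fit()`` returns a results object):

* :class:`LinearCOP` — multivariate linear least squares on a flat design
  matrix (optionally including signal history), the baseline model.
* :class:`LSTMCOP` — a single hidden layer of LSTM units reading the most
  recent 0.1 s (10 samples) of the selected channels, with a linear readout
  of the last hidden state, trained with Adam on the mean-squared error
  until the train error stops decreasing (patience rule).

Both fit the two COP components jointly.  LSTM inputs are z-scored per
feature on the training data; the targets are likewise z-scored per output
inside the optimizer (predictions are mapped back to mm), which makes the
fixed 0.001 learning rate well-scaled regardless of the COP amplitude.
Windows are stateless: the hidden state is reset per window, so predictions
are order-independent.

``fine_tune`` implements the standing-calibration update: the linear model
refits on the pooled original + calibration rows with the calibration
upweighted; the LSTM continues Adam training on the calibration data only
at a tenth of the base learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from . import _lstm
from .dataset import ChannelSpec, build_design_matrix, build_windows
from .series import Session

__all__ = [
    "TrainConfig",
    "LinearCOP",
    "LinearCOPResults",
    "LSTMCOP",
    "LSTMCOPResults",
    "fit_linear",
    "fit_lstm",
    "fine_tune",
    "load_results",
]


@dataclass(frozen=True)
class TrainConfig:
    """LSTM training configuration (Adam on the MSE).

    ``patience`` operationalizes "until train error stopped decreasing":
    stop when the epoch-level train loss has not improved for that many
    epochs; the best-epoch weights are kept.
    """

    learning_rate: float = 0.001
    batch_size: int = 256
    max_epochs: int = 500
    patience: int = 10
    seed: int = 0
    hidden_units: int = 100
    finetune_lr_factor: float = 0.1
    finetune_max_epochs: int = 50
    calib_weight: float = 10.0  # linear-model calibration upweighting

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be ≥ 1")
        if self.batch_size < 1 or self.max_epochs < 1 or self.hidden_units < 1:
            raise ValueError("batch_size, max_epochs and hidden_units must be ≥ 1")


# ---------------------------------------------------------------------------
# linear model


class LinearCOP:
    """Multivariate linear regression of COP on a flat design matrix."""

    def __init__(self, X: np.ndarray, Y: np.ndarray, channel_spec: ChannelSpec | None = None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("X must be (n, p) and Y must be (n, 2)")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        if X.shape[0] < 1:
            raise ValueError("need at least one sample")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("non-finite entries in X or Y")
        self.X, self.Y = X, Y
        self.channel_spec = channel_spec

    @classmethod
    def from_session(cls, session: Session, spec: ChannelSpec) -> "LinearCOP":
        X, Y = build_design_matrix(session, spec)
        return cls(X, Y, channel_spec=spec)

    def fit(self, sample_weight: np.ndarray | None = None) -> "LinearCOPResults":
        """Least-squares solution (minimum-norm under rank deficiency)."""
        Xaug = np.hstack([self.X, np.ones((self.X.shape[0], 1))])
        Yw, Xw = self.Y, Xaug
        if sample_weight is not None:
            sw = np.sqrt(np.asarray(sample_weight, dtype=float))[:, None]
            Xw, Yw = Xaug * sw, self.Y * sw
        # rcond cutoff: rank-deficient (and numerically near-deficient)
        # directions are dropped, giving the minimum-norm solution without
        # round-off amplification on collinear noiseless channels
        coef, *_ = np.linalg.lstsq(Xw, Yw, rcond=1e-8)
        return LinearCOPResults(self, weights=coef[:-1], intercept=coef[-1])


class LinearCOPResults:
    """Fitted linear COP map: ``Y_hat = X @ weights + intercept``."""

    def __init__(self, model: LinearCOP, weights: np.ndarray, intercept: np.ndarray):
        self.model = model
        self.weights = np.asarray(weights, dtype=float)
        self.intercept = np.asarray(intercept, dtype=float)
        resid = model.Y - self.predict(model.X)
        self.train_mse = float(np.mean(resid**2))
        self.train_rmse = np.sqrt(np.mean(resid**2, axis=0))  # per output, mm

    @property
    def channel_spec(self) -> ChannelSpec | None:
        return self.model.channel_spec

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
                f"model expects {self.weights.shape[0]}"
            )
        return X @ self.weights + self.intercept

    def predict_session(self, session: Session) -> tuple[np.ndarray, np.ndarray]:
        if self.channel_spec is None:
            raise ValueError("model was not built from a session (no channel spec)")
        X, Y = build_design_matrix(session, self.channel_spec)
        return self.predict(X), Y

    def summary(self) -> str:
        p, n = self.weights.shape[0], self.model.X.shape[0]
        lines = [
            "Linear COP regression results",
            "=" * 46,
            f"{'n train samples':<28}{n:>18}",
            f"{'n features':<28}{p:>18}",
            f"{'train RMSE anterior [mm]':<28}{self.train_rmse[0]:>18.3f}",
            f"{'train RMSE lateral [mm]':<28}{self.train_rmse[1]:>18.3f}",
            f"{'intercept [mm]':<28}{self.intercept[0]:>9.2f}{self.intercept[1]:>9.2f}",
        ]
        if self.channel_spec is not None:
            cs = self.channel_spec
            lines.append(
                f"{'channels':<28}{''.join(cs.components)} | IMUs "
                f"{','.join(map(str, cs.imus))} | h={cs.history}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "kind": "linear",
            "channel_spec": None if self.channel_spec is None else self.channel_spec.to_dict(),
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            weights=self.weights,
            intercept=self.intercept,
            X=self.model.X,
            Y=self.model.Y,
        )


# ---------------------------------------------------------------------------
# LSTM model


class LSTMCOP:
    """Windowed LSTM regression of COP on the recent signal history."""

    def __init__(
        self,
        windows: np.ndarray,
        Y: np.ndarray,
        config: TrainConfig | None = None,
        channel_spec: ChannelSpec | None = None,
    ):
        W = np.asarray(windows, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if W.ndim != 3 or Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("windows must be (n, T, d) and Y must be (n, 2)")
        if W.shape[0] != Y.shape[0] or W.shape[0] < 1:
            raise ValueError("windows and Y must share a positive row count")
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(Y))):
            raise ValueError("non-finite entries in windows or Y")
        self.windows, self.Y = W, Y
        self.config = config or TrainConfig()
        self.channel_spec = channel_spec

    @classmethod
    def from_session(
        cls, session: Session, spec: ChannelSpec, config: TrainConfig | None = None
    ) -> "LSTMCOP":
        W, Y = build_windows(session, spec)
        return cls(W, Y, config=config, channel_spec=spec)

    def fit(self) -> "LSTMCOPResults":
        cfg = self.config
        W, Y = self.windows, self.Y
        n, T, d = W.shape

        x_mu = W.reshape(-1, d).mean(axis=0)
        x_sd = W.reshape(-1, d).std(axis=0)
        x_sd = np.where(x_sd < 1e-8, 1.0, x_sd)
        y_mu = Y.mean(axis=0)
        y_sd = Y.std(axis=0)
        y_sd = np.where(y_sd < 1e-8, 1.0, y_sd)

        Wn = (W - x_mu) / x_sd
        Yn = (Y - y_mu) / y_sd

        rng = np.random.default_rng(cfg.seed)
        params = _lstm.init_params(d, cfg.hidden_units, rng)
        opt = _lstm.AdamState(params, cfg.learning_rate)
        trace, best_loss, best_params, stale = [], np.inf, params.copy(), 0
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                yb = Yn[idx]
                pred, cache = _lstm.forward(params, Wn[idx], cache=True)
                err = pred - yb
                losses.append(float(np.mean(err**2)))
                if not np.isfinite(losses[-1]):
                    raise FloatingPointError("LSTM training diverged (NaN/inf loss)")
                dY = 2.0 * err / err.size
                grads = _lstm.backward(params, cache, dY)
                _lstm.adam_step(params, grads, opt)
            epoch_loss = float(np.mean(losses))
            trace.append(epoch_loss)
            if epoch_loss < best_loss - 1e-12:
                best_loss, best_params, stale = epoch_loss, params.copy(), 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        return LSTMCOPResults(
            self, best_params, (x_mu, x_sd), (y_mu, y_sd), trace, config=cfg
        )


class LSTMCOPResults:
    """Fitted LSTM COP map with its standardization constants and loss trace."""

    def __init__(self, model, params, x_scale, y_scale, loss_trace, config: TrainConfig):
        self.model = model
        self.params = params
        self.x_mu, self.x_sd = x_scale
        self.y_mu, self.y_sd = y_scale
        self.loss_trace = list(loss_trace)
        self.config = config

    @property
    def channel_spec(self) -> ChannelSpec | None:
        return getattr(self.model, "channel_spec", None)

    def predict(self, windows: np.ndarray, chunk: int = 4096) -> np.ndarray:
        W = np.asarray(windows, dtype=float)
        d = self.params["Wx"].shape[0]
        if W.ndim != 3 or W.shape[2] != d:
            raise ValueError(f"windows must be (n, T, {d})")
        out = []
        for start in range(0, W.shape[0], chunk):
            Wn = (W[start : start + chunk] - self.x_mu) / self.x_sd
            out.append(_lstm.forward(self.params, Wn) * self.y_sd + self.y_mu)
        return np.concatenate(out, axis=0)

    def predict_session(self, session: Session) -> tuple[np.ndarray, np.ndarray]:
        if self.channel_spec is None:
            raise ValueError("model was not built from a session (no channel spec)")
        W, Y = build_windows(session, self.channel_spec)
        return self.predict(W), Y

    def summary(self) -> str:
        n, T, d = self.model.windows.shape
        final = self.loss_trace[-1] if self.loss_trace else float("nan")
        lines = [
            "LSTM COP regression results",
            "=" * 46,
            f"{'n train windows':<28}{n:>18}",
            f"{'window × input width':<28}{f'{T} × {d}':>18}",
            f"{'hidden units':<28}{self.config.hidden_units:>18}",
            f"{'epochs run':<28}{len(self.loss_trace):>18}",
            f"{'best train loss (z units)':<28}{min(self.loss_trace):>18.5f}",
            f"{'final train loss (z units)':<28}{final:>18.5f}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        meta = {
            "kind": "lstm",
            "config": {
                k: getattr(self.config, k)
                for k in (
                    "learning_rate",
                    "batch_size",
                    "max_epochs",
                    "patience",
                    "seed",
                    "hidden_units",
                )
            },
            "channel_spec": None if self.channel_spec is None else self.channel_spec.to_dict(),
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            x_mu=self.x_mu,
            x_sd=self.x_sd,
            y_mu=self.y_mu,
            y_sd=self.y_sd,
            loss_trace=np.asarray(self.loss_trace),
            **{f"p_{k}": v for k, v in self.params.items()},
        )


# ---------------------------------------------------------------------------
# functional wrappers and calibration


def fit_linear(X, Y, channel_spec: ChannelSpec | None = None) -> LinearCOPResults:
    return LinearCOP(X, Y, channel_spec=channel_spec).fit()


def fit_lstm(windows, Y, config: TrainConfig | None = None, channel_spec=None) -> LSTMCOPResults:
    return LSTMCOP(windows, Y, config=config, channel_spec=channel_spec).fit()


def fine_tune(results, calib_X, calib_Y, config: TrainConfig | None = None):
    """Subject-calibration update from a short standing recording.

    Linear results: refit on the pooled original + calibration rows with
    the calibration upweighted (default 10×).  LSTM results: continue Adam
    training on the calibration windows only, at ``finetune_lr_factor`` ×
    the base learning rate, for at most ``finetune_max_epochs`` epochs under
    the same patience rule.  Empty calibration returns the results unchanged.
    """
    calib_X = np.asarray(calib_X, dtype=float)
    calib_Y = np.asarray(calib_Y, dtype=float)
    if calib_X.shape[0] == 0:
        return results

    if isinstance(results, LinearCOPResults):
        cfg = config or TrainConfig()
        if calib_X.ndim != 2 or calib_X.shape[1] != results.weights.shape[0]:
            raise ValueError("calibration layout does not match the model")
        X0, Y0 = results.model.X, results.model.Y
        X = np.vstack([X0, calib_X])
        Y = np.vstack([Y0, calib_Y])
        w = np.concatenate(
            [np.ones(X0.shape[0]), np.full(calib_X.shape[0], cfg.calib_weight)]
        )
        return LinearCOP(X, Y, channel_spec=results.channel_spec).fit(sample_weight=w)

    if isinstance(results, LSTMCOPResults):
        base_cfg = config or results.config
        if calib_X.ndim != 3 or calib_X.shape[2] != results.params["Wx"].shape[0]:
            raise ValueError("calibration layout does not match the model")
        cfg = replace(
            base_cfg,
            learning_rate=base_cfg.learning_rate * base_cfg.finetune_lr_factor,
            max_epochs=base_cfg.finetune_max_epochs,
        )
        Wn = (calib_X - results.x_mu) / results.x_sd
        Yn = (calib_Y - results.y_mu) / results.y_sd
        n = Wn.shape[0]
        rng = np.random.default_rng(cfg.seed)
        params = results.params.copy()
        opt = _lstm.AdamState(params, cfg.learning_rate)

        def _calib_loss(p):
            return float(np.mean((_lstm.forward(p, Wn) - Yn) ** 2))

        # the pre-tune model is the fallback: fine-tuning never ends with a
        # model worse on the calibration set than the one it started from
        best_loss = _calib_loss(params)
        best_params, stale, trace = params.copy(), 0, []
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                pred, cache = _lstm.forward(params, Wn[idx], cache=True)
                err = pred - Yn[idx]
                if not np.isfinite(err).all():
                    raise FloatingPointError("fine-tuning diverged (NaN/inf loss)")
                grads = _lstm.backward(params, cache, 2.0 * err / err.size)
                _lstm.adam_step(params, grads, opt)
            epoch_loss = _calib_loss(params)
            trace.append(epoch_loss)
            if epoch_loss < best_loss - 1e-12:
                best_loss, best_params, stale = epoch_loss, params.copy(), 0
            else:
                stale += 1
                if stale >= base_cfg.patience:
                    break
        return LSTMCOPResults(
            results.model,
            best_params,
            (results.x_mu, results.x_sd),
            (results.y_mu, results.y_sd),
            results.loss_trace + trace,
            config=results.config,
        )

    raise TypeError(f"cannot fine-tune object of type {type(results).__name__}")


def load_results(path):
    """Reload a saved results container (bit-exact weights)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        spec = meta.get("channel_spec")
        spec = ChannelSpec.from_dict(spec) if spec else None
        if meta["kind"] == "linear":
            model = LinearCOP(data["X"], data["Y"], channel_spec=spec)
            return LinearCOPResults(model, data["weights"], data["intercept"])
        if meta["kind"] == "lstm":
            params = _lstm.LstmParams(
                {k[2:]: data[k] for k in data.files if k.startswith("p_")}
            )
            cfg = TrainConfig(**meta["config"])

            class _Stub:
                windows = np.zeros((1, 1, params["Wx"].shape[0]))
                channel_spec = spec

            return LSTMCOPResults(
                _Stub(),
                params,
                (data["x_mu"], data["x_sd"]),
                (data["y_mu"], data["y_sd"]),
                list(data["loss_trace"]),
                config=cfg,
            )
    raise ValueError("unrecognized model container")
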