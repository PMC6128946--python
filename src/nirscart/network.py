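"""Shallow neural-network regression trained with Levenberg-Marquardt.

The model is a single hidden layer of at most eight tanh units with a linear
output, trained full-batch by damped Gauss-Newton: each epoch solves
``(J^T J + mu I) dw = J^T e`` for the weight update, where ``J`` is the
model Jacobian and ``e`` the residual vector; ``mu`` shrinks after accepted
steps and grows on rejections, interpolating between Newton and gradient
descent. Training halts early once validation error has failed to reach a
new minimum for six consecutive epochs, and the best-validation weights are
kept. Inputs and targets are min-max scaled to [-1, 1] using the calibration
set only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

MAX_HIDDEN = 8


@dataclass
class ShallowNet:
    """Weight container for a 1-hidden-layer scalar-output network."""

    W: np.ndarray       # (n_hidden, n_inputs)
    b_h: np.ndarray     # (n_hidden,)
    w_out: np.ndarray   # (n_hidden,)
    b_out: float
    activation: str = "tanh"  # "identity" supported for optimizer verification

    @property
    def n_weights(self) -> int:
        return self.W.size + self.b_h.size + self.w_out.size + 1

    def _act(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Activation and its derivative."""
        if self.activation == "tanh":
            a = np.tanh(z)
            return a, 1.0 - a**2
        if self.activation == "identity":
            return z, np.ones_like(z)
        raise ValueError(f"unknown activation {self.activation!r}")

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Scaled-space prediction: w_out . act(W x + b_h) + b_out."""
        X = np.atleast_2d(X)
        if X.shape[1] != self.W.shape[1]:
            raise ValueError(
                f"input dimension {X.shape[1]} != network inputs {self.W.shape[1]}"
            )
        a, _ = self._act(X @ self.W.T + self.b_h)
        return a @ self.w_out + self.b_out

    def jacobian(self, X: np.ndarray) -> np.ndarray:
        """Model Jacobian d f(x_i) / d w, rows = samples, columns = weights
        in flatten() order."""
        X = np.atleast_2d(X)
        z = X @ self.W.T + self.b_h
        a, da = self._act(z)
        g_hidden = da * self.w_out  # (n, h): d f / d z_j
        # d f / d W_jk = g_hidden_j * x_k
        dW = g_hidden[:, :, None] * X[:, None, :]
        n = X.shape[0]
        return np.concatenate(
            [dW.reshape(n, -1), g_hidden, a, np.ones((n, 1))], axis=1
        )

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.W.ravel(), self.b_h, self.w_out, [self.b_out]]
        )

    def with_weights(self, flat: np.ndarray) -> "ShallowNet":
        h, d = self.W.shape
        W = flat[: h * d].reshape(h, d)
        b_h = flat[h * d : h * d + h]
        w_out = flat[h * d + h : h * d + 2 * h]
        return ShallowNet(
            W=W.copy(), b_h=b_h.copy(), w_out=w_out.copy(),
            b_out=float(flat[-1]), activation=self.activation,
        )


def nguyen_widrow_init(
    n_inputs: int, n_hidden: int, rng: np.random.Generator, activation: str = "tanh"
) -> ShallowNet:
    """Nguyen-Widrow-style initialisation: hidden-unit hyperplanes with
    magnitude 0.7 h^(1/d) spread across the [-1, 1] input cube."""
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, n_inputs))
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    scale = 0.7 * n_hidden ** (1.0 / max(n_inputs, 1))
    W = scale * W / norms
    b_h = scale * rng.uniform(-1.0, 1.0, size=n_hidden)
    w_out = rng.uniform(-0.5, 0.5, size=n_hidden)
    return ShallowNet(W=W, b_h=b_h, w_out=w_out, b_out=0.0, activation=activation)


def sse(net: ShallowNet, X: np.ndarray, y: np.ndarray) -> float:
    r = y - net.forward(X)
    return float(r @ r)


def lm_step(
    net: ShallowNet,
    X: np.ndarray,
    y: np.ndarray,
    mu: float,
    mu_up: float = 10.0,
    mu_down: float = 0.1,
    mu_cap: float = 1e10,
) -> tuple[ShallowNet, float, bool]:
    """One Levenberg-Marquardt epoch.

    Solves (J^T J + mu I) dw = J^T e; the step is accepted only if training
    SSE decreases, otherwise mu is inflated and the solve retried until the
    damping cap is hit. Returns (new_net, new_mu, accepted).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    J = net.jacobian(X)
    e = y - net.forward(X)
    base = sse(net, X, y)
    JtJ = J.T @ J
    Jte = J.T @ e
    eye = np.eye(JtJ.shape[0])
    while mu <= mu_cap:
        try:
            dw = np.linalg.solve(JtJ + mu * eye, Jte)
        except np.linalg.LinAlgError:
            mu *= mu_up
            continue
        cand = net.with_weights(net.flatten() + dw)
        if sse(cand, X, y) < base or base == 0.0:
            return cand, max(mu * mu_down, 1e-300), True
        mu *= mu_up
    return net, mu, False


@dataclass
class FitResult:
    """Serializable record of one trained network."""

    weights: dict
    n_hidden: int
    epochs_run: int
    stop_reason: str
    train_sse: list[float]
    val_sse: list[float]
    scaling: dict
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights,
                "n_hidden": self.n_hidden,
                "epochs_run": self.epochs_run,
                "stop_reason": self.stop_reason,
                "train_sse": self.train_sse,
                "val_sse": self.val_sse,
                "scaling": self.scaling,
                "config": self.config,
            },
            indent=1,
        )

    @staticmethod
    def from_json(text: str) -> "FitResult":
        d = json.loads(text)
        return FitResult(**d)


class _MinMaxScaler:
    """Min-max scaling to [-1, 1]; constant columns map to 0."""

    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        span = self.hi - self.lo
        self.span = np.where(span > 0, span, 1.0)

    @staticmethod
    def fit(values: np.ndarray) -> "_MinMaxScaler":
        values = np.atleast_2d(values)
        return _MinMaxScaler(values.min(axis=0), values.max(axis=0))

    def transform(self, values: np.ndarray) -> np.ndarray:
        return 2.0 * (values - self.lo) / self.span - 1.0

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        return (scaled + 1.0) / 2.0 * self.span + self.lo


class LMRegressor(RegressorMixin, BaseEstimator):
    """Single-hidden-layer tanh network trained with Levenberg-Marquardt.

    Parameters
    ----------
    n_hidden : int, default 4
        Hidden units (1..8).
    max_epochs : int, default 200
        Full-batch LM epochs per restart.
    mu_init, mu_up, mu_down, mu_cap : float
        Damping schedule: initial value, inflation factor on rejection,
        shrink factor on acceptance, and overflow cap.
    max_val_failures : int, default 6
        Early stop after this many consecutive epochs without a new
        validation-SSE minimum.
    n_restarts : int, default 3
        Independent seeded initialisations; the restart with the lowest
        validation SSE wins.
    random_state : int or None
        Seed for the initialisations.

    A validation set may be passed to :meth:`fit`; without one the training
    set doubles as validation (early stopping then only guards against
    damping stagnation).
    """

    def __init__(
        self,
        n_hidden: int = 4,
        max_epochs: int = 200,
        mu_init: float = 1e-3,
        mu_up: float = 10.0,
        mu_down: float = 0.1,
        mu_cap: float = 1e10,
        max_val_failures: int = 6,
        n_restarts: int = 3,
        random_state: int | None = None,
    ):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.mu_init = mu_init
        self.mu_up = mu_up
        self.mu_down = mu_down
        self.mu_cap = mu_cap
        self.max_val_failures = max_val_failures
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(X, y, y_numeric=True)
        if not 1 <= self.n_hidden <= MAX_HIDDEN:
            raise ValueError(f"n_hidden must be in 1..{MAX_HIDDEN}")
        if self.mu_up <= 1.0 or not 0.0 < self.mu_down < 1.0:
            raise ValueError("require mu_up > 1 and 0 < mu_down < 1")
        if X_val is None:
            X_val, y_val = X, y
        else:
            X_val, y_val = check_X_y(X_val, y_val, y_numeric=True)

        self.x_scaler_ = _MinMaxScaler.fit(X)
        self.y_scaler_ = _MinMaxScaler.fit(y.reshape(-1, 1))
        self.n_features_in_ = X.shape[1]

        if np.ptp(y) == 0.0:
            warnings.warn("degenerate targets (zero variance); constant predictor")
            self.constant_value_ = float(y[0])
            self.net_ = ShallowNet(
                W=np.zeros((self.n_hidden, X.shape[1])),
                b_h=np.zeros(self.n_hidden),
                w_out=np.zeros(self.n_hidden),
                b_out=0.0,
            )
            self.n_epochs_ = 0
            self.stop_reason_ = "degenerate_targets"
            self.train_sse_, self.val_sse_ = [], []
            self._record_result()
            return self

        self.constant_value_ = None
        Xs = self.x_scaler_.transform(X)
        ys = self.y_scaler_.transform(y.reshape(-1, 1)).ravel()
        Xv = self.x_scaler_.transform(X_val)
        yv = self.y_scaler_.transform(np.asarray(y_val).reshape(-1, 1)).ravel()

        ss = np.random.SeedSequence(self.random_state)
        best = None
        for child in ss.spawn(max(1, self.n_restarts)):
            rng = np.random.default_rng(child)
            run = self._train_once(Xs, ys, Xv, yv, rng)
            if best is None or run["best_val"] < best["best_val"]:
                best = run
        self.net_ = best["net"]
        self.n_epochs_ = best["epochs"]
        self.stop_reason_ = best["stop_reason"]
        self.train_sse_ = best["train_sse"]
        self.val_sse_ = best["val_sse"]
        self._record_result()
        return self

    def _train_once(self, Xs, ys, Xv, yv, rng):
        net = nguyen_widrow_init(Xs.shape[1], self.n_hidden, rng)
        mu = self.mu_init
        # epoch 1 always establishes the first validation minimum; the
        # failure counter tracks epochs without a new minimum thereafter
        best_net, best_val = net, np.inf
        failures = 0
        train_traj, val_traj = [], []
        stop_reason = "max_epochs"
        epochs = 0
        for _ in range(self.max_epochs):
            net, mu, accepted = lm_step(
                net, Xs, ys, mu, self.mu_up, self.mu_down, self.mu_cap
            )
            epochs += 1
            train_traj.append(sse(net, Xs, ys))
            v = sse(net, Xv, yv)
            val_traj.append(v)
            if v < best_val:
                best_val, best_net, failures = v, net, 0
            else:
                failures += 1
            if not accepted:
                stop_reason = "mu_overflow"
                break
            if failures >= self.max_val_failures:
                stop_reason = "val_failures"
                break
        return {
            "net": best_net,
            "best_val": best_val,
            "epochs": epochs,
            "stop_reason": stop_reason,
            "train_sse": train_traj,
            "val_sse": val_traj,
        }

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X)
        if self.constant_value_ is not None:
            return np.full(X.shape[0], self.constant_value_)
        ys = self.net_.forward(self.x_scaler_.transform(X))
        return self.y_scaler_.inverse(ys.reshape(-1, 1)).ravel()

    def _record_result(self):
        self.fit_result_ = FitResult(
            weights={
                "W": self.net_.W.tolist(),
                "b_h": self.net_.b_h.tolist(),
                "w_out": self.net_.w_out.tolist(),
                "b_out": self.net_.b_out,
            },
            n_hidden=self.n_hidden,
            epochs_run=self.n_epochs_,
            stop_reason=self.stop_reason_,
            train_sse=list(map(float, self.train_sse_)),
            val_sse=list(map(float, self.val_sse_)),
            scaling={
                "x_lo": self.x_scaler_.lo.tolist(),
                "x_hi": self.x_scaler_.hi.tolist(),
                "y_lo": self.y_scaler_.lo.tolist(),
                "y_hi": self.y_scaler_.hi.tolist(),
            },
            config=self.get_params(),
        )


def train(
    X_cal, y_cal, X_val, y_val, n_hidden: int = 4, random_state: int | None = None, **kwargs
) -> LMRegressor:
    """Convenience wrapper: fit an :class:`LMRegressor` with an explicit
    pony-disjoint validation set."""
    est = LMRegressor(n_hidden=n_hidden, random_state=random_state, **kwargs)
    return est.fit(X_cal, y_cal, X_val=X_val, y_val=y_val)
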