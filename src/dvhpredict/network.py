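"""Three-layer sigmoid feedforward network trained by the online delta rule.

The network maps the scaled geometry features (P, L, S) to the four scaled
dose-volume outputs through a single hidden layer (default width 6, i.e. the
3-6-4 topology).  Both layers use the logistic sigmoid; net input is
``sum(w·activation) - threshold``.  Training is plain online backpropagation:
for each sample the output-node error is

    delta_j = yhat_j (1 - yhat_j) (y_j - yhat_j)

and the hidden-node error is the sigmoid-weighted backpropagated sum
``delta_j = yhat_j (1 - yhat_j) sum_k w_jk delta_k``; weights move by
``eta * delta_j * upstream_activation`` and thresholds by ``-eta * delta_j``.
These deltas are exactly the negative gradient of the half squared error with
respect to each node's net input, which the test suite verifies against
central finite differences.  Epochs stop when the epoch-level mean squared
error over samples and outputs drops to the target (default 1e-5) or the
epoch cap is reached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dvhpredict.preprocessing import ScalingParams, scale_features

N_INPUT = 3
N_HIDDEN = 6
N_OUTPUT = 4


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class NetworkParams:
    """All weights and thresholds; 52 free parameters at the default 3-6-4 size."""

    w_ih: np.ndarray  # (n_input, n_hidden)
    b_h: np.ndarray  # (n_hidden,)
    w_ho: np.ndarray  # (n_hidden, n_output)
    b_o: np.ndarray  # (n_output,)

    def __post_init__(self) -> None:
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.w_ho = np.asarray(self.w_ho, dtype=float)
        self.b_o = np.asarray(self.b_o, dtype=float)
        if not all(np.all(np.isfinite(a)) for a in (self.w_ih, self.b_h, self.w_ho, self.b_o)):
            raise ValueError("network parameters must be finite")

    @property
    def topology(self) -> tuple[int, int, int]:
        return (self.w_ih.shape[0], self.w_ih.shape[1], self.w_ho.shape[1])

    @property
    def flat_length(self) -> int:
        n_in, n_hid, n_out = self.topology
        return (n_in + 1) * n_hid + (n_hid + 1) * n_out

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.w_ih.ravel(), self.b_h, self.w_ho.ravel(), self.b_o])

    @classmethod
    def unflatten(
        cls, flat: np.ndarray, topology: tuple[int, int, int] = (N_INPUT, N_HIDDEN, N_OUTPUT)
    ) -> "NetworkParams":
        n_in, n_hid, n_out = topology
        flat = np.asarray(flat, dtype=float)
        expected = (n_in + 1) * n_hid + (n_hid + 1) * n_out
        if flat.shape != (expected,):
            raise ValueError(f"flat parameter vector must have length {expected}")
        i = 0
        w_ih = flat[i : i + n_in * n_hid].reshape(n_in, n_hid); i += n_in * n_hid
        b_h = flat[i : i + n_hid]; i += n_hid
        w_ho = flat[i : i + n_hid * n_out].reshape(n_hid, n_out); i += n_hid * n_out
        b_o = flat[i : i + n_out]
        return cls(w_ih=w_ih.copy(), b_h=b_h.copy(), w_ho=w_ho.copy(), b_o=b_o.copy())

    @classmethod
    def zeros(cls, topology: tuple[int, int, int] = (N_INPUT, N_HIDDEN, N_OUTPUT)) -> "NetworkParams":
        n_in, n_hid, n_out = topology
        return cls(
            w_ih=np.zeros((n_in, n_hid)),
            b_h=np.zeros(n_hid),
            w_ho=np.zeros((n_hid, n_out)),
            b_o=np.zeros(n_out),
        )

    @classmethod
    def random(
        cls,
        seed: int | np.random.Generator,
        topology: tuple[int, int, int] = (N_INPUT, N_HIDDEN, N_OUTPUT),
        half_width: float = 0.5,
    ) -> "NetworkParams":
        """Uniform initialization on [-half_width, half_width] (plain-BP default)."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n_in, n_hid, n_out = topology
        flat = rng.uniform(-half_width, half_width, (n_in + 1) * n_hid + (n_hid + 1) * n_out)
        return cls.unflatten(flat, topology)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            w_ih=self.w_ih.copy(), b_h=self.b_h.copy(),
            w_ho=self.w_ho.copy(), b_o=self.b_o.copy(),
        )


@dataclass
class TrainConfig:
    """Online-backpropagation settings (learning rate 0.1, target error 1e-5)."""

    eta: float = 0.1
    target_error: float = 1e-5
    max_epochs: int = 10_000
    shuffle_seed: int = 0

    def validate(self) -> None:
        if not self.eta > 0:
            raise ValueError("eta must be positive")
        if not self.target_error > 0:
            raise ValueError("target_error must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")


@dataclass
class TrainingState:
    t: int
    epoch_mse: list[float] = field(default_factory=list)
    converged: bool = False


def forward(params: NetworkParams, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-sample forward pass; returns (hidden, output) activations."""
    x = np.asarray(x, dtype=float)
    hidden = _sigmoid(x @ params.w_ih - params.b_h)
    output = _sigmoid(hidden @ params.w_ho - params.b_o)
    return hidden, output


def forward_batch(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Output activations for a matrix of samples (rows)."""
    hidden = _sigmoid(np.asarray(X, dtype=float) @ params.w_ih - params.b_h)
    return _sigmoid(hidden @ params.w_ho - params.b_o)


def mse(params: NetworkParams, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean squared error averaged over samples and output nodes."""
    diff = forward_batch(params, X) - np.asarray(Y, dtype=float)
    return float(np.mean(diff**2))


def delta_errors(
    params: NetworkParams,
    hidden: np.ndarray,
    output: np.ndarray,
    target: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-rule node errors for one sample.

    Output node: ``delta = yhat (1-yhat) (y - yhat)``; hidden node:
    ``delta = yhat (1-yhat) sum_k w_jk delta_k``.  Each delta equals the
    negative gradient of the half squared error with respect to that node's
    net input.
    """
    target = np.asarray(target, dtype=float)
    if output.shape != target.shape or hidden.shape[0] != params.w_ho.shape[0]:
        raise ValueError("activation/target dimensions do not match the network")
    delta_out = output * (1.0 - output) * (target - output)
    delta_hidden = hidden * (1.0 - hidden) * (params.w_ho @ delta_out)
    return delta_out, delta_hidden


def update_step(
    params: NetworkParams, x: np.ndarray, target: np.ndarray, eta: float
) -> NetworkParams:
    """One online update on a single sample; returns new parameters."""
    if not eta > 0:
        raise ValueError("eta must be positive")
    x = np.asarray(x, dtype=float)
    hidden, output = forward(params, x)
    delta_out, delta_hidden = delta_errors(params, hidden, output, target)
    new = params.copy()
    new.w_ho += eta * np.outer(hidden, delta_out)
    new.b_o -= eta * delta_out
    new.w_ih += eta * np.outer(x, delta_hidden)
    new.b_h -= eta * delta_hidden
    return new


def train(
    params0: NetworkParams, X: np.ndarray, Y: np.ndarray, cfg: TrainConfig
) -> tuple[NetworkParams, TrainingState]:
    """Online backpropagation over shuffled epochs until the MSE target or cap."""
    cfg.validate()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("training set must be a nonempty 2-d matrix")
    if len(X) != len(Y):
        raise ValueError("X and Y must have the same number of rows")
    rng = np.random.default_rng(cfg.shuffle_seed)

    # in-place arrays for the hot loop; copied back into NetworkParams at exit
    w_ih = params0.w_ih.copy()
    b_h = params0.b_h.copy()
    w_ho = params0.w_ho.copy()
    b_o = params0.b_o.copy()
    eta = cfg.eta

    state = TrainingState(t=0)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X))
        for i in order:
            x = X[i]
            hidden = _sigmoid(x @ w_ih - b_h)
            output = _sigmoid(hidden @ w_ho - b_o)
            delta_out = output * (1.0 - output) * (Y[i] - output)
            delta_hidden = hidden * (1.0 - hidden) * (w_ho @ delta_out)
            w_ho += eta * np.outer(hidden, delta_out)
            b_o -= eta * delta_out
            w_ih += eta * np.outer(x, delta_hidden)
            b_h -= eta * delta_hidden
        state.t = epoch + 1
        hid = _sigmoid(X @ w_ih - b_h)
        out = _sigmoid(hid @ w_ho - b_o)
        epoch_mse = float(np.mean((out - Y) ** 2))
        state.epoch_mse.append(epoch_mse)
        if epoch_mse <= cfg.target_error:
            state.converged = True
            break
    params = NetworkParams(w_ih=w_ih, b_h=b_h, w_ho=w_ho, b_o=b_o)
    return params, state


def predict(
    params: NetworkParams, scaler: ScalingParams, raw_features: np.ndarray
) -> np.ndarray:
    """Dose-volume predictions in percent for raw (P, L, S) rows.

    Scales the features with the training-fold scaler, runs the forward pass
    and maps the sigmoid outputs back to the percent scale.
    """
    if scaler is None:
        raise ValueError("a fitted ScalingParams is required")
    x = scale_features(raw_features, scaler)
    out = forward_batch(params, x)
    return out * scaler.outcome_divisor


def save_model(
    params: NetworkParams, scaler: ScalingParams, path: str | Path, seed: int | None = None
) -> None:
    """Bit-exact JSON serialization of the model (topology, parameters, scaler)."""
    doc = {
        "topology": list(params.topology),
        "weights": {
            "w_ih": params.w_ih.tolist(),
            "w_ho": params.w_ho.tolist(),
        },
        "thresholds": {"b_h": params.b_h.tolist(), "b_o": params.b_o.tolist()},
        "scaler": scaler.to_dict(),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> tuple[NetworkParams, ScalingParams, int | None]:
    doc = json.loads(Path(path).read_text())
    params = NetworkParams(
        w_ih=np.asarray(doc["weights"]["w_ih"], dtype=float),
        b_h=np.asarray(doc["thresholds"]["b_h"], dtype=float),
        w_ho=np.asarray(doc["weights"]["w_ho"], dtype=float),
        b_o=np.asarray(doc["thresholds"]["b_o"], dtype=float),
    )
    scaler = ScalingParams.from_dict(doc["scaler"])
    return params, scaler, doc.get("seed")
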