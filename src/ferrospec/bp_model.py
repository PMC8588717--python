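"""Back-propagation regression network (5-3-1) with momentum, plus dataset
splitting and accuracy evaluation.

The regressor is a classic fully-connected feed-forward network: a tanh
hidden layer and a linear output, trained by full-batch gradient descent
with an additional momentum term.  Inputs and targets are min-max scaled to
[-1, 1] before training (tanh saturates otherwise) and predictions are
inverse-scaled back to g/kg.  Training is deterministic given the seed.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import SpectralDataset

__all__ = [
    "BPConfig",
    "TrainedBPModel",
    "EvalReport",
    "SPLIT_SCHEMES",
    "split_dataset",
    "train_bp",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]

#: Train counts per soil stratum: (expected total, training samples).
SPLIT_SCHEMES = {
    "loessial": (51, 35),
    "sandy": (33, 20),
    "mixed": (84, 45),
}


@dataclass
class BPConfig:
    """Training hyperparameters of the back-propagation network.

    ``topology`` is (inputs, hidden, outputs); the default 5-3-1 takes the
    five PCA scores.  ``goal_mse`` is the early-stopping target on the
    scaled ([-1, 1]) training MSE.
    """

    topology: tuple[int, int, int] = (5, 3, 1)
    max_iterations: int = 2000
    learning_rate: float = 0.01
    momentum: float = 0.9
    goal_mse: float = 0.001
    seed: int = 0
    r2_mode: str = "pearson"  # or "sse" for 1 - SSE/SST

    def __post_init__(self) -> None:
        if min(self.topology) < 1 or len(self.topology) != 3 or self.topology[2] != 1:
            raise ValueError("topology must be (n_inputs, n_hidden, 1)")
        if self.max_iterations < 1 or self.learning_rate <= 0 or self.goal_mse <= 0:
            raise ValueError("hyperparameters must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass
class TrainedBPModel:
    """Fitted network: weights, scalers and the training-loss trace."""

    config: BPConfig
    w_hidden: np.ndarray   # (n_hidden, n_inputs)
    b_hidden: np.ndarray   # (n_hidden,)
    w_out: np.ndarray      # (n_hidden,)
    b_out: float
    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    loss_trace: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class EvalReport:
    """Accuracy metrics between measured and predicted TICS.

    R^2 is the squared Pearson correlation of measured vs predicted (the
    measured-vs-estimated scatter-fit convention); RMSE and MAE are in g/kg.
    MAE <= RMSE always (power-mean inequality).
    """

    r_squared: float
    rmse: float
    mae: float
    n: int
    r2_undefined: bool = False


def split_dataset(
    dataset: SpectralDataset,
    scheme: str = "per-soil",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/test split with the per-stratum counts.

    ``per-soil`` splits each soil type separately with its stated counts
    (loessial 51 -> 35 train, sandy 33 -> 20 train); ``pooled`` treats the
    whole dataset as mixed soil (84 -> 45 train).  If a stratum's size
    differs from the expected total, the stated training *fraction* is used
    instead, with a warning.  Returns (train_indices, test_indices), sorted,
    disjoint and jointly exhaustive.
    """
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    if scheme == "pooled":
        groups = [("mixed", np.arange(n))]
    elif scheme == "per-soil":
        labels = np.asarray(dataset.soil_type)
        groups = [(lbl, np.flatnonzero(labels == lbl)) for lbl in pd_unique(labels)]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    train_parts, test_parts = [], []
    for label, idx in groups:
        expected, n_train = SPLIT_SCHEMES.get(str(label), SPLIT_SCHEMES["mixed"])
        if idx.size != expected:
            frac = n_train / expected
            n_train_here = int(round(idx.size * frac))
            warnings.warn(
                f"{label}: {idx.size} samples instead of {expected}; "
                f"using proportional training fraction {frac:.3f} -> {n_train_here}",
                stacklevel=2,
            )
        else:
            n_train_here = n_train
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train_here])
        test_parts.append(perm[n_train_here:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


def pd_unique(values: np.ndarray) -> list:
    """Unique labels in order of first appearance."""
    seen: dict = {}
    for v in values:
        seen.setdefault(v, None)
    return list(seen)


def _minmax_scale(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def train_bp(features: np.ndarray, targets: np.ndarray, config: BPConfig | None = None) -> TrainedBPModel:
    """Train the network by full-batch gradient descent with momentum.

    Stops at ``max_iterations`` or when the scaled-space training MSE drops
    to ``goal_mse``.  Weight initialisation is seeded uniform in
    [-0.5, 0.5], so identical (data, config) pairs give bitwise-identical
    loss traces.
    """
    if config is None:
        config = BPConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("features must be (n, d) with matching target length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("features/targets must be finite")
    n, d = x.shape
    n_in, n_hidden, _ = config.topology
    if d != n_in:
        raise ValueError(f"feature width {d} does not match topology input {n_in}")
    if n < 10:
        raise ValueError("need at least 10 training samples")

    x_min, x_max = x.min(axis=0), x.max(axis=0)
    span = x_max - x_min
    if np.any(span == 0):
        raise ValueError("constant feature column: scaling not invertible")
    y_min, y_max = float(y.min()), float(y.max())
    if y_max == y_min:
        # constant target: widen the scaling window symmetrically so the
        # inverse transform stays defined
        y_min, y_max = y_min - 0.5, y_max + 0.5
    xs = _minmax_scale(x, x_min, x_max)
    ys = _minmax_scale(y, y_min, y_max)

    rng = np.random.default_rng(config.seed)
    w1 = rng.uniform(-0.5, 0.5, size=(n_hidden, n_in))
    b1 = rng.uniform(-0.5, 0.5, size=n_hidden)
    w2 = rng.uniform(-0.5, 0.5, size=n_hidden)
    b2 = float(rng.uniform(-0.5, 0.5))

    vw1 = np.zeros_like(w1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = 0.0
    lr, mom = config.learning_rate, config.momentum
    trace = np.empty(config.max_iterations)
    n_done = 0
    for it in range(config.max_iterations):
        hidden = np.tanh(xs @ w1.T + b1)            # (n, h)
        pred = hidden @ w2 + b2                     # (n,)
        err = pred - ys
        loss = float(np.mean(err ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (NaN/inf loss) at iteration {it}; "
                "try a lower learning_rate"
            )
        trace[it] = loss
        n_done = it + 1
        if loss <= config.goal_mse:
            break
        g_out = 2.0 * err / n                       # dL/dpred
        gw2 = hidden.T @ g_out
        gb2 = float(np.sum(g_out))
        g_hidden = np.outer(g_out, w2) * (1.0 - hidden ** 2)
        gw1 = g_hidden.T @ xs
        gb1 = g_hidden.sum(axis=0)
        vw1 = mom * vw1 - lr * gw1
        vb1 = mom * vb1 - lr * gb1
        vw2 = mom * vw2 - lr * gw2
        vb2 = mom * vb2 - lr * gb2
        w1 += vw1
        b1 += vb1
        w2 += vw2
        b2 += vb2

    return TrainedBPModel(
        config=config,
        w_hidden=w1,
        b_hidden=b1,
        w_out=w2,
        b_out=b2,
        x_min=x_min,
        x_max=x_max,
        y_min=y_min,
        y_max=y_max,
        loss_trace=trace[:n_done].copy(),
    )


def predict(model: TrainedBPModel, features: np.ndarray) -> np.ndarray:
    """Forward pass, inverse-scaled to g/kg."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != model.w_hidden.shape[1]:
        raise ValueError(
            f"feature width {x.shape[1]} does not match model input "
            f"{model.w_hidden.shape[1]}"
        )
    xs = _minmax_scale(x, model.x_min, model.x_max)
    hidden = np.tanh(xs @ model.w_hidden.T + model.b_hidden)
    ys = hidden @ model.w_out + model.b_out
    return (ys + 1.0) / 2.0 * (model.y_max - model.y_min) + model.y_min


def evaluate(measured: np.ndarray, predicted: np.ndarray, r2_mode: str = "pearson") -> EvalReport:
    """RMSE, MAE and R^2 between measured and predicted values.

    ``RMSE = sqrt(sum (y - yhat)^2 / n)``; ``MAE = (1/n) sum |y - yhat|``;
    R^2 is the squared Pearson correlation (``r2_mode="pearson"``, default)
    or the 1 - SSE/SST coefficient of determination (``r2_mode="sse"``).
    Zero variance in either vector makes the correlation undefined; the
    report then carries R^2 = 0 with ``r2_undefined`` set.
    """
    y = np.asarray(measured, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size != yhat.size:
        raise ValueError("measured and predicted must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    undefined = False
    if r2_mode == "pearson":
        sy, syh = y.std(), yhat.std()
        if sy == 0 or syh == 0:
            r2, undefined = 0.0, True
        else:
            r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    elif r2_mode == "sse":
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            r2, undefined = 0.0, True
        else:
            r2 = 1.0 - float(np.sum(err ** 2)) / sst
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return EvalReport(r_squared=r2, rmse=rmse, mae=mae, n=int(y.size), r2_undefined=undefined)


def save_model(model: TrainedBPModel, path: str | os.PathLike) -> None:
    """Serialise a trained model as structured text (JSON)."""
    payload = {
        "config": {
            "topology": list(model.config.topology),
            "max_iterations": model.config.max_iterations,
            "learning_rate": model.config.learning_rate,
            "momentum": model.config.momentum,
            "goal_mse": model.config.goal_mse,
            "seed": model.config.seed,
            "r2_mode": model.config.r2_mode,
        },
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out,
        "x_min": model.x_min.tolist(),
        "x_max": model.x_max.tolist(),
        "y_min": model.y_min,
        "y_max": model.y_max,
        "loss_trace": model.loss_trace.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str | os.PathLike) -> TrainedBPModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    cfg["topology"] = tuple(cfg["topology"])
    return TrainedBPModel(
        config=BPConfig(**cfg),
        w_hidden=np.array(payload["w_hidden"]),
        b_hidden=np.array(payload["b_hidden"]),
        w_out=np.array(payload["w_out"]),
        b_out=float(payload["b_out"]),
        x_min=np.array(payload["x_min"]),
        x_max=np.array(payload["x_max"]),
        y_min=float(payload["y_min"]),
        y_max=float(payload["y_max"]),
        loss_trace=np.array(payload["loss_trace"]),
    )
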