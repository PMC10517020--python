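"""Basic and denoising autoencoders (zero-masking and additive Gaussian).

A single-hidden-layer (bottleneck) autoencoder trained with Adam on mean
squared reconstruction error of the *clean* matrix from a corrupted input;
corruption is resampled every epoch. Early stopping monitors validation loss
with a fixed patience and restores the best weights. Implemented directly on
numpy so training is single-threaded and bit-deterministic given the seed.

Hidden activation is configurable (relu / tanh / sigmoid); the output layer
is linear since inputs are z-scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZEROS_LEVELS = (0.2, 0.3, 0.4)
GAUSSIAN_LEVELS = (0.5, 1.0, 1.5)
ACTIVATIONS = ("relu", "tanh", "sigmoid")

#: Late-integration bottleneck widths (sum matches the early 160).
LATE_BOTTLENECKS = {"mrna": 50, "methylation": 50, "mirna": 30, "lncrna": 30}
EARLY_BOTTLENECK = 160


@dataclass(frozen=True)
class EncoderSpec:
    input_dim: int
    bottleneck_dim: int
    activation: str = "sigmoid"
    noise_type: str = "zeros"  # none | zeros | gaussian
    noise_level: float = 0.3
    learning_rate: float = 0.001
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.bottleneck_dim >= self.input_dim:
            raise ValueError("bottleneck_dim must be smaller than input_dim")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.noise_type not in ("none", "zeros", "gaussian"):
            raise ValueError(f"unknown noise_type {self.noise_type!r}")
        if self.noise_type == "zeros" and not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("zeros noise_level must be a fraction in [0, 1]")
        if self.noise_type == "gaussian" and self.noise_level < 0:
            raise ValueError("gaussian noise_level (SD) must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def early_integration_spec(input_dim: int = 1600,
                           bottleneck_dim: int = EARLY_BOTTLENECK,
                           **kw) -> EncoderSpec:
    return EncoderSpec(input_dim=input_dim, bottleneck_dim=bottleneck_dim, **kw)


def late_integration_spec(modality: str, input_dim: int | None = None, **kw) -> EncoderSpec:
    bottleneck = LATE_BOTTLENECKS[modality]
    if input_dim is None:
        input_dim = bottleneck * 10  # 500-50-500 / 300-30-300 defaults
    return EncoderSpec(input_dim=input_dim, bottleneck_dim=bottleneck, **kw)


@dataclass
class TrainedEncoder:
    spec: EncoderSpec
    weights: dict[str, np.ndarray]
    training_history: pd.DataFrame  # epoch, train_loss, val_loss
    stopped_epoch: int


# --------------------------------------------------------------------------
# corruption


def corrupt_zeros(matrix: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Return a copy with each entry independently zeroed with probability
    ``fraction``; the input is never modified."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.array(matrix, dtype=float, copy=True)
    mask = rng.random(out.shape) < fraction
    out[mask] = 0.0
    return out


def corrupt_gaussian(matrix: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Return a copy with i.i.d. zero-centered Gaussian noise of the given SD
    added to every entry."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = np.array(matrix, dtype=float, copy=True)
    if sd > 0:
        out += rng.normal(0.0, sd, size=out.shape)
    return out


def _corrupt(matrix, spec: EncoderSpec, seed: int) -> np.ndarray:
    if spec.noise_type == "zeros":
        return corrupt_zeros(matrix, spec.noise_level, seed)
    if spec.noise_type == "gaussian":
        return corrupt_gaussian(matrix, spec.noise_level, seed)
    return np.array(matrix, dtype=float, copy=True)


# --------------------------------------------------------------------------
# training

_ACT = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, h: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, h: 1.0 - h * h),
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
        lambda z, h: h * (1.0 - h),
    ),
}


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _forward(X, weights, act):
    z1 = X @ weights["W1"] + weights["b1"]
    h = act(z1)
    out = h @ weights["W2"] + weights["b2"]
    return z1, h, out


def train_autoencoder(
    spec: EncoderSpec,
    train: np.ndarray | pd.DataFrame,
    validation: np.ndarray | pd.DataFrame | None = None,
) -> TrainedEncoder:
    """Train on corrupted input against the clean reconstruction target.

    If no validation matrix is given, ``spec.validation_fraction`` of the
    training patients is held out internally for early stopping. Validation
    loss is the clean-input reconstruction error.
    """
    X = np.asarray(train, dtype=float)
    if X.shape[1] != spec.input_dim:
        raise ValueError(f"input width {X.shape[1]} != spec.input_dim {spec.input_dim}")
    rng = np.random.default_rng(spec.seed)
    if validation is None:
        n_val = max(1, int(round(spec.validation_fraction * X.shape[0])))
        perm = rng.permutation(X.shape[0])
        X_val, X = X[perm[:n_val]], X[perm[n_val:]]
    else:
        X_val = np.asarray(validation, dtype=float)
    if X_val.size == 0 or X.size == 0:
        raise ValueError("empty training or validation matrix")

    d, b = spec.input_dim, spec.bottleneck_dim
    lim1 = np.sqrt(6.0 / (d + b))
    weights = {
        "W1": rng.uniform(-lim1, lim1, size=(d, b)),
        "b1": np.zeros(b),
        "W2": rng.uniform(-lim1, lim1, size=(b, d)),
        "b2": np.zeros(d),
    }
    act, dact = _ACT[spec.activation]
    params = [weights[k] for k in ("W1", "b1", "W2", "b2")]
    opt = _Adam(params, spec.learning_rate)

    best_val = np.inf
    best_weights = {k: v.copy() for k, v in weights.items()}
    wait = 0
    history = []
    stopped_epoch = 0
    n = X.shape[0]
    for epoch in range(1, spec.max_epochs + 1):
        Xc = _corrupt(X, spec, seed=int(rng.integers(0, 2**63)))  # fresh each epoch
        order = rng.permutation(n)
        train_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb_clean, xb = X[idx], Xc[idx]
            z1, h, out = _forward(xb, weights, act)
            resid = out - xb_clean
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "NaN/inf reconstruction loss; check input scaling or learning rate"
                )
            train_loss += loss * len(idx)
            dout = 2.0 * resid / resid.size
            gW2 = h.T @ dout
            gb2 = dout.sum(axis=0)
            dh = (dout @ weights["W2"].T) * dact(z1, h)
            gW1 = xb.T @ dh
            gb1 = dh.sum(axis=0)
            opt.step(params, [gW1, gb1, gW2, gb2])
        train_loss /= n
        _, _, out_val = _forward(X_val, weights, act)
        val_loss = float(np.mean((out_val - X_val) ** 2))
        history.append((epoch, train_loss, val_loss))
        stopped_epoch = epoch
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = {k: v.copy() for k, v in weights.items()}
            wait = 0
        else:
            wait += 1
            if wait >= spec.patience:
                logger.info("early stopping at epoch %d (best val %.5g)", epoch, best_val)
                break
    return TrainedEncoder(
        spec=spec,
        weights=best_weights,
        training_history=pd.DataFrame(history, columns=["epoch", "train_loss", "val_loss"]),
        stopped_epoch=stopped_epoch,
    )


def encode(model: TrainedEncoder, matrix: np.ndarray | pd.DataFrame) -> pd.DataFrame:
    """Clean (uncorrupted) forward pass through the encoder half."""
    index = matrix.index if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"input width {X.shape[1]} != spec.input_dim {model.spec.input_dim}"
        )
    act, _ = _ACT[model.spec.activation]
    emb = act(X @ model.weights["W1"] + model.weights["b1"])
    cols = [f"dim_{i:03d}" for i in range(model.spec.bottleneck_dim)]
    return pd.DataFrame(emb, index=index, columns=cols)


def reconstruct(model: TrainedEncoder, matrix) -> np.ndarray:
    act, _ = _ACT[model.spec.activation]
    _, _, out = _forward(np.asarray(matrix, dtype=float), model.weights, act)
    return out


# --------------------------------------------------------------------------
# hyperparameter grid


def default_grid() -> list[dict]:
    """The evaluated grid: basic, zero-masking at {0.2, 0.3, 0.4} and
    Gaussian at SD {0.5, 1, 1.5}, each crossed with relu/tanh/sigmoid
    (21 configurations)."""
    grid: list[dict] = []
    for activation in ACTIVATIONS:
        grid.append({"noise_type": "none", "noise_level": 0.0, "activation": activation})
        for level in ZEROS_LEVELS:
            grid.append({"noise_type": "zeros", "noise_level": level, "activation": activation})
        for level in GAUSSIAN_LEVELS:
            grid.append({"noise_type": "gaussian", "noise_level": level, "activation": activation})
    return grid


def grid_search_autoencoders(dataset, base_config, grid: list[dict] | None = None) -> pd.DataFrame:
    """Evaluate autoencoder variants by the mean C-index over each unimodal
    pipeline plus the multimodal one; returns the ranked table."""
    from . import pipeline  # local import: pipeline orchestrates this module

    if grid is None:
        grid = default_grid()
    biological = [m for m in base_config.modalities if m != "clinical"]
    rows = []
    for entry in grid:
        scores = []
        combos = [[m] for m in biological] + [list(base_config.modalities)]
        for combo in combos:
            cfg = replace(base_config, modalities=tuple(combo), ae_overrides={
                **(base_config.ae_overrides or {}), **entry,
            })
            report = pipeline.run_configuration(cfg, dataset)
            scores.append(report.mean)
        rows.append({**entry, "mean_cindex": float(np.mean(scores))})
    table = pd.DataFrame(rows).sort_values("mean_cindex", ascending=False)
    return table.reset_index(drop=True)
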