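"""Symmetric fully connected autoencoder trained with minibatch SGD.

The encoder compresses a gene panel (e.g. 1000 genes) through progressively
narrower fully connected layers (default 400 -> 100 -> 20) and the decoder
mirrors the chain back to the input width. Every hidden layer, including the
bottleneck by default, is followed by a ReLU; the reconstruction output is
linear because the targets are z-scores. The objective is the regularized
square loss

    L = sum_i 0.5 * ||x_i - D(E(x_i))||^2 + lambda * ||w||^2

where ``||w||^2`` sums the squared entries of every weight matrix (biases
are excluded). Gradients are computed analytically (plain backprop); the
implementation is deliberately dependency-free so the gradient of the loss
can be verified against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_HIDDEN = (400, 100, 20)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainingConfig:
    """Hyperparameters for SGD training. All values are config-overridable."""

    lambda_reg: float = 1e-4
    learning_rate: float = 3e-4
    momentum: float = 0.9
    epochs: int = 500
    batch_size: int = 32
    seed: int = 0
    bottleneck: int = 20
    hidden_sizes: tuple[int, ...] | None = None  # derived from bottleneck if None
    linear_bottleneck: bool = False
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs and batch_size must be positive")

    def resolve_hidden(self, d_in: int) -> tuple[int, ...]:
        if self.hidden_sizes is not None:
            return tuple(self.hidden_sizes)
        hidden = tuple(h for h in DEFAULT_HIDDEN[:-1] if h < d_in) + (self.bottleneck,)
        return hidden


@dataclass
class AutoencoderModel:
    """Weights and biases of the encoder/decoder pair.

    ``layer_sizes`` lists the encoder chain including the input width, e.g.
    ``[1000, 400, 100, 20]``; the decoder mirrors it. Weights are stored as
    (fan_in, fan_out) matrices so encoding is ``a @ W + b`` on samples-by-
    features input.
    """

    layer_sizes: list[int]
    enc_W: list[np.ndarray]
    enc_b: list[np.ndarray]
    dec_W: list[np.ndarray]
    dec_b: list[np.ndarray]
    linear_bottleneck: bool = False
    trained: bool = False
    loss_history: list[float] = field(default_factory=list)

    @property
    def d_in(self) -> int:
        return int(self.layer_sizes[0])

    @property
    def bottleneck(self) -> int:
        return int(self.layer_sizes[-1])

    def parameters(self):
        """All parameter arrays in a fixed order."""
        return [*self.enc_W, *self.enc_b, *self.dec_W, *self.dec_b]

    def weight_matrices(self):
        return [*self.enc_W, *self.dec_W]

    def weight_norm_sq(self) -> float:
        return float(sum((w**2).sum() for w in self.weight_matrices()))


def relu(x):
    """max(x, 0), elementwise."""
    return np.maximum(x, 0)


def init_model(
    d_in: int,
    hidden_sizes: tuple[int, ...] = DEFAULT_HIDDEN,
    seed: int = 0,
    linear_bottleneck: bool = False,
    dtype: str = "float64",
) -> AutoencoderModel:
    """Create an untrained model with scaled-uniform weights and zero biases.

    Weights are drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in)) using only
    ``seed``, so two calls with the same arguments are bitwise identical.
    """
    sizes = [int(d_in)] + [int(h) for h in hidden_sizes]
    if any(s <= 0 for s in sizes):
        raise ValueError("layer sizes must be positive")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(
            f"layer sizes must strictly decrease to the bottleneck, got {sizes}"
        )
    rng = np.random.default_rng(seed)
    dt = np.dtype(dtype)

    def draw(fan_in, fan_out):
        lim = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(dt)

    enc_W = [draw(a, b) for a, b in zip(sizes, sizes[1:])]
    enc_b = [np.zeros(b, dtype=dt) for b in sizes[1:]]
    rsizes = sizes[::-1]
    dec_W = [draw(a, b) for a, b in zip(rsizes, rsizes[1:])]
    dec_b = [np.zeros(b, dtype=dt) for b in rsizes[1:]]
    return AutoencoderModel(
        layer_sizes=sizes,
        enc_W=enc_W,
        enc_b=enc_b,
        dec_W=dec_W,
        dec_b=dec_b,
        linear_bottleneck=linear_bottleneck,
    )


def _forward_cached(model: AutoencoderModel, X: np.ndarray):
    """Forward pass keeping post-activation outputs for backprop.

    Returns (activations, F, Xhat); ``activations[0]`` is X and the list has
    one entry per layer output.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.d_in:
        raise ValueError(
            f"input has shape {X.shape}, expected (n_samples, {model.d_in})"
        )
    acts = [X]
    a = X
    n_enc = len(model.enc_W)
    for i, (W, b) in enumerate(zip(model.enc_W, model.enc_b)):
        z = a @ W + b
        is_bottleneck = i == n_enc - 1
        a = z if (is_bottleneck and model.linear_bottleneck) else relu(z)
        acts.append(a)
    F = a
    n_dec = len(model.dec_W)
    for i, (W, b) in enumerate(zip(model.dec_W, model.dec_b)):
        z = a @ W + b
        a = z if i == n_dec - 1 else relu(z)  # linear reconstruction output
        acts.append(a)
    return acts, F, a


def forward(model: AutoencoderModel, X: np.ndarray):
    """Return (F, Xhat): bottleneck scores and reconstruction."""
    _, F, Xhat = _forward_cached(model, X)
    return F, Xhat


def loss(model: AutoencoderModel, X: np.ndarray, lambda_reg: float) -> float:
    """Regularized square loss summed over samples."""
    _, _, Xhat = _forward_cached(model, X)
    sq = 0.5 * float(((np.asarray(X) - Xhat) ** 2).sum())
    return sq + lambda_reg * model.weight_norm_sq()


def loss_gradients(model: AutoencoderModel, X: np.ndarray, lambda_reg: float):
    """Analytic gradients of :func:`loss` w.r.t. every parameter.

    Returns (grad_enc_W, grad_enc_b, grad_dec_W, grad_dec_b) matching the
    shapes of the model's parameter lists.
    """
    X = np.asarray(X)
    acts, _, Xhat = _forward_cached(model, X)
    n_enc = len(model.enc_W)
    n_dec = len(model.dec_W)
    Ws = model.enc_W + model.dec_W

    g_W = [None] * (n_enc + n_dec)
    g_b = [None] * (n_enc + n_dec)
    delta = Xhat - X  # linear output layer
    for li in range(n_enc + n_dec - 1, -1, -1):
        a_prev = acts[li]
        g_W[li] = a_prev.T @ delta + 2.0 * lambda_reg * Ws[li]
        g_b[li] = delta.sum(axis=0)
        if li > 0:
            delta = delta @ Ws[li].T
            is_linear_act = li - 1 == n_enc - 1 and model.linear_bottleneck
            if not is_linear_act:
                delta = delta * (acts[li] > 0)
    return g_W[:n_enc], g_b[:n_enc], g_W[n_enc:], g_b[n_enc:]


def train(
    model: AutoencoderModel,
    X: np.ndarray,
    config: TrainingConfig,
) -> tuple[AutoencoderModel, list[float]]:
    """Minibatch SGD with momentum; fully reproducible from ``config.seed``.

    ``X`` is samples x d_in (z-scored). The per-epoch loss history records
    the full-data regularized loss normalized per sample. Divergence (NaN or
    inf loss) raises :class:`TrainingDivergedError`.
    """
    X = np.asarray(X, dtype=np.dtype(config.dtype))
    n = X.shape[0]
    if n < config.batch_size:
        raise ValueError(f"n={n} samples is smaller than batch_size={config.batch_size}")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    velocity = [np.zeros_like(p) for p in params]
    history: list[float] = []

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = X[idx]
            gW_e, gb_e, gW_d, gb_d = loss_gradients(model, batch, 0.0)
            grads = [*gW_e, *gb_e, *gW_d, *gb_d]
            scale = 1.0 / len(idx)
            weight_set = set(map(id, model.weight_matrices()))
            for p, v, g in zip(params, velocity, grads):
                g = g * scale
                if id(p) in weight_set:
                    g = g + 2.0 * config.lambda_reg * p
                v *= config.momentum
                v -= config.learning_rate * g
                p += v
        epoch_loss = loss(model, X, config.lambda_reg) / n
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(
                f"loss became non-finite at epoch {_epoch + 1}; "
                "try a smaller learning rate"
            )
        history.append(float(epoch_loss))

    model.trained = True
    model.loss_history = history
    return model, history


def encode(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Bottleneck scores (n_samples, bottleneck) of a trained model."""
    if not model.trained:
        raise RuntimeError("model is not trained; call train() first")
    F, _ = forward(model, X)
    return F


def reconstruction_r2(model: AutoencoderModel, X: np.ndarray) -> float:
    """1 - SS_res/SS_tot over all matrix entries."""
    X = np.asarray(X)
    _, Xhat = forward(model, X)
    ss_tot = float(((X - X.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("input matrix is constant; R^2 undefined")
    ss_res = float(((X - Xhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot
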