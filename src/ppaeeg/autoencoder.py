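"""Encoder-decoder transform of the time domain.

A fully-connected autoencoder is trained to reproduce 1 s single-channel
windows of the cleaned EEG at its output; the bottleneck code is then used
as a learned feature domain, alongside the spectral and wavelet transforms.
One network is shared across channels (windows from every channel are
training samples), which keeps the parameter count small; per subject the
codes are aggregated to the mean and standard deviation of each latent
unit over epochs, per channel.

The implementation is plain NumPy (mirrored fully-connected encoder and
decoder, MSE loss, Adam optimizer) and is deterministic given the seed.
To guard against leakage the model records the subject ids it was trained
on; the pipeline trains it on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "relu": (lambda x: np.maximum(x, 0.0), lambda a: (a > 0).astype(float)),
    "linear": (lambda x: x, lambda a: np.ones_like(a)),
}


@dataclass
class AEConfig:
    window_len: int = 500
    latent_dim: int = 16
    hidden: tuple[int, ...] = (64,)
    activation: str = "tanh"
    epochs: int = 15
    lr: float = 1e-3
    batch_size: int = 128
    max_windows: int = 20000  # training windows subsampled beyond this
    standardize: bool = True
    use_bias: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim >= self.window_len:
            raise ValueError("latent_dim must be smaller than window_len")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class AEModel:
    config: AEConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    n_encoder_layers: int
    mu: float
    sd: float
    loss_history: list[float] = field(default_factory=list)
    trained_on: list[str] = field(default_factory=list)

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Return activations per layer; output layer and latent are linear."""
        act, _ = _ACTIVATIONS[self.config.activation]
        out = [X]
        n_layers = len(self.weights)
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = out[-1] @ W + b
            is_latent = li == self.n_encoder_layers - 1
            is_output = li == n_layers - 1
            out.append(z if (is_latent or is_output) else act(z))
        return out

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Latent codes for rows of X (each row one window)."""
        if X.shape[1] != self.config.window_len:
            raise ValueError(
                f"window length {X.shape[1]} != model's {self.config.window_len}"
            )
        Xs = (X - self.mu) / self.sd
        acts = self._forward(Xs)
        return acts[self.n_encoder_layers]

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.mu) / self.sd
        return self._forward(Xs)[-1] * self.sd + self.mu


def _collect_windows(epoch_sets: list[EpochSet]) -> tuple[np.ndarray, list[str]]:
    windows, subjects = [], []
    for es in epoch_sets:
        windows.append(es.epochs.reshape(-1, es.n_times))
        subjects.append(es.subject_id)
    return np.concatenate(windows, axis=0), subjects


def train_autoencoder(
    epoch_sets: list[EpochSet] | EpochSet, cfg: AEConfig | None = None
) -> AEModel:
    """Train on all windows of the given (training-split) epoch sets."""
    cfg = cfg or AEConfig()
    cfg.validate()
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    if not epoch_sets or all(es.n_epochs == 0 for es in epoch_sets):
        raise ValueError("need at least one epoch to train on")
    X, subjects = _collect_windows(epoch_sets)
    if X.shape[1] != cfg.window_len:
        raise ValueError(
            f"epoch length {X.shape[1]} != configured window_len {cfg.window_len}"
        )
    rng = np.random.default_rng(cfg.seed)
    if X.shape[0] > cfg.max_windows:
        X = X[rng.choice(X.shape[0], cfg.max_windows, replace=False)]

    mu = float(X.mean()) if cfg.standardize else 0.0
    sd = float(X.std()) if cfg.standardize else 1.0
    sd = sd if sd > 0 else 1.0
    Xs = (X - mu) / sd

    sizes = (
        [cfg.window_len, *cfg.hidden, cfg.latent_dim]
        + [*cfg.hidden[::-1], cfg.window_len]
    )
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.normal(0.0, scale, (fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    model = AEModel(
        config=cfg,
        weights=weights,
        biases=biases,
        n_encoder_layers=len(cfg.hidden) + 1,
        mu=mu,
        sd=sd,
        trained_on=sorted(s for s in subjects if s),
    )

    act, dact = _ACTIVATIONS[cfg.activation]
    n_layers = len(weights)
    m_w = [np.zeros_like(W) for W in weights]
    v_w = [np.zeros_like(W) for W in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def full_loss() -> float:
        rec = model._forward(Xs)[-1]
        return float(np.mean((rec - Xs) ** 2))

    model.loss_history.append(full_loss())
    n = Xs.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            batch = Xs[order[start : start + cfg.batch_size]]
            acts = model._forward(batch)
            grad = 2.0 * (acts[-1] - batch) / batch.size
            for li in range(n_layers - 1, -1, -1):
                gW = acts[li].T @ grad
                gb = grad.sum(axis=0)
                if li > 0:
                    grad = grad @ model.weights[li].T
                    is_latent_in = li - 1 == model.n_encoder_layers - 1
                    if not is_latent_in:
                        grad = grad * dact(acts[li])
                step_li = step + 1
                for g, m, v, param in (
                    (gW, m_w[li], v_w[li], model.weights[li]),
                    (gb, m_b[li], v_b[li], model.biases[li]),
                ):
                    if param is model.biases[li] and not cfg.use_bias:
                        continue
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g**2
                    mhat = m / (1 - beta1**step_li)
                    vhat = v / (1 - beta2**step_li)
                    param -= cfg.lr * mhat / (np.sqrt(vhat) + eps)
            step += 1
        model.loss_history.append(full_loss())
    return model


def encode_epochs(model: AEModel, epochs: EpochSet) -> np.ndarray:
    """Latent codes, shaped [n_epochs x n_channels x latent_dim]."""
    X = epochs.epochs.reshape(-1, epochs.n_times)
    codes = model.encode(X)
    return codes.reshape(epochs.n_epochs, epochs.n_channels, -1)


def latent_features(model: AEModel, epochs: EpochSet) -> dict[str, float]:
    """Per channel, mean and sd over epochs of each latent unit.

    Names: ``ae|<channel>|z<j>|<mean|sd>``; n_channels * latent_dim * 2
    features per subject.
    """
    codes = encode_epochs(model, epochs)
    mean = codes.mean(axis=0)
    sd = codes.std(axis=0)
    row: dict[str, float] = {}
    for ci, ch in enumerate(epochs.channel_names):
        for j in range(codes.shape[2]):
            row[f"ae|{ch}|z{j}|mean"] = float(mean[ci, j])
            row[f"ae|{ch}|z{j}|sd"] = float(sd[ci, j])
    return row
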