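"""Training: multi-head binary cross-entropy optimized with Adam.

Every prediction head (nine data sectors plus the class token) is trained
against the same slice-level label; the loss is the weighted mean of the
per-head binary cross-entropies.  Adam follows the standard bias-corrected
first/second-moment update with beta1 = 0.9, beta2 = 0.999, eps = 1e-8,
weight decay 0 and AMSGrad off.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .network import VViTNetwork, vote_fusion

PROB_CLIP = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1.0e-8
    weight_decay: float = 0.0
    amsgrad: bool = False
    epochs: int = 1000
    batch_size: int = 32
    seed: int = 0
    head_loss_weights: list[float] | None = None  # default uniform
    checkpoint_every: int | None = None           # epochs between checkpoints

    def __post_init__(self) -> None:
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ValueError("betas must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)  # voted training accuracy
    epoch_seconds: list[float] = field(default_factory=list)
    diverged: bool = False


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 epsilon: float = 1e-8, weight_decay: float = 0.0,
                 amsgrad: bool = False):
        self.params = params
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.epsilon, self.weight_decay, self.amsgrad = epsilon, weight_decay, amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.vhat_max = [np.zeros_like(p.data) for p in params] if amsgrad else None

    @classmethod
    def from_config(cls, params: list[Tensor], config: TrainConfig) -> "Adam":
        return cls(params, lr=config.learning_rate, beta1=config.beta1,
                   beta2=config.beta2, epsilon=config.epsilon,
                   weight_decay=config.weight_decay, amsgrad=config.amsgrad)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.t)
            if self.amsgrad:
                self.vhat_max[i] = np.maximum(self.vhat_max[i], self.v[i])
                v_hat = self.vhat_max[i] / (1 - b2 ** self.t)
            else:
                v_hat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.epsilon)


def multi_head_bce(probs: Tensor, labels: np.ndarray,
                   weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean over heads of the per-head binary cross-entropy.

    ``probs`` has shape (B, H); every head is scored against the same label.
    Probabilities are clipped to [1e-7, 1 - 1e-7] before the log.
    """
    if not np.all(np.isfinite(probs.data)):
        raise FloatingPointError("non-finite probabilities in loss")
    b, h = probs.shape
    y = np.asarray(labels, dtype=np.float64).reshape(b, 1)
    if weights is None:
        w = np.full(h, 1.0 / h)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (h,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("head weights must be nonnegative, length n_heads")
        w = w / w.sum()
    p = probs.clip(PROB_CLIP, 1.0 - PROB_CLIP)
    per_head = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log())  # (B, H)
    return (per_head * Tensor(w.reshape(1, h))).sum(axis=1).mean()


def train(network: VViTNetwork, inputs: dict[str, np.ndarray],
          labels: np.ndarray, config: TrainConfig,
          verbose: bool = False,
          checkpoint_dir: str | None = None) -> TrainHistory:
    """Optimize the network in place; returns the per-epoch history.

    Deterministic for a fixed seed (parameter init is seeded separately via
    ``ModelConfig.seed``).  If the loss turns non-finite the run aborts,
    restoring the parameters from the end of the last finite epoch.
    """
    n = len(labels)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    opt = Adam.from_config(network.parameters(), config)
    weights = (np.asarray(config.head_loss_weights)
               if config.head_loss_weights is not None else None)
    history = TrainHistory()
    voters = [network.head_names.index(nm) for nm in network._vote_columns()]
    checkpoint = {k: v.data.copy() for k, v in network.params.items()}

    for epoch in range(config.epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        epoch_losses = []
        correct = 0
        diverged = False
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = {k: v[idx] for k, v in inputs.items()}
            opt.zero_grad()
            try:
                probs = network.forward(batch, training=True, rng=rng)
                loss = multi_head_bce(probs, labels[idx], weights)
            except FloatingPointError:
                diverged = True
                break
            if not np.isfinite(loss.data):
                diverged = True
                break
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            calls = (probs.data[:, voters] >= 0.5).astype(int)
            for i in range(len(idx)):
                voted = vote_fusion(calls[i], probs.data[i, voters])
                correct += int(voted == labels[idx][i])
        if diverged:
            for k, v in checkpoint.items():
                network.params[k].data = v
            history.diverged = True
            break
        checkpoint = {k: v.data.copy() for k, v in network.params.items()}
        history.loss.append(float(np.mean(epoch_losses)))
        history.accuracy.append(correct / n)
        history.epoch_seconds.append(time.perf_counter() - t0)
        if (checkpoint_dir is not None and config.checkpoint_every
                and (epoch + 1) % config.checkpoint_every == 0):
            from pathlib import Path
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            network.save(str(Path(checkpoint_dir) / f"epoch{epoch + 1:04d}"))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs} "
                  f"loss={history.loss[-1]:.4f} acc={history.accuracy[-1]:.3f}")
    return history
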