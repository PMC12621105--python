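"""Fine-tuning of component models with a deterministic checkpoint cadence.

Cross-entropy training with decoupled-weight-decay Adam (AdamW).  Validation
accuracy is measured midway through and at the end of every epoch, and a
checkpoint (parameters + measured accuracy + provenance) is emitted at each
of those points - the stream the greedy-soup module consumes.

Default hyperparameters follow the experiment-scale settings (batch size 32
or 16, learning rate 1e-4, weight decay 0.01); the alternative configuration
(learning rate 1e-3, weight decay 0.9) is reachable through TrainConfig.
"""

from __future__ import annotations

import dataclasses
import logging
import random
from typing import Callable, Optional

import numpy as np

from . import _autodiff as ad
from .core_types import Checkpoint, ParameterSet, Provenance
from .data import ArrayDataset
from .encoders import ComponentModel, EncoderConfig, Vocabulary

logger = logging.getLogger(__name__)


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed every source of randomness and return the dedicated generator."""
    random.seed(seed)
    np.random.seed(seed % (2**32))
    return np.random.Generator(np.random.PCG64(seed))


@dataclasses.dataclass
class TrainConfig:
    role: str = "answer"  # or "qtype"
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    epochs: int = 1
    seed: int = 42
    optimizer: str = "adamw"
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    checkpoint_cadence: tuple[str, ...] = ("half", "end")
    class_weighting: bool = False

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.role not in ("answer", "qtype"):
            raise ValueError("role must be 'answer' or 'qtype'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["betas"] = list(self.betas)
        d["checkpoint_cadence"] = list(self.checkpoint_cadence)
        return d


class AdamW:
    """Adam with decoupled weight decay over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.params = params
        self.lr = config.learning_rate
        self.wd = config.weight_decay
        self.b1, self.b2 = config.betas
        self.eps = config.eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)


def evaluate_accuracy(
    model: ComponentModel,
    dataset: ArrayDataset,
    params: Optional[ParameterSet] = None,
    role: Optional[str] = None,
) -> float:
    role = role or model.config.role
    pred = model.predict_indices(dataset.token_ids, dataset.images, params)
    return float((pred == dataset.labels(role)).mean())


def train_component(
    train: ArrayDataset,
    val: ArrayDataset,
    config: TrainConfig,
    model_config: EncoderConfig,
    vocab: Vocabulary,
    mu: np.ndarray,
    sigma: np.ndarray,
    log_step: Optional[Callable[[int, float], None]] = None,
) -> tuple[ComponentModel, list[Checkpoint]]:
    """Train one component model; return it plus the checkpoint stream.

    Two runs with equal seed and config produce bit-identical checkpoints.
    """
    if model_config.role != config.role:
        raise ValueError("model_config.role must match config.role")
    rng = set_global_seed(config.seed)
    model = ComponentModel.initialize(model_config, vocab, mu, sigma, seed=config.seed)
    labels = train.labels(config.role)
    if labels.max() >= model_config.n_classes:
        raise ValueError("labels exceed the head's label space")

    class_w = None
    if config.class_weighting:
        counts = np.bincount(labels, minlength=model_config.n_classes).astype(np.float64)
        class_w = np.where(counts > 0, counts.sum() / np.maximum(counts, 1) / len(counts), 0.0)

    opt = AdamW(model.params.entries, config)
    n = len(train)
    steps_per_epoch = max(1, -(-n // config.batch_size))
    half_step = max(1, steps_per_epoch // 2)
    checkpoints: list[Checkpoint] = []
    hyper = config.to_dict()
    meta = {
        "config": model_config.to_dict(),
        "vocab": vocab.to_dict(),
        "mu": model.mu.tolist(),
        "sigma": model.sigma.tolist(),
    }

    def emit(epoch: int, phase: str) -> None:
        acc = evaluate_accuracy(model, val)
        checkpoints.append(
            Checkpoint(
                params=model.params.copy(),
                val_accuracy=acc,
                provenance=Provenance(epoch=epoch, phase=phase, hyperparameters=hyper, seed=config.seed),
                meta=dict(meta),
            )
        )
        logger.info("checkpoint epoch=%d phase=%s val_acc=%.4f", epoch, phase, acc)

    step = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            p = model.wrap_params(requires_grad=True)
            logits = model.forward_logits(p, train.token_ids[idx], train.images[idx])
            y = labels[idx]
            if class_w is not None:
                ls = ad.log_softmax(logits, axis=-1)
                picked = ls[np.arange(len(y)), y]
                wts = class_w[y]
                loss = -(picked * ad.as_tensor(wts)).sum() * (1.0 / wts.sum())
            else:
                loss = ad.cross_entropy(logits, y)
            loss.backward()
            grads = {k: t.grad for k, t in p.items()}
            opt.step(grads)
            step += 1
            if log_step is not None:
                log_step(step, float(loss.data))
            if "half" in config.checkpoint_cadence and b + 1 == half_step:
                emit(epoch, "half")
        if "end" in config.checkpoint_cadence:
            emit(epoch, "end")
    return model, checkpoints


def run_seed_study(
    train: ArrayDataset,
    val: ArrayDataset,
    test: ArrayDataset,
    config: TrainConfig,
    model_config: EncoderConfig,
    vocab: Vocabulary,
    mu: np.ndarray,
    sigma: np.ndarray,
    seeds: list[int],
) -> list[tuple[int, float]]:
    """Train one model per seed (identical config otherwise); test accuracies."""
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    results = []
    for seed in seeds:
        cfg = dataclasses.replace(config, seed=seed)
        model, _ = train_component(train, val, cfg, model_config, vocab, mu, sigma)
        results.append((seed, evaluate_accuracy(model, test)))
    return results
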