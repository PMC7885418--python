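"""Network calibration: corrupted-input loss minimization with AdamW and
validation-based early stopping.

The objective is the mean per-sample L1 inference error plus a weighted
contractive penalty (mean squared input-output derivative), evaluated on
minibatches whose inputs are corrupted with isotropic Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .network import (
    NetParams,
    Topology,
    batch_jacobians,
    build,
    forward_tensors,
    params_to_tensors,
    tensors_to_params,
)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the calibration procedure (defaults per study)."""

    contractive_weight: float = 1e-2
    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-6
    noise_variance: float = 1e-1
    batch_size: int = 2 ** 12
    validation_fraction: float = 0.10
    lookback: int = 300
    max_iterations: int = 5000
    seed: int = 0
    adam_eps: float = 1e-8
    # whether the early-stopping validation loss includes the contractive
    # term; its composition is not pinned down, and the inference term is
    # what stopping should track, so the cheap variant is the default
    validation_contractive: bool = False

    def __post_init__(self):
        if self.contractive_weight < 0:
            raise ValueError("contractive_weight must be >= 0")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.lookback < 1 or self.max_iterations < 1:
            raise ValueError("batch_size, lookback, max_iterations must be >= 1")


@dataclass
class TrainingLog:
    total: list = field(default_factory=list)
    inference: list = field(default_factory=list)
    contractive: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    stop_reason: str = ""
    best_iteration: int = -1

    def to_rows(self):
        for k in range(len(self.total)):
            yield k, self.total[k], self.inference[k], self.contractive[k], self.validation[k]


def inference_loss(targets: np.ndarray, outputs: np.ndarray) -> float:
    """Mean over samples of the L1 norm of the per-sample error vector.

    Arguments are (J, n_samples): rows are DoFs, columns are samples.
    """
    targets = np.asarray(targets, float)
    outputs = np.asarray(outputs, float)
    if targets.shape != outputs.shape:
        raise ValueError(f"shape mismatch: {targets.shape} vs {outputs.shape}")
    err = np.abs(targets - outputs)
    if targets.ndim == 1:
        return float(err.mean())
    return float(err.sum(axis=0).mean())


def contractive_loss(params: NetParams, batch: np.ndarray) -> float:
    """Mean squared input-output derivative over samples, inputs, DoFs."""
    batch = np.asarray(batch, float)
    if batch.ndim == 1:
        batch = batch[None, :]
    et = ad.Tensor(batch, requires_grad=True)
    rows = batch_jacobians(params_to_tensors(params), params.topology, et)
    sq = sum(float((r.data ** 2).sum()) for r in rows)
    B, I = batch.shape
    J = params.topology.n_dofs
    return sq / (B * I * J)


def total_loss(l_inference: float, l_contractive: float, contractive_weight: float) -> float:
    return l_inference + contractive_weight * l_contractive


def corrupt(batch: np.ndarray, noise_variance: float, rng: np.random.Generator) -> np.ndarray:
    """Additive isotropic Gaussian corruption; no clipping afterwards."""
    if noise_variance < 0:
        raise ValueError("noise_variance must be >= 0")
    if noise_variance == 0:
        return np.array(batch, float)
    return batch + np.sqrt(noise_variance) * rng.standard_normal(np.shape(batch))


def split_validation(n_samples: int, fraction: float, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/validation index split (|val| = round(P*T))."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n_val = int(round(fraction * n_samples))
    if n_val == 0 or n_val == n_samples:
        raise ValueError("split leaves an empty set")
    perm = rng.permutation(n_samples)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _batch_losses(param_tensors, topology: Topology, inputs: np.ndarray,
                  targets: np.ndarray, contractive_weight: float,
                  create_graph: bool):
    """Build the differentiable total loss for one batch.

    ``inputs`` is (B, I); ``targets`` is (B, J).  Returns (loss tensor,
    inference value, contractive value).
    """
    B, I = inputs.shape
    J = topology.n_dofs
    et = ad.Tensor(inputs, requires_grad=True)
    _, outs = forward_tensors(param_tensors, topology, et)
    y_hat = outs  # list of (B, 1) tensors
    err = ad.Tensor(np.zeros(()))
    for j in range(J):
        err = err + ad.tsum(ad.absolute(ad.Tensor(targets[:, j:j + 1]) - y_hat[j]))
    l_inf = err * (1.0 / B)

    loss = l_inf
    l_con = None
    if contractive_weight > 0:
        sq = ad.Tensor(np.zeros(()))
        for yj in y_hat:
            (g,) = ad.grad(ad.tsum(yj), [et], create_graph=create_graph)
            sq = sq + ad.tsum(g * g)
        l_con = sq * (1.0 / (B * I * J))
        loss = loss + contractive_weight * l_con
    l_con_val = float(l_con.data) if l_con is not None else 0.0
    return loss, float(l_inf.data), l_con_val


class _AdamW:
    """Decoupled-weight-decay Adam; decay applied to weight matrices only."""

    def __init__(self, shapes, is_weight, config: TrainingConfig):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.is_weight = is_weight
        self.cfg = config
        self.t = 0

    def step(self, params_data, grads):
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.beta1 ** self.t
        b2t = 1.0 - c.beta2 ** self.t
        for k, (p, g) in enumerate(zip(params_data, grads)):
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + c.adam_eps)
            if self.is_weight[k]:
                update = update + c.weight_decay * p
            p -= c.learning_rate * update


def calibrate(envelopes: np.ndarray, stimuli: np.ndarray, topology: Topology,
              config: TrainingConfig) -> tuple[NetParams, TrainingLog]:
    """Fit network parameters on synchronized (envelope, intent) columns.

    Parameters
    ----------
    envelopes : (I, T) normalized envelope matrix.
    stimuli : (J, T) ternary intent matrix, index-synchronous.

    Minibatch membership is reshuffled every epoch; training inputs are
    corrupted before each loss evaluation; a clean validation split is
    scored after every update and training stops when the validation loss
    exceeds its value ``lookback`` iterations earlier, or at
    ``max_iterations``.  The returned parameters are the configuration
    with the lowest observed validation loss.
    """
    X = np.asarray(envelopes, float).T  # (T, I)
    Y = np.asarray(stimuli, float).T  # (T, J)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("envelopes and stimuli must have the same sample count")
    if X.shape[1] != topology.n_inputs or Y.shape[1] != topology.n_dofs:
        raise ValueError("data dimensions do not match topology")

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = split_validation(X.shape[0], config.validation_fraction, rng)
    X_tr, Y_tr = X[train_idx], Y[train_idx]
    X_val, Y_val = X[val_idx], Y[val_idx]

    params = build(topology, seed=config.seed)
    tensors = params_to_tensors(params)
    is_weight = [k % 2 == 0 for k in range(len(tensors))]
    opt = _AdamW([t.shape for t in tensors], is_weight, config)

    log = TrainingLog()
    best_val = np.inf
    best_snapshot = [t.data.copy() for t in tensors]

    n_train = X_tr.shape[0]
    batch_size = min(config.batch_size, n_train)
    order = rng.permutation(n_train)
    cursor = 0

    for it in range(config.max_iterations):
        if cursor + batch_size > n_train:
            order = rng.permutation(n_train)
            cursor = 0
        sel = order[cursor:cursor + batch_size]
        cursor += batch_size

        xb = corrupt(X_tr[sel], config.noise_variance, rng)
        yb = Y_tr[sel]
        loss, l_inf, l_con = _batch_losses(
            tensors, topology, xb, yb, config.contractive_weight, create_graph=True
        )
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"training diverged at iteration {it}")
        grads = ad.grad(loss, tensors)
        opt.step([t.data for t in tensors], [g.data for g in grads])

        val_weight = config.contractive_weight if config.validation_contractive else 0.0
        val_loss_t, val_inf, val_con = _batch_losses(
            tensors, topology, X_val, Y_val, val_weight, create_graph=False,
        )
        l_v = float(val_loss_t.data)

        log.total.append(float(loss.data))
        log.inference.append(l_inf)
        log.contractive.append(l_con)
        log.validation.append(l_v)

        if l_v < best_val:
            best_val = l_v
            best_snapshot = [t.data.copy() for t in tensors]
            log.best_iteration = it

        if it >= config.lookback and l_v > log.validation[it - config.lookback]:
            log.stop_reason = "lookback"
            break
    else:
        log.stop_reason = "max-iter"

    for t, snap in zip(tensors, best_snapshot):
        t.data = snap
    return tensors_to_params(tensors, topology), log
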