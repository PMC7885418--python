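"""Shared-encoder / per-DoF-decoder feed-forward regression network.

The encoder maps an I-channel envelope sample through ``N`` fully
connected blocks (affine -> leaky ReLU -> parameter-free layer
normalization) with widths ``2**K, 2**(K-1), ..., 2**(K-N+1)``; the final
block's output is the shared code.  Each of the ``J`` output degrees of
freedom has a dedicated decoder branch: one hidden block of width
``2**S`` followed by a single linear output neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import autodiff as ad

LEAKY_SLOPE = 0.01
LAYERNORM_EPS = 1e-5


@dataclass(frozen=True)
class Topology:
    """Structural hyperparameters of the regression network."""

    n_inputs: int = 8
    n_dofs: int = 2
    first_layer_log2: int = 7
    encoder_depth: int = 5
    decoder_hidden_log2: int = 5

    def __post_init__(self):
        if self.encoder_depth < 1 or self.n_dofs < 1 or self.n_inputs < 1:
            raise ValueError("topology dimensions must be positive")
        if self.first_layer_log2 < self.encoder_depth:
            raise ValueError(
                "first_layer_log2 must be >= encoder_depth "
                f"(got {self.first_layer_log2} < {self.encoder_depth})"
            )

    @property
    def encoder_widths(self) -> list[int]:
        k, n = self.first_layer_log2, self.encoder_depth
        return [2 ** (k - d) for d in range(n)]

    @property
    def code_width(self) -> int:
        return 2 ** (self.first_layer_log2 - self.encoder_depth + 1)

    @property
    def decoder_hidden_width(self) -> int:
        return 2 ** self.decoder_hidden_log2


@dataclass
class NetParams:
    """Weights and biases for every layer of a :class:`Topology`.

    ``encoder`` holds ``(W, b)`` per encoder block; ``decoders`` holds, per
    DoF, the hidden block ``(W, b)`` and the output layer ``(w, c)``.
    """

    topology: Topology
    encoder: list = field(default_factory=list)
    decoders: list = field(default_factory=list)

    def layers(self):
        """Yield every (W, b) pair in a fixed order."""
        for W, b in self.encoder:
            yield W, b
        for (Wh, bh), (Wo, bo) in self.decoders:
            yield Wh, bh
            yield Wo, bo

    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in self.layers())

    def copy(self) -> "NetParams":
        return NetParams(
            self.topology,
            [(W.copy(), b.copy()) for W, b in self.encoder],
            [
                ((Wh.copy(), bh.copy()), (Wo.copy(), bo.copy()))
                for (Wh, bh), (Wo, bo) in self.decoders
            ],
        )


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def build(topology: Topology, seed: int) -> NetParams:
    """Initialize parameters: Glorot-uniform weights, zero biases."""
    rng = np.random.default_rng(seed)
    params = NetParams(topology)
    width_in = topology.n_inputs
    for width_out in topology.encoder_widths:
        params.encoder.append(
            (_glorot(rng, width_in, width_out), np.zeros(width_out))
        )
        width_in = width_out
    code = topology.code_width
    hidden = topology.decoder_hidden_width
    for _ in range(topology.n_dofs):
        head = (_glorot(rng, code, hidden), np.zeros(hidden))
        out = (_glorot(rng, hidden, 1), np.zeros(1))
        params.decoders.append((head, out))
    return params


def layer_norm(v: np.ndarray, eps: float = LAYERNORM_EPS) -> np.ndarray:
    """Normalize across the last axis to zero mean, ~unit variance."""
    v = np.asarray(v, dtype=float)
    mu = v.mean(axis=-1, keepdims=True)
    var = ((v - mu) ** 2).mean(axis=-1, keepdims=True)
    return (v - mu) / np.sqrt(var + eps)


def _layer_norm_t(v: ad.Tensor, eps: float = LAYERNORM_EPS) -> ad.Tensor:
    mu = ad.mean(v, axis=-1, keepdims=True)
    centered = v - mu
    var = ad.mean(centered * centered, axis=-1, keepdims=True)
    return centered * ad.power(var + eps, -0.5)


def _block(x, W, b, tensor_mode: bool):
    if tensor_mode:
        return _layer_norm_t(ad.leaky_relu(x @ W + b, LEAKY_SLOPE))
    z = x @ W + b
    return layer_norm(np.where(z > 0, z, LEAKY_SLOPE * z))


def forward(params: NetParams, e: np.ndarray):
    """Run the network on envelope input(s).

    Parameters
    ----------
    e : array of shape (I,) or (B, I)

    Returns
    -------
    (code, y_hat) with shapes matching the input batchness.
    """
    e = np.asarray(e, dtype=float)
    single = e.ndim == 1
    x = e[None, :] if single else e
    if x.shape[1] != params.topology.n_inputs:
        raise ValueError(
            f"expected {params.topology.n_inputs} input channels, got {x.shape[1]}"
        )
    for W, b in params.encoder:
        x = _block(x, W, b, tensor_mode=False)
    code = x
    outs = []
    for (Wh, bh), (Wo, bo) in params.decoders:
        hcol = _block(code, Wh, bh, tensor_mode=False)
        outs.append(hcol @ Wo + bo)
    y = np.concatenate(outs, axis=1)
    if single:
        return code[0], y[0]
    return code, y


def forward_tensors(param_tensors, topology: Topology, e: ad.Tensor):
    """Differentiable forward pass on :class:`~.autodiff.Tensor` inputs.

    ``param_tensors`` is the flat list produced by :func:`params_to_tensors`
    (same ordering as :meth:`NetParams.layers`).
    """
    it = iter(param_tensors)
    x = e
    for _ in range(topology.encoder_depth):
        W, b = next(it), next(it)
        x = _block(x, W, b, tensor_mode=True)
    code = x
    outs = []
    for _ in range(topology.n_dofs):
        Wh, bh = next(it), next(it)
        Wo, bo = next(it), next(it)
        hcol = _block(code, Wh, bh, tensor_mode=True)
        outs.append(hcol @ Wo + bo)
    return code, outs


def params_to_tensors(params: NetParams):
    """Flatten parameters into autodiff leaves (order of ``layers()``)."""
    tensors = []
    for W, b in params.layers():
        tensors.append(ad.Tensor(W, requires_grad=True))
        tensors.append(ad.Tensor(b, requires_grad=True))
    return tensors


def tensors_to_params(tensors, topology: Topology) -> NetParams:
    params = NetParams(topology)
    it = iter(tensors)
    width_in = topology.n_inputs
    for _ in range(topology.encoder_depth):
        W, b = next(it), next(it)
        params.encoder.append((np.array(W.data), np.array(b.data)))
        width_in = W.data.shape[1]
    for _ in range(topology.n_dofs):
        Wh, bh = next(it), next(it)
        Wo, bo = next(it), next(it)
        params.decoders.append(
            ((np.array(Wh.data), np.array(bh.data)), (np.array(Wo.data), np.array(bo.data)))
        )
    return params


def jacobian(params: NetParams, e: np.ndarray) -> np.ndarray:
    """Exact derivative matrix d(y_hat_j)/d(e_i), shape (J, I)."""
    e = np.asarray(e, dtype=float)
    if e.ndim != 1:
        raise ValueError("jacobian expects a single envelope sample")
    et = ad.Tensor(e[None, :], requires_grad=True)
    _, outs = forward_tensors(params_to_tensors(params), params.topology, et)
    rows = []
    for yj in outs:
        (g,) = ad.grad(ad.tsum(yj), [et])
        rows.append(g.data[0])
    return np.stack(rows, axis=0)


def batch_jacobians(param_tensors, topology: Topology, e: ad.Tensor,
                    create_graph: bool = False):
    """Per-sample input-output derivative rows for a (B, I) batch.

    Returns a list of J tensors, each of shape (B, I): element (b, i) is
    d(y_hat_j[b])/d(e[b, i]).  Valid because sample b's output depends
    only on sample b's input.
    """
    _, outs = forward_tensors(param_tensors, topology, e)
    rows = []
    for yj in outs:
        (g,) = ad.grad(ad.tsum(yj), [e], create_graph=create_graph)
        rows.append(g)
    return rows


# -- serialization ------------------------------------------------------

def save_params(path, params: NetParams) -> None:
    with h5py.File(path, "w") as f:
        t = params.topology
        f.attrs["n_inputs"] = t.n_inputs
        f.attrs["n_dofs"] = t.n_dofs
        f.attrs["first_layer_log2"] = t.first_layer_log2
        f.attrs["encoder_depth"] = t.encoder_depth
        f.attrs["decoder_hidden_log2"] = t.decoder_hidden_log2
        for idx, (W, b) in enumerate(params.encoder):
            f.create_dataset(f"encoder/{idx}/W", data=W)
            f.create_dataset(f"encoder/{idx}/b", data=b)
        for j, ((Wh, bh), (Wo, bo)) in enumerate(params.decoders):
            f.create_dataset(f"decoder/{j}/hidden/W", data=Wh)
            f.create_dataset(f"decoder/{j}/hidden/b", data=bh)
            f.create_dataset(f"decoder/{j}/out/W", data=Wo)
            f.create_dataset(f"decoder/{j}/out/b", data=bo)


def load_params(path) -> NetParams:
    with h5py.File(path, "r") as f:
        topology = Topology(
            n_inputs=int(f.attrs["n_inputs"]),
            n_dofs=int(f.attrs["n_dofs"]),
            first_layer_log2=int(f.attrs["first_layer_log2"]),
            encoder_depth=int(f.attrs["encoder_depth"]),
            decoder_hidden_log2=int(f.attrs["decoder_hidden_log2"]),
        )
        params = NetParams(topology)
        for idx in range(topology.encoder_depth):
            params.encoder.append(
                (f[f"encoder/{idx}/W"][...], f[f"encoder/{idx}/b"][...])
            )
        for j in range(topology.n_dofs):
            params.decoders.append(
                (
                    (f[f"decoder/{j}/hidden/W"][...], f[f"decoder/{j}/hidden/b"][...]),
                    (f[f"decoder/{j}/out/W"][...], f[f"decoder/{j}/out/b"][...]),
                )
            )
    return params
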