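"""The multitask 3D CNN: shared convolutional body, three task heads.

Architecture (per block): batch-norm -> conv 3x3x3 (ReLU) -> max-pool 3x3x3
stride 2.  After the last block: flatten -> dropout -> dense (ReLU), then one
head per task, each dense(1) -> batch-norm -> output activation (sigmoid for
gender and diagnosis, identity for age).  Batch norm precedes the layer it
feeds, and the L2 penalty applies to all conv and dense kernels.

Input batches are channel-last ``(N, X, Y, Z, 2)`` with channel 0 = gray
matter and channel 1 = white matter; internally the network works in
``(N, C, X, Y, Z)``.

Label encoding (stated here because the source datasets leave it implicit):
gender positive class = female, diagnosis positive class = disorder.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from .layers import (BatchNorm, Conv3D, Dense, Dropout, Flatten, Layer,
                     MaxPool3D, Parameter, ReLU, Sigmoid)
from .losses import TASKS

__all__ = ["ModelConfig", "MultitaskCNN3D", "build_model", "pooled_dim"]


@dataclass
class ModelConfig:
    """Hyperparameters of the network.

    Kernel (3x3x3), pool window (3x3x3) and pool stride (2) are fixed by the
    architecture.  ``filters_per_block`` sets both the depth (number of
    conv/pool blocks) and the width of each block.  Defaults target the full
    128^3 grid; tests and the synthetic benchmark use the small preset
    (2 blocks, filters (4, 8), dense 32 on 32^3 inputs).
    """

    filters_per_block: tuple[int, ...] = (8, 16, 32, 64)
    dense_units: int = 256
    dropout_rate: float = 0.5
    l2_coefficient: float = 1e-3
    bn_momentum: float = 0.9
    in_channels: int = 2

    @property
    def conv_blocks(self) -> int:
        return len(self.filters_per_block)

    def __post_init__(self):
        if len(self.filters_per_block) < 1:
            raise ValueError("at least one conv block is required")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_coefficient < 0:
            raise ValueError("l2_coefficient must be >= 0")

    @classmethod
    def small(cls) -> "ModelConfig":
        """2-block configuration for 32^3 inputs (tests and benchmark runs)."""
        return cls(filters_per_block=(4, 8), dense_units=32)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filters_per_block"] = list(self.filters_per_block)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["filters_per_block"] = tuple(d["filters_per_block"])
        return cls(**d)


def pooled_dim(d: int) -> int:
    """Output size of one pooling step (window 3, stride 2, pad 1)."""
    return (d - 1) // 2 + 1


class ConfigurationError(ValueError):
    pass


class MultitaskCNN3D:
    """Shared-body multitask network with age, gender and diagnosis heads."""

    def __init__(self, config: ModelConfig, input_shape: tuple[int, int, int], seed: int = 0):
        self.config = config
        self.input_shape = tuple(int(s) for s in input_shape)
        if len(self.input_shape) != 3:
            raise ValueError("input_shape must have three spatial dimensions")
        rng = np.random.default_rng(seed)

        dims = list(self.input_shape)
        self.body: list[Layer] = []
        in_ch = config.in_channels
        for i, f in enumerate(config.filters_per_block):
            if min(dims) < 4:
                raise ConfigurationError(
                    f"input too small for block {i}: spatial dims {tuple(dims)} "
                    f"cannot support another conv/pool block")
            self.body.append(BatchNorm(in_ch, momentum=config.bn_momentum, name=f"block{i}.bn"))
            self.body.append(Conv3D(in_ch, f, rng, name=f"block{i}.conv"))
            self.body.append(ReLU())
            self.body.append(MaxPool3D())
            dims = [pooled_dim(d) for d in dims]
            in_ch = f
        self.spatial_trace = self._trace()

        flat = in_ch * int(np.prod(dims))
        self.body.append(Flatten())
        self._dropout = Dropout(config.dropout_rate)
        self.body.append(self._dropout)
        self.body.append(Dense(flat, config.dense_units, rng, name="shared.dense"))
        self.body.append(ReLU())

        self.heads: dict[str, list[Layer]] = {}
        for task in TASKS:
            head: list[Layer] = [
                Dense(config.dense_units, 1, rng, name=f"{task}.dense"),
                BatchNorm(1, momentum=config.bn_momentum, name=f"{task}.bn"),
            ]
            if task in ("gender", "diagnosis"):
                head.append(Sigmoid())
            self.heads[task] = head

    # -- introspection ------------------------------------------------------

    def _trace(self) -> list[tuple[int, int, int]]:
        dims = tuple(self.input_shape)
        trace = [dims]
        for _ in self.config.filters_per_block:
            dims = tuple(pooled_dim(d) for d in dims)
            trace.append(dims)
        return trace

    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for layer in self.body:
            ps.extend(layer.params())
        for task in TASKS:
            for layer in self.heads[task]:
                ps.extend(layer.params())
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                dropout_rng: np.random.Generator | None = None) -> dict[str, np.ndarray]:
        """Map a channel-last batch ``(N, X, Y, Z, 2)`` to per-task outputs.

        Returns ``{"age": (N,), "gender": (N,), "diagnosis": (N,)}`` with the
        classification outputs already passed through the sigmoid.
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:  # single example without batch axis
            x = x[None]
        if x.shape[1:4] != self.input_shape or x.shape[4] != self.config.in_channels:
            raise ValueError(f"expected input (N, {self.input_shape}, {self.config.in_channels}), "
                             f"got {x.shape}")
        if dropout_rng is not None:
            self._dropout.set_rng(dropout_rng)
        h = np.ascontiguousarray(x.transpose(0, 4, 1, 2, 3))
        for layer in self.body:
            h = layer.forward(h, training)
        self._shared_out = h
        outputs = {}
        for task in TASKS:
            t = h
            for layer in self.heads[task]:
                t = layer.forward(t, training)
            outputs[task] = t.ravel()
        return outputs

    def backward(self, grad_outputs: dict[str, np.ndarray],
                 need_param_grads: bool = True) -> np.ndarray:
        """Backpropagate per-task output gradients; returns the input gradient.

        ``grad_outputs`` maps task name to an ``(N,)`` gradient w.r.t. that
        task's (post-activation) output; omitted tasks contribute nothing,
        which is how saliency isolates a single head.
        """
        gshared = np.zeros_like(self._shared_out)
        for task, gout in grad_outputs.items():
            if task not in self.heads:
                raise KeyError(f"unknown task {task!r}")
            g = np.asarray(gout, dtype=np.float32).reshape(-1, 1)
            for layer in reversed(self.heads[task]):
                g = layer.backward(g, need_param_grads)
            gshared += g
        g = gshared
        for layer in reversed(self.body):
            g = layer.backward(g, need_param_grads)
        # back to channel-last
        return g.transpose(0, 2, 3, 4, 1)

    def input_gradient(self, x: np.ndarray, task: str) -> np.ndarray:
        """Gradient of one head's scalar output w.r.t. the input (inference mode).

        The other heads are excluded from the gradient target.  ``x`` may be a
        single channel-last example or a batch; the result has the same shape.
        """
        if task not in self.heads:
            raise KeyError(f"unknown task {task!r}")
        single = np.asarray(x).ndim == 4
        out = self.forward(x, training=False)
        n = out[task].size
        g = self.backward({task: np.ones(n, dtype=np.float32)}, need_param_grads=False)
        return g[0] if single else g

    # -- state --------------------------------------------------------------

    def _layers(self):
        yield from self.body
        for task in TASKS:
            yield from self.heads[task]

    def get_state(self) -> dict:
        """Deep copy of all parameter values and batch-norm running moments."""
        return {
            "params": [p.value.copy() for p in self.parameters()],
            "extra": [copy.deepcopy(layer.extra_state()) for layer in self._layers()],
            "config": self.config.to_dict(),
            "input_shape": self.input_shape,
        }

    def set_state(self, state: dict) -> None:
        params = self.parameters()
        if len(params) != len(state["params"]):
            raise ValueError("state does not match this architecture")
        for p, v in zip(params, state["params"]):
            if p.value.shape != v.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = v
        for layer, extra in zip(self._layers(), state["extra"]):
            layer.load_extra_state(extra)

    def zero_grads(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def build_model(config: ModelConfig, input_shape: tuple[int, int, int],
                seed: int = 0) -> MultitaskCNN3D:
    """Construct the network, validating that the input survives all poolings."""
    return MultitaskCNN3D(config, input_shape, seed=seed)
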