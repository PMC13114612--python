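"""Small neural-network building blocks on top of :mod:`dfcmamba.autodiff`.

Provides a ``Module`` base with a flat, name-addressable parameter registry
(used for checkpointing and for the warmup freeze contract), ``Linear`` /
``LayerNorm`` layers with standard fan-in initialisation, inverted dropout,
and an Adam optimiser with per-group learning rates and freeze flags.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Adam", "dropout_mask"]


class Module:
    """Base class: child modules and parameters are discovered by attribute."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for name, t in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {t.data.shape}"
                )
            t.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    """Affine map with uniform fan-in init, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(n_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, size=(n_out,)), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.scale = Tensor(np.ones(dim), requires_grad=True)
        self.shift = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        return normed * self.scale + self.shift


def dropout_mask(shape: tuple[int, ...], p: float, rng: np.random.Generator) -> Tensor:
    """Inverted-dropout multiplier: 0 with probability p, else 1/(1-p)."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"dropout probability must be in [0,1), got {p}")
    keep = (rng.random(shape) >= p).astype(np.float64)
    return Tensor(keep / (1.0 - p))


class Adam:
    """Adam with parameter groups: each group has its own lr and freeze flag."""

    def __init__(
        self,
        groups: list[dict],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        # groups: [{"params": [Tensor,...], "lr": float, "frozen": bool}, ...]
        self.groups = []
        for g in groups:
            params = list(g["params"])
            self.groups.append(
                {
                    "params": params,
                    "lr": float(g["lr"]),
                    "frozen": bool(g.get("frozen", False)),
                    "m": [np.zeros_like(p.data) for p in params],
                    "v": [np.zeros_like(p.data) for p in params],
                }
            )
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for g in self.groups:
            if g["frozen"]:
                continue
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                if p.grad is None:
                    continue
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad**2
                p.data -= g["lr"] * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()
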