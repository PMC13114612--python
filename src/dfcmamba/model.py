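"""End-to-end classifier: per-window VAE -> Mamba temporal encoder -> KAN head.

A session enters as its ``K x D`` vectorised dFC sequence; each window is
encoded to a latent vector (posterior mean at evaluation, reparameterized
sample during training), the latent sequence is summarised by the selective
state-space encoder into a temporal context vector, and the KAN head maps
the context to class logits.  Ablation switches reproduce the reference
configurations: ``use_mamba=False`` mean-pools the latents straight into the
head, ``head='mlp'`` swaps the KAN for a ReLU MLP of the same hidden width.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, no_grad
from .kan import KANClassifier, SplineGrid
from .nn import Linear, Module
from .ssm import MambaConfig, MambaEncoder, SelectivityTrace, selectivity_scores
from .vae import VAE, VAEArchitecture, kl_divergence, reconstruction_loss

__all__ = ["ModelConfig", "MLPHead", "DFCClassifier", "ForwardResult"]


@dataclass
class ModelConfig:
    vae: VAEArchitecture = field(default_factory=VAEArchitecture)
    mamba: MambaConfig = field(default_factory=MambaConfig)
    kan_hidden: int = 64
    n_classes: int = 2
    head: str = "kan"  # "kan" | "mlp"
    use_mamba: bool = True
    grid: SplineGrid = field(default_factory=SplineGrid)

    def __post_init__(self):
        if self.head not in ("kan", "mlp"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.mamba.d_model != self.vae.latent_dim:
            raise ValueError(
                f"mamba d_model={self.mamba.d_model} must equal latent_dim={self.vae.latent_dim}"
            )

    @staticmethod
    def desk(input_dim: int = 190, n_classes: int = 2, **kwargs) -> "ModelConfig":
        return ModelConfig(
            vae=VAEArchitecture.desk(input_dim),
            mamba=MambaConfig.desk(d_model=32),
            kan_hidden=8,
            n_classes=n_classes,
            **kwargs,
        )

    def to_dict(self) -> dict:
        return {
            "vae": asdict(self.vae),
            "mamba": asdict(self.mamba),
            "kan_hidden": self.kan_hidden,
            "n_classes": self.n_classes,
            "head": self.head,
            "use_mamba": self.use_mamba,
            "grid": asdict(self.grid),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            vae=VAEArchitecture(**d["vae"]),
            mamba=MambaConfig(**d["mamba"]),
            kan_hidden=d["kan_hidden"],
            n_classes=d["n_classes"],
            head=d.get("head", "kan"),
            use_mamba=d.get("use_mamba", True),
            grid=SplineGrid(**d.get("grid", {})),
        )


class MLPHead(Module):
    """Two-layer ReLU MLP head (the no-KAN ablation)."""

    def __init__(self, n_in: int, n_hidden: int, n_classes: int, rng: np.random.Generator):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_classes, rng)
        self.n_classes = n_classes

    def __call__(self, c):
        c = c if isinstance(c, Tensor) else Tensor(np.asarray(c, dtype=np.float64))
        return self.fc2(self.fc1(c).relu())


@dataclass
class ForwardResult:
    logits: Tensor
    recon: Tensor
    kl: Tensor
    traces: list[SelectivityTrace]
    inputs: Tensor  # the dFC input tensor (differentiable, for attribution)
    context: Tensor


class DFCClassifier(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.vae = VAE(cfg.vae, rng)
        self.mamba = MambaEncoder(cfg.mamba, rng) if cfg.use_mamba else None
        if cfg.head == "kan":
            self.head = KANClassifier(cfg.vae.latent_dim, cfg.kan_hidden,
                                      cfg.n_classes, rng, grid=cfg.grid)
        else:
            self.head = MLPHead(cfg.vae.latent_dim, cfg.kan_hidden, cfg.n_classes, rng)

    def forward(self, vectors: np.ndarray | Tensor, train_mode: bool = False,
                rng: np.random.Generator | None = None,
                sample_latent: bool = False) -> ForwardResult:
        """Full differentiable pass over ``(K, D)`` or batched ``(B, K, D)`` input."""
        x = vectors if isinstance(vectors, Tensor) else Tensor(np.asarray(vectors, dtype=np.float64))
        mu, log_var = self.vae.encode(x)
        if sample_latent:
            if rng is None:
                raise ValueError("sample_latent requires an rng")
            z = self.vae.reparameterize(mu, log_var, rng.standard_normal(mu.shape))
        else:
            z = mu
        v_hat = self.vae.decode(z)
        recon = reconstruction_loss(_flatten_windows(x), _flatten_windows(v_hat))
        kl = kl_divergence(_flatten_windows(mu), _flatten_windows(log_var))
        if self.mamba is not None:
            context, traces = self.mamba(z, train_mode=train_mode, rng=rng)
        else:
            context, traces = z.mean(axis=-2), []
        logits = self.head(context)
        return ForwardResult(logits=logits, recon=recon, kl=kl, traces=traces,
                             inputs=x, context=context)

    # -- inference helpers -------------------------------------------------
    def predict_session(self, seq) -> np.ndarray:
        """Class probability vector for one session (deterministic)."""
        vec = seq.vectors if hasattr(seq, "vectors") else np.asarray(seq)
        if vec.shape[-1] != self.cfg.vae.input_dim:
            raise ValueError(
                f"session has {vec.shape[-1]} features, model expects {self.cfg.vae.input_dim}"
            )
        with no_grad():
            res = self.forward(vec, train_mode=False, sample_latent=False)
            return res.logits.softmax().data.copy()

    def session_selectivity(self, seq) -> np.ndarray:
        """Temporal-importance scores s_k for one session."""
        if self.mamba is None:
            raise ValueError("selectivity requires the Mamba encoder")
        vec = seq.vectors if hasattr(seq, "vectors") else np.asarray(seq)
        with no_grad():
            res = self.forward(vec, train_mode=False, sample_latent=False)
        trace = self.mamba.trace_for_importance(res.traces)
        return selectivity_scores(trace)

    def parameter_count(self) -> dict[str, int]:
        """Itemised learnable-parameter counts per component."""
        counts: dict[str, int] = {}
        for name, p in self.named_parameters():
            top = name.split(".", 1)[0]
            counts[top] = counts.get(top, 0) + p.data.size
        counts["total"] = sum(v for k, v in counts.items())
        if self.cfg.head == "kan":
            counts["kan_spline_coeffs"] = sum(
                p.data.size for n, p in self.named_parameters() if "spline_coeff" in n
            )
            counts["kan_base_weights"] = sum(
                p.data.size for n, p in self.named_parameters() if "base_weight" in n
            )
        return counts


def _flatten_windows(t: Tensor) -> Tensor:
    """(B, K, D) -> (B*K, D); (K, D) unchanged — per-window sample axis."""
    if t.ndim <= 2:
        return t
    return t.reshape((-1, t.shape[-1]))
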