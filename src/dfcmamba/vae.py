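"""Per-window variational autoencoder over vectorised connectivity snapshots.

Each ``D``-dimensional window vector is compressed independently through a
ReLU MLP encoder to a diagonal-Gaussian posterior ``q(z|v) = N(mu, sigma^2)``
with two parallel affine heads, sampled via the reparameterization trick
``z = mu + sigma * eps``, and reconstructed by a mirror decoder whose sigmoid
output lives in (0, 1) — matching unit-rescaled correlations.  Training
minimises the negative ELBO: a batch-mean squared reconstruction error plus
a weighted KL divergence to the standard-normal prior.

The reference architecture is [D=6670, 2048, 1024, 512, 256] with a
128-dimensional latent space; every contract is width-agnostic and a small
"desk" stack is used on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import Linear, Module

__all__ = [
    "VAEArchitecture",
    "LatentSequence",
    "VAE",
    "kl_divergence",
    "reconstruction_loss",
]


@dataclass
class VAEArchitecture:
    """Widths of the encoder stack; the decoder is the exact mirror.

    ``encoder_dims[0]`` is the input dimension D; the remaining entries are
    hidden widths.  ``kl_weight`` is the beta multiplier on the KL term
    (default 1.0).
    """

    encoder_dims: list[int] = field(default_factory=lambda: [6670, 2048, 1024, 512, 256])
    latent_dim: int = 128
    kl_weight: float = 1.0

    def __post_init__(self):
        if len(self.encoder_dims) < 2:
            raise ValueError("encoder_dims needs at least [input, one hidden]")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")

    @property
    def input_dim(self) -> int:
        return self.encoder_dims[0]

    @property
    def decoder_dims(self) -> list[int]:
        return [self.latent_dim] + self.encoder_dims[::-1]

    @staticmethod
    def desk(input_dim: int = 190) -> "VAEArchitecture":
        """Small CPU-scale stack.

        The KL weight shrinks with the input width: the reconstruction term
        sums squared error over D features, so a desk-scale D needs a
        proportionally smaller KL weight to keep the same reconstruction-KL
        balance as the reference 6670-feature architecture (a fixed weight
        of 1.0 at D~200 collapses the posterior to the prior).
        """
        return VAEArchitecture(encoder_dims=[input_dim, 96], latent_dim=32,
                               kl_weight=input_dim / 6670.0)


@dataclass
class LatentSequence:
    """K x L per-window latent matrix; row k depends only on window k."""

    values: np.ndarray
    source: str  # "posterior-mean" | "sampled"
    subject_id: str = ""
    session_id: str = ""
    label: int = -1


class VAE(Module):
    def __init__(self, arch: VAEArchitecture, rng: np.random.Generator):
        self.arch = arch
        dims = arch.encoder_dims
        self.enc_layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.mu_head = Linear(dims[-1], arch.latent_dim, rng)
        self.logvar_head = Linear(dims[-1], arch.latent_dim, rng)
        # start the posterior tight (sigma ~ 0.14): with sigma ~ 1 at init the
        # reparameterization noise swamps mu and the decoder learns to ignore
        # the latent entirely (posterior collapse); the KL term re-inflates
        # sigma later wherever a dimension stays uninformative
        self.logvar_head.bias.data[:] = -4.0
        dec_dims = arch.decoder_dims
        self.dec_layers = [Linear(a, b, rng) for a, b in zip(dec_dims[:-1], dec_dims[1:])]

    # -- core passes ------------------------------------------------------
    def encode(self, v: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
        """Posterior parameters (mu, log sigma^2) for a batch (B, D) or (D,)."""
        h = v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))
        if h.shape[-1] != self.arch.input_dim:
            raise ValueError(
                f"input dim {h.shape[-1]} != architecture D={self.arch.input_dim}"
            )
        for layer in self.enc_layers:
            h = layer(h).relu()
        return self.mu_head(h), self.logvar_head(h)

    @staticmethod
    def reparameterize(mu: Tensor, log_var: Tensor, noise: np.ndarray) -> Tensor:
        """z = mu + exp(log_var / 2) * noise (noise supplied by caller)."""
        return mu + (log_var * 0.5).exp() * Tensor(np.asarray(noise, dtype=np.float64))

    def decode(self, z: Tensor | np.ndarray) -> Tensor:
        """Mirror MLP with sigmoid output; entries strictly inside (0, 1)."""
        h = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))
        if h.shape[-1] != self.arch.latent_dim:
            raise ValueError(
                f"latent dim {h.shape[-1]} != architecture L={self.arch.latent_dim}"
            )
        for layer in self.dec_layers[:-1]:
            h = layer(h).relu()
        return self.dec_layers[-1](h).sigmoid()

    # -- loss -------------------------------------------------------------
    def loss(self, v: np.ndarray, rng: np.random.Generator,
             sample: bool = True) -> tuple[Tensor, Tensor, Tensor]:
        """(total, reconstruction, kl) on a batch of window vectors (B, D).

        total = recon + kl_weight * kl; both terms are batch means, so the
        joint-objective weighting is invariant to batch size.
        """
        v = np.atleast_2d(np.asarray(v, dtype=np.float64))
        mu, log_var = self.encode(v)
        noise = rng.standard_normal(mu.shape) if sample else np.zeros(mu.shape)
        z = self.reparameterize(mu, log_var, noise)
        v_hat = self.decode(z)
        recon = reconstruction_loss(Tensor(v), v_hat)
        kl = kl_divergence(mu, log_var)
        total = recon + self.arch.kl_weight * kl
        return total, recon, kl

    # -- sequence encoding -------------------------------------------------
    def encode_sequence(self, seq, mode: str = "posterior-mean",
                        rng: np.random.Generator | None = None) -> LatentSequence:
        """Encode the K windows of a dFC sequence independently.

        ``mode`` is "posterior-mean" (deterministic, evaluation) or "sampled"
        (reparameterized draw, training; requires ``rng``).
        """
        if mode not in ("posterior-mean", "sampled"):
            raise ValueError(f"unknown mode {mode!r}")
        with no_grad():
            mu, log_var = self.encode(seq.vectors)
            if mode == "sampled":
                if rng is None:
                    raise ValueError("sampled mode requires an rng")
                z = self.reparameterize(mu, log_var, rng.standard_normal(mu.shape))
            else:
                z = mu
        return LatentSequence(
            values=z.data.copy(), source=mode,
            subject_id=seq.subject_id, session_id=seq.session_id, label=seq.label,
        )


def kl_divergence(mu: Tensor, log_var: Tensor) -> Tensor:
    """KL(N(mu, sigma^2) || N(0, I)) = -1/2 sum_j (1 + log s2_j - mu_j^2 - s2_j).

    For batched input the per-sample KL (sum over latent dims) is averaged
    over the batch, matching the reconstruction term's convention.
    """
    per = -0.5 * (1.0 + log_var - mu * mu - log_var.exp())
    per_sample = per.sum(axis=-1)
    return per_sample.mean() if per_sample.ndim > 0 else per_sample


def reconstruction_loss(v: Tensor, v_hat: Tensor) -> Tensor:
    """Mean over the batch of the squared L2 reconstruction error."""
    diff = v - v_hat
    sq = (diff * diff).sum(axis=-1)
    return sq.mean() if sq.ndim > 0 else sq
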