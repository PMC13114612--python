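"""Three-layer interpretability stack.

1. **Temporal** — the selective scan's per-window time-step values Delta are
   averaged over channels into importance scores s_k; class-mean profiles
   over the K windows show which scan periods drive the decision.
2. **Functional** — KAN edge activations are model parameters; ranking the
   first-layer inputs by mean absolute activation over probe contexts picks
   the most influential latent dimensions and their learned curves.
3. **Anatomical** — the Jacobian of a class logit with respect to every
   window's connectivity features, averaged over windows, maps decision
   evidence back onto region-pair space; thresholding and node strength give
   top connections and a region ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .dfc import DFCSequence, devectorize
from .kan import ActivationCurve
from .model import DFCClassifier
from .ssm import selectivity_scores

__all__ = [
    "TemporalImportanceProfile",
    "AttributionMatrix",
    "class_temporal_profile",
    "rank_activation_curves",
    "gradient_attribution",
    "class_attribution",
    "threshold_top_percent",
    "region_ranking",
]


@dataclass
class TemporalImportanceProfile:
    class_label: int
    mean_s: np.ndarray  # length K
    sd_s: np.ndarray
    zscored: bool
    n_sessions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.class_label,
            "window": np.arange(self.mean_s.size),
            "mean": self.mean_s,
            "sd": self.sd_s,
        })


@dataclass
class AttributionMatrix:
    class_label: int
    values: np.ndarray  # N x N symmetric, zero diagonal
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("attribution values must be square")
        self.values = v
        if not self.roi_names:
            self.roi_names = [f"ROI_{i + 1}" for i in range(v.shape[0])]

    @property
    def strength(self) -> np.ndarray:
        """Node strength: sum of absolute attributions over incident edges."""
        return np.abs(self.values).sum(axis=1)


def class_temporal_profile(model: DFCClassifier, sessions: list[DFCSequence],
                           class_label: int, zscore: bool = True) -> TemporalImportanceProfile:
    """Mean +/- sd selectivity profile over the sessions of one class.

    ``zscore`` standardises the class-mean curve across its K windows (the
    default rendering, centring every class curve near zero).
    """
    members = [s for s in sessions if s.label == class_label]
    if not members:
        raise ValueError(f"no sessions with class {class_label}")
    scores = np.stack([model.session_selectivity(s) for s in members])
    mean_s = scores.mean(axis=0)
    sd_s = scores.std(axis=0)
    if zscore:
        mu, sd = mean_s.mean(), mean_s.std()
        mean_s = (mean_s - mu) / (sd if sd > 0 else 1.0)
        sd_s = sd_s / (sd if sd > 0 else 1.0)
    return TemporalImportanceProfile(
        class_label=class_label, mean_s=mean_s, sd_s=sd_s,
        zscored=zscore, n_sessions=len(members),
    )


def rank_activation_curves(model: DFCClassifier, probes: np.ndarray,
                           top_k: int = 10) -> list[ActivationCurve]:
    """Rank first-layer KAN inputs by mean |phi_{j,i}(x_i)| over probes.

    ``probes`` is a matrix of temporal-context vectors (one per probe
    session).  Returns the ``top_k`` most influential inputs' curves in
    descending influence order (one representative curve per input, the
    output unit with the largest mean absolute activation).
    """
    if model.cfg.head != "kan":
        raise ValueError("activation-curve ranking requires the KAN head")
    layer = model.head.layer1
    probes = np.atleast_2d(np.asarray(probes, dtype=np.float64))
    if probes.shape[1] != layer.n_in:
        raise ValueError(f"probe width {probes.shape[1]} != layer n_in {layer.n_in}")
    if top_k > layer.n_in:
        warnings.warn(f"top_k={top_k} exceeds n_in={layer.n_in}; clamped", stacklevel=2)
        top_k = layer.n_in
    from .kan import bspline_basis

    basis = bspline_basis(probes, layer.grid)  # (P, n_in, n_basis)
    spline = np.einsum("pib,jib->pji", basis, layer.spline_coeff.data)
    silu = probes / (1.0 + np.exp(-probes))
    phi = layer.base_weight.data[None, :, :] * silu[:, None, :] + spline  # (P, j, i)
    per_edge = np.abs(phi).mean(axis=0)  # (j, i)
    influence = per_edge.mean(axis=0)  # mean over output units j, per input i
    order = np.argsort(-influence)[:top_k]
    curves = []
    for i in order:
        j = int(np.argmax(per_edge[:, i]))
        curve = model.head.extract_curve(1, j, int(i))
        curve.influence = float(influence[i])
        curves.append(curve)
    return curves


def gradient_attribution(model: DFCClassifier, session: DFCSequence,
                         target_class: int, per_r_units: bool = False) -> AttributionMatrix:
    """Jacobian of the target-class logit w.r.t. the session's dFC features,
    averaged over the K windows and mapped back to the N x N edge space
    (symmetric, zero diagonal).

    ``per_r_units`` converts from the model's unit-rescaled input scale to
    raw correlation units via the chain-rule factor 1/2.
    """
    if not 0 <= target_class < model.cfg.n_classes:
        raise ValueError(f"class {target_class} out of range")
    x = Tensor(np.asarray(session.vectors, dtype=np.float64), requires_grad=True)
    res = model.forward(x, train_mode=False, sample_latent=False)
    res.logits[target_class].backward()
    grad = x.grad  # (K, D)
    a_vec = grad.mean(axis=0)
    if per_r_units and session.rescaled:
        a_vec = a_vec * 0.5
    values = devectorize(a_vec, session.n_rois, diagonal=0.0)
    return AttributionMatrix(class_label=target_class, values=values)


def class_attribution(model: DFCClassifier, sessions: list[DFCSequence],
                      target_class: int, **kwargs) -> AttributionMatrix:
    """Session-level attributions averaged over the sessions of the class."""
    members = [s for s in sessions if s.label == target_class]
    if not members:
        raise ValueError(f"no sessions with class {target_class}")
    mats = [gradient_attribution(model, s, target_class, **kwargs).values for s in members]
    return AttributionMatrix(class_label=target_class, values=np.mean(mats, axis=0))


def threshold_top_percent(a: AttributionMatrix, percent: float = 1.0) -> list[tuple[int, int, float]]:
    """Keep the ceil(percent% of D) strongest unique connections.

    Returns (i, j, a_ij) sorted by |a_ij| descending; exact ties at the
    cutoff are broken by (i, j) lexicographic order.
    """
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    n = a.values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = a.values[iu, ju]
    d = vals.size
    keep = int(np.ceil(percent / 100.0 * d))
    order = sorted(range(d), key=lambda k: (-abs(vals[k]), iu[k], ju[k]))[:keep]
    return [(int(iu[k]), int(ju[k]), float(vals[k])) for k in order]


def region_ranking(a: AttributionMatrix, top_n: int = 20) -> pd.DataFrame:
    """Regions sorted by node strength, with names and scores."""
    strength = a.strength
    order = np.argsort(-strength)[:top_n]
    return pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "roi": [a.roi_names[i] for i in order],
        "roi_index": order,
        "strength": strength[order],
    })
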