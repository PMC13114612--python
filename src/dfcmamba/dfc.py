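"""Sliding-window dynamic functional connectivity (dFC) construction.

A resting-state scan is summarised as an ``N x T`` matrix of regional BOLD
time series.  Each series is z-scored over time, segmented into overlapping
windows of ``window_length`` time points advanced by ``step``, and each
window's pairwise Pearson correlation matrix is vectorised into its upper
triangle.  The result is a ``K x D`` sequence of connectivity snapshots with
``K = floor((T - Lw)/s) + 1`` windows and ``D = N(N-1)/2`` unique edges.

With the default atlas of 116 regions and 137 retained volumes this yields
the canonical 54 x 6670 representation per scan session.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROITimeSeries",
    "DFCConfig",
    "DFCSequence",
    "zscore_normalize",
    "count_windows",
    "window_pearson",
    "vectorize_upper",
    "devectorize",
    "rescale_unit",
    "build_dfc",
]


@dataclass
class ROITimeSeries:
    """One scan session: regional BOLD signals plus identifiers.

    ``data`` is ``N x T`` (regions by time points).  ``label`` is a 0-based
    class index; ``tr_seconds`` is the repetition time of the acquisition.
    """

    subject_id: str
    session_id: str
    label: int
    data: np.ndarray
    tr_seconds: float = 3.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (N x T), got shape {self.data.shape}")
        n, t = self.data.shape
        if n < 2 or t < 2:
            raise ValueError(f"need at least 2 ROIs and 2 time points, got {n} x {t}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))
            raise ValueError(f"non-finite value at (roi, t) = {tuple(bad[0])}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class DFCConfig:
    """Sliding-window parameters: length ``Lw`` and step ``s`` in time points."""

    window_length: int = 30
    step: int = 2
    rescale_to_unit: bool = True

    def __post_init__(self):
        if self.window_length < 1:
            raise ValueError("window_length must be a positive integer")
        if not 1 <= self.step <= self.window_length:
            raise ValueError("step must satisfy 1 <= step <= window_length")


@dataclass
class DFCSequence:
    """K x D vectorised windowed-correlation sequence for one session."""

    subject_id: str
    session_id: str
    label: int
    vectors: np.ndarray
    window_starts: np.ndarray
    n_rois: int
    rescaled: bool = False
    roi_names: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]


def zscore_normalize(ts: ROITimeSeries) -> ROITimeSeries:
    """Z-score each ROI series over time using the population sd (divisor T).

    Raises if any ROI is temporally flat — a flat row signals a failed
    extraction and would make the correlation undefined everywhere.
    """
    data = ts.data
    mu = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)  # population convention
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        raise ValueError(f"zero variance in ROI row(s) {flat.tolist()}")
    return ROITimeSeries(
        subject_id=ts.subject_id,
        session_id=ts.session_id,
        label=ts.label,
        data=(data - mu) / sd,
        tr_seconds=ts.tr_seconds,
    )


def count_windows(t: int, cfg: DFCConfig) -> int:
    """Number of sliding windows: floor((T - Lw)/s) + 1."""
    if t < cfg.window_length:
        raise ValueError(
            f"session too short: T={t} < window_length={cfg.window_length}"
        )
    return (t - cfg.window_length) // cfg.step + 1


def window_pearson(window: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of an ``N x Lw`` window.

    Rows with zero within-window variance get zero off-diagonal correlation
    (with a warning) instead of NaN, so degenerate windows stay usable.
    """
    window = np.asarray(window, dtype=np.float64)
    sd = window.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero within-window variance in ROI row(s) "
            f"{np.nonzero(degenerate)[0].tolist()}; correlations set to 0",
            stacklevel=2,
        )
        window = window.copy()
        # any finite values work: centred row becomes zero => r forced to 0 below
    centered = window - window.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom[degenerate] = 1.0
    r = (centered @ centered.T) / np.outer(denom, denom)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def vectorize_upper(r: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (i<j) vector of a symmetric unit-diagonal matrix."""
    r = np.asarray(r, dtype=np.float64)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {r.shape}")
    if np.max(np.abs(r - r.T)) > 1e-8:
        raise ValueError("matrix is not symmetric within 1e-8")
    iu = np.triu_indices(r.shape[0], k=1)
    return r[iu]


def devectorize(v: np.ndarray, n: int, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric ``N x N`` matrix from its upper-triangle vector.

    ``diagonal`` selects the reconstructed diagonal: 1 for correlation
    matrices, 0 for attribution maps.
    """
    v = np.asarray(v, dtype=np.float64)
    d = n * (n - 1) // 2
    if v.shape != (d,):
        raise ValueError(f"expected vector of length {d} for N={n}, got {v.shape}")
    out = np.full((n, n), 0.0)
    iu = np.triu_indices(n, k=1)
    out[iu] = v
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return out


def rescale_unit(v: np.ndarray) -> np.ndarray:
    """Affine map r -> (r+1)/2 from [-1, 1] onto [0, 1]."""
    v = np.asarray(v, dtype=np.float64)
    if np.any(v < -1.0) or np.any(v > 1.0):
        raise ValueError("correlation values must lie in [-1, 1]")
    return (v + 1.0) / 2.0


def build_dfc(ts: ROITimeSeries, cfg: DFCConfig) -> DFCSequence:
    """Full per-session pipeline: z-score, slide, correlate, vectorise."""
    normed = zscore_normalize(ts)
    t = normed.n_timepoints
    k = count_windows(t, cfg)
    starts = np.arange(k) * cfg.step
    n = normed.n_rois
    vectors = np.empty((k, n * (n - 1) // 2))
    for idx, start in enumerate(starts):
        window = normed.data[:, start : start + cfg.window_length]
        vectors[idx] = vectorize_upper(window_pearson(window))
    if cfg.rescale_to_unit:
        vectors = rescale_unit(vectors)
    return DFCSequence(
        subject_id=ts.subject_id,
        session_id=ts.session_id,
        label=ts.label,
        vectors=vectors,
        window_starts=starts,
        n_rois=n,
        rescaled=cfg.rescale_to_unit,
    )
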