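"""Synthetic multi-session rs-fMRI cohorts with planted connectivity structure.

Real disease-stage cohorts are access-controlled, so every stage of the
pipeline is exercised on simulated data whose ground truth is known exactly.
Sessions are drawn from a piecewise-stationary multivariate normal process:
a base inter-regional correlation template is modified by

* **class effects** — per-class correlation shifts on named edges, active for
  the whole scan (a stationary diagnostic signature), and
* **temporal effects** — shifts active only inside a range of sliding-window
  indices (a transient brain state), mapped to time points via the window
  grid ``[k*s, k*s + Lw)``.

Piecewise stationarity keeps the per-window target correlations exact and
analysable, which is what the planted-signal recovery tests require.
Independent Gaussian observation noise is added on top.  All draws are fully
determined by ``(cfg.seed, class index, subject index, session index)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dfc import ROITimeSeries

__all__ = [
    "TemporalEffect",
    "SyntheticCohortConfig",
    "default_base_correlation",
    "nearest_spd_correlation",
    "generate_session",
    "generate_cohort",
    "subject_level_split",
    "write_cohort",
    "desk_preset",
    "adni_like_preset",
]

Edge = tuple[int, int]


@dataclass
class TemporalEffect:
    """Correlation shift on ``edges`` active only in windows k1..k2 inclusive."""

    window_range: tuple[int, int]
    edges: list[Edge]
    delta_r: float


@dataclass
class SyntheticCohortConfig:
    n_classes: int = 2
    subjects_per_class: int = 15
    sessions_per_subject: tuple[int, int] = (1, 2)
    n_rois: int = 20
    n_timepoints: int = 137
    tr_seconds: float = 3.0
    window_length: int = 30
    step: int = 2
    class_effects: dict[int, list[tuple[Edge, float]]] = field(default_factory=dict)
    temporal_effects: dict[int, list[TemporalEffect]] = field(default_factory=dict)
    noise_sd: float = 0.2
    # subject-level connectivity heterogeneity: each subject carries a
    # low-rank deviation from the base template, shared by all of the
    # subject's sessions (longitudinal consistency)
    subject_rank: int = 4
    subject_sd: float = 0.06
    seed: int = 0
    # optional exact per-class totals (overrides random session counts)
    sessions_per_class_total: list[int] | None = None
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_effects"] = {
            str(c): [[list(e), dr] for e, dr in effs] for c, effs in self.class_effects.items()
        }
        d["temporal_effects"] = {
            str(c): [
                {"window_range": list(t.window_range), "edges": [list(e) for e in t.edges], "delta_r": t.delta_r}
                for t in effs
            ]
            for c, effs in self.temporal_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCohortConfig":
        d = dict(d)
        d["class_effects"] = {
            int(c): [(tuple(e), float(dr)) for e, dr in effs]
            for c, effs in d.get("class_effects", {}).items()
        }
        d["temporal_effects"] = {
            int(c): [
                TemporalEffect(tuple(t["window_range"]), [tuple(e) for e in t["edges"]], float(t["delta_r"]))
                for t in effs
            ]
            for c, effs in d.get("temporal_effects", {}).items()
        }
        d["sessions_per_subject"] = tuple(d["sessions_per_subject"])
        d["split_fractions"] = tuple(d.get("split_fractions", (0.7, 0.1, 0.2)))
        return cls(**d)


def default_base_correlation(n_rois: int, block_size: int = 5,
                             within: float = 0.35, between: float = 0.10) -> np.ndarray:
    """Block-structured correlation template emulating modular brain networks."""
    c = np.full((n_rois, n_rois), between)
    for lo in range(0, n_rois, block_size):
        hi = min(lo + block_size, n_rois)
        c[lo:hi, lo:hi] = within
    np.fill_diagonal(c, 1.0)
    return c


def nearest_spd_correlation(c: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the SPD cone (eigenvalue clipping) and
    renormalise to unit diagonal."""
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    if w.min() < eig_floor:
        c = (v * np.maximum(w, eig_floor)) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _subject_deviation(cfg: SyntheticCohortConfig, label: int, subject_seed: int) -> np.ndarray:
    """Low-rank symmetric correlation deviation specific to one subject.

    The deviation patterns are fixed per cohort; the subject's loadings are
    drawn once and shared by all of the subject's sessions, emulating stable
    individual connectivity profiles.  Per-edge marginal sd is
    ``cfg.subject_sd``.
    """
    if cfg.subject_rank <= 0 or cfg.subject_sd <= 0:
        return np.zeros((cfg.n_rois, cfg.n_rois))
    pat_rng = np.random.default_rng([cfg.seed, 777])
    patterns = pat_rng.standard_normal((cfg.subject_rank, cfg.n_rois, cfg.n_rois))
    patterns = (patterns + patterns.transpose(0, 2, 1)) / np.sqrt(2.0)
    loadings = np.random.default_rng(
        [cfg.seed, 555, label, subject_seed]
    ).standard_normal(cfg.subject_rank)
    dev = np.einsum("f,fij->ij", loadings, patterns)
    dev *= cfg.subject_sd / np.sqrt(cfg.subject_rank)
    np.fill_diagonal(dev, 0.0)
    return dev


def _effective_correlation(cfg: SyntheticCohortConfig, label: int,
                           active_temporal: list[TemporalEffect],
                           subject_dev: np.ndarray | None = None) -> np.ndarray:
    c = default_base_correlation(cfg.n_rois)
    if subject_dev is not None:
        c = c + subject_dev
        np.fill_diagonal(c, 1.0)
    for (i, j), dr in cfg.class_effects.get(label, []):
        c[i, j] += dr
        c[j, i] += dr
    for eff in active_temporal:
        for i, j in eff.edges:
            c[i, j] += eff.delta_r
            c[j, i] += eff.delta_r
    off = ~np.eye(cfg.n_rois, dtype=bool)
    if np.any(np.abs(c[off]) > 0.95):
        c[off] = np.clip(c[off], -0.95, 0.95)
    return nearest_spd_correlation(c)


def _segments(cfg: SyntheticCohortConfig, label: int) -> list[tuple[int, int, list[TemporalEffect]]]:
    """Partition [0, T) into maximal runs with a constant set of active effects."""
    t_total = cfg.n_timepoints
    effects = cfg.temporal_effects.get(label, [])
    spans = []
    for eff in effects:
        k1, k2 = eff.window_range
        t_lo = k1 * cfg.step
        t_hi = min(k2 * cfg.step + cfg.window_length, t_total)
        spans.append((t_lo, t_hi, eff))
    cuts = sorted({0, t_total, *(s[0] for s in spans), *(s[1] for s in spans)})
    segments = []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        active = [eff for (t_lo, t_hi, eff) in spans if t_lo <= lo and hi <= t_hi]
        segments.append((lo, hi, active))
    return segments


def generate_session(cfg: SyntheticCohortConfig, label: int,
                     subject_seed: int, session_idx: int = 0,
                     subject_id: str = "sub", session_id: str = "ses") -> ROITimeSeries:
    """Draw one scan session from the piecewise-stationary process."""
    if not 0 <= label < cfg.n_classes:
        raise ValueError(f"label {label} out of range for {cfg.n_classes} classes")
    rng = np.random.default_rng([cfg.seed, label, subject_seed, session_idx])
    subject_dev = _subject_deviation(cfg, label, subject_seed)
    data = np.empty((cfg.n_rois, cfg.n_timepoints))
    for lo, hi, active in _segments(cfg, label):
        c = _effective_correlation(cfg, label, active, subject_dev)
        try:
            chol = np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - SPD projection precludes this
            raise ValueError(f"non-SPD covariance in segment [{lo},{hi})") from exc
        z = rng.standard_normal((cfg.n_rois, hi - lo))
        data[:, lo:hi] = chol @ z
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(data.shape)
    return ROITimeSeries(
        subject_id=subject_id, session_id=session_id, label=label,
        data=data, tr_seconds=cfg.tr_seconds,
    )


def _session_counts(cfg: SyntheticCohortConfig, label: int, rng: np.random.Generator) -> list[int]:
    n = cfg.subjects_per_class
    lo, hi = cfg.sessions_per_subject
    if cfg.sessions_per_class_total is not None:
        total = cfg.sessions_per_class_total[label]
        if not n * lo <= total <= n * hi:
            raise ValueError(
                f"class {label}: total {total} sessions infeasible for {n} subjects in [{lo},{hi}]"
            )
        counts = [lo] * n
        k = 0
        for _ in range(total - n * lo):  # round-robin up to the cap
            while counts[k % n] >= hi:
                k += 1
            counts[k % n] += 1
            k += 1
        return counts
    return [int(rng.integers(lo, hi + 1)) for _ in range(n)]


def largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    """Apportion n items to fractions by largest remainder (ties to earlier bins)."""
    quotas = [n * f for f in fractions]
    base = [int(np.floor(q)) for q in quotas]
    short = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def subject_level_split(labels: pd.DataFrame, fractions=(0.7, 0.1, 0.2),
                        seed: int = 0) -> dict[str, list[str]]:
    """Disjoint train/val/test subject-id sets, per-class largest-remainder.

    All sessions of a subject follow the subject, so no subject spans
    partitions (leakage guard).
    """
    rng = np.random.default_rng(seed)
    split: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    per_subject = labels.drop_duplicates("subject_id")
    for _, grp in per_subject.groupby("class_label", sort=True):
        subjects = sorted(grp["subject_id"])
        rng.shuffle(subjects)
        n_tr, n_va, n_te = largest_remainder(len(subjects), tuple(fractions))
        if min(n_tr, n_va, n_te) < 1:
            raise ValueError(
                f"class with {len(subjects)} subjects cannot populate all partitions"
            )
        split["train"] += subjects[:n_tr]
        split["val"] += subjects[n_tr : n_tr + n_va]
        split["test"] += subjects[n_tr + n_va :]
    return {k: sorted(v) for k, v in split.items()}


def generate_cohort(cfg: SyntheticCohortConfig):
    """Generate the full cohort.

    Returns ``(sessions, labels, split)`` where ``sessions`` is a list of
    :class:`ROITimeSeries`, ``labels`` a DataFrame with columns
    subject_id / session_id / class_label, and ``split`` the subject-level
    partition dict.
    """
    rng = np.random.default_rng([cfg.seed, 10_000])
    sessions: list[ROITimeSeries] = []
    rows = []
    for label in range(cfg.n_classes):
        counts = _session_counts(cfg, label, rng)
        for s_idx, n_ses in enumerate(counts):
            subject_id = f"sub-c{label}s{s_idx:03d}"
            for ses in range(n_ses):
                session_id = f"{subject_id}_ses{ses}"
                sessions.append(
                    generate_session(cfg, label, s_idx, ses, subject_id, session_id)
                )
                rows.append((subject_id, session_id, label))
    labels = pd.DataFrame(rows, columns=["subject_id", "session_id", "class_label"])
    split = subject_level_split(labels, cfg.split_fractions, seed=cfg.seed)
    return sessions, labels, split


def write_cohort(cfg: SyntheticCohortConfig, out_dir: str | Path):
    """Materialise the cohort as per-session CSVs + labels.csv + split.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sessions, labels, split = generate_cohort(cfg)
    for ts in sessions:
        pd.DataFrame(ts.data).to_csv(out_dir / f"{ts.session_id}.csv",
                                     index=False, header=False)
    labels.to_csv(out_dir / "labels.csv", index=False)
    (out_dir / "split.json").write_text(json.dumps(split, indent=1))
    (out_dir / "cohort_config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    return sessions, labels, split


def desk_preset(n_classes: int = 2, delta_r: float = 0.4, seed: int = 0) -> SyntheticCohortConfig:
    """Canonical small cohort used throughout the test suite.

    N=20 regions (D=190 edges), T=137 time points (K=54 windows at Lw=30,
    s=2), 20 subjects per class with 1-2 sessions each (enough subjects that
    the 70/10/20 split leaves a usable validation and test partition).  Each class carries
    one planted discriminative edge at +``delta_r``; class 1 additionally has
    a transient coupling increase confined to windows 10-20, giving the
    temporal-importance probes a known target.
    """
    if n_classes not in (2, 4):
        raise ValueError("desk preset supports 2 or 4 classes")
    # Disease-stage signatures are diffuse: each class carries one primary
    # discriminative edge at the full delta_r plus weaker stationary
    # satellite edges (0.45 * delta_r).  Class 1 additionally recruits a
    # transient five-edge network in windows 10-20 (a coherent brain-state
    # episode), giving the temporal recovery probes a known target range.
    class_edges = {0: (3, 12), 1: (2, 7), 2: (6, 17), 3: (1, 13)}
    satellites = {
        0: [(0, 9), (5, 16), (11, 18), (1, 6), (8, 13), (14, 19)],
        1: [(0, 15), (3, 10), (6, 12), (4, 9), (11, 16), (7, 18)],
        2: [(2, 13), (5, 10), (0, 19), (9, 14), (3, 16), (1, 12)],
        3: [(4, 15), (2, 11), (7, 14), (0, 10), (6, 18), (5, 19)],
    }
    class_effects = {
        c: [(class_edges[c], delta_r)] + [(e, 0.45 * delta_r) for e in satellites[c]]
        for c in range(n_classes)
    }
    episode_edges = [(2, 7), (5, 14), (1, 9), (8, 16), (4, 18)]
    temporal_effects = {
        1: [TemporalEffect(window_range=(10, 20), edges=episode_edges, delta_r=0.35)]
    }
    return SyntheticCohortConfig(
        n_classes=n_classes,
        subjects_per_class=20,
        sessions_per_subject=(1, 2),
        n_rois=20,
        n_timepoints=137,
        tr_seconds=3.0,
        window_length=30,
        step=2,
        class_effects=class_effects,
        temporal_effects=temporal_effects,
        noise_sd=0.2,
        seed=seed,
    )


def adni_like_preset(seed: int = 0, n_rois: int = 20, n_timepoints: int = 137) -> SyntheticCohortConfig:
    """Cohort with the published four-stage census: subject counts
    (48, 50, 45, 31) and session totals (154, 165, 145, 99).

    Only the census is emulated; regions/time points stay at desk scale.
    """
    base = desk_preset(n_classes=4, seed=seed)
    counts = [48, 50, 45, 31]
    # subjects_per_class must be uniform in this config; use per-class configs
    cfg = SyntheticCohortConfig(
        n_classes=4,
        subjects_per_class=0,  # filled per class below by generate_census_cohort
        sessions_per_subject=(1, 6),
        n_rois=n_rois,
        n_timepoints=n_timepoints,
        class_effects=base.class_effects,
        temporal_effects=base.temporal_effects,
        noise_sd=base.noise_sd,
        seed=seed,
    )
    cfg.subjects_per_class_list = counts  # type: ignore[attr-defined]
    cfg.sessions_per_class_total = [154, 165, 145, 99]
    return cfg


def census_tables(cfg: SyntheticCohortConfig):
    """Labels table and split for a cohort with per-class subject counts
    given by ``cfg.subjects_per_class_list`` (no time series generated)."""
    counts = getattr(cfg, "subjects_per_class_list", None)
    if counts is None:
        counts = [cfg.subjects_per_class] * cfg.n_classes
    rng = np.random.default_rng([cfg.seed, 10_000])
    rows = []
    for label, n_subj in enumerate(counts):
        sub_cfg = SyntheticCohortConfig(**{**_plain_fields(cfg), "subjects_per_class": n_subj})
        sub_cfg.sessions_per_class_total = cfg.sessions_per_class_total
        ses_counts = _session_counts(sub_cfg, label, rng)
        for s_idx, n_ses in enumerate(ses_counts):
            subject_id = f"sub-c{label}s{s_idx:03d}"
            for ses in range(n_ses):
                rows.append((subject_id, f"{subject_id}_ses{ses}", label))
    labels = pd.DataFrame(rows, columns=["subject_id", "session_id", "class_label"])
    split = subject_level_split(labels, cfg.split_fractions, seed=cfg.seed)
    return labels, split


def _plain_fields(cfg: SyntheticCohortConfig) -> dict:
    return {
        "n_classes": cfg.n_classes,
        "subjects_per_class": cfg.subjects_per_class,
        "sessions_per_subject": cfg.sessions_per_subject,
        "n_rois": cfg.n_rois,
        "n_timepoints": cfg.n_timepoints,
        "tr_seconds": cfg.tr_seconds,
        "window_length": cfg.window_length,
        "step": cfg.step,
        "class_effects": cfg.class_effects,
        "temporal_effects": cfg.temporal_effects,
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "split_fractions": cfg.split_fractions,
    }
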