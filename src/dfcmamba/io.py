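"""Dataset loading, run configuration and checkpoint serialisation.

Sessions arrive as one CSV/TSV per scan (N ROI rows x T time-point columns,
with an optional header row and an optional leading column of ROI names),
indexed by a labels table with columns ``subject_id, session_id,
class_label`` and an optional subject-level split JSON.  Checkpoints are
single ``.npz`` files carrying every parameter plus JSON metadata
(architecture + training phase); loading refuses mismatched architectures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dfc import DFCConfig, ROITimeSeries
from .model import DFCClassifier, ModelConfig
from .train import TrainConfig

__all__ = [
    "load_session_csv",
    "load_cohort",
    "load_split",
    "RunConfig",
    "load_config",
    "save_checkpoint",
    "load_checkpoint",
    "validate_dataset",
    "aal116_names",
]


def load_session_csv(path: str | Path, subject_id: str, session_id: str,
                     label: int, tr_seconds: float = 3.0) -> ROITimeSeries:
    """Read one N x T session matrix; tolerates a header row / ROI-name column."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, header=None)
    if not _all_numeric(df.iloc[0, 1:]):  # textual header row
        df = df.iloc[1:, :]
    if not _all_numeric(df.iloc[:, 0]):  # ROI-name column
        df = df.iloc[:, 1:]
    data = df.astype(float).to_numpy()
    return ROITimeSeries(subject_id=subject_id, session_id=session_id,
                         label=label, data=data, tr_seconds=tr_seconds)


def _all_numeric(series: pd.Series) -> bool:
    try:
        pd.to_numeric(series)
        return True
    except (ValueError, TypeError):
        return False


def load_cohort(data_dir: str | Path, labels_path: str | Path | None = None,
                tr_seconds: float = 3.0) -> list[ROITimeSeries]:
    """Load every session named in the labels table from ``data_dir``."""
    data_dir = Path(data_dir)
    labels_path = Path(labels_path) if labels_path else data_dir / "labels.csv"
    labels = pd.read_csv(labels_path)
    required = {"subject_id", "session_id", "class_label"}
    if not required <= set(labels.columns):
        raise ValueError(f"labels table needs columns {sorted(required)}")
    sessions = []
    for row in labels.itertuples(index=False):
        matches = [data_dir / f"{row.session_id}{ext}" for ext in (".csv", ".tsv")]
        path = next((p for p in matches if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"no matrix file for session {row.session_id}")
        sessions.append(load_session_csv(path, row.subject_id, row.session_id,
                                         int(row.class_label), tr_seconds))
    return sessions


def load_split(path: str | Path) -> dict[str, list[str]]:
    split = json.loads(Path(path).read_text())
    missing = {"train", "val", "test"} - set(split)
    if missing:
        raise ValueError(f"split file missing partitions: {sorted(missing)}")
    return {k: list(split[k]) for k in ("train", "val", "test")}


# -------------------------------------------------------------------------
# Run configuration
# -------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Umbrella config: nested dfc / model / train sections plus run metadata."""

    dfc: DFCConfig = field(default_factory=DFCConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    run_name: str = "run"
    out_dir: str = "runs"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "dfc": asdict(self.dfc),
            "model": self.model.to_dict(),
            "train": asdict(self.train),
            "run_name": self.run_name,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from YAML/JSON; unknown keys are rejected by name.

    An empty or missing file yields the full default configuration
    (Lw=30, s=2, L=128, d_state=16, d_conv=4, E=2, 2 blocks, dropout 0.15,
    G=5, p=3, alpha=0.1, 15 warmup epochs, batch 32, 100+100 epochs).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = (yaml.safe_load(text) or {}) if text.strip() else {}
    if overrides:
        raw = _deep_merge(raw, overrides)
    known_top = {"dfc", "model", "train", "run_name", "out_dir", "log_level"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    dfc = _build(DFCConfig, raw.get("dfc", {}), "dfc")
    model_raw = dict(raw.get("model", {}))
    model_defaults = ModelConfig().to_dict()
    for section in ("vae", "mamba", "grid"):
        if section in model_raw:
            sect = model_raw[section]
            unknown = set(sect) - set(model_defaults[section])
            if unknown:
                raise ValueError(f"unknown config key(s) in model.{section}: {sorted(unknown)}")
            model_raw[section] = {**model_defaults[section], **sect}
    unknown = set(model_raw) - set(model_defaults)
    if unknown:
        raise ValueError(f"unknown config key(s) in model: {sorted(unknown)}")
    model = ModelConfig.from_dict({**model_defaults, **model_raw})
    train = _build(TrainConfig, raw.get("train", {}), "train")
    return RunConfig(dfc=dfc, model=model, train=train,
                     run_name=raw.get("run_name", "run"),
                     out_dir=raw.get("out_dir", "runs"),
                     log_level=raw.get("log_level", "INFO"))


def _build(cls, section: dict, name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) in {name}: {sorted(unknown)}")
    kwargs = dict(section)
    for key, val in kwargs.items():
        if isinstance(val, list) and cls.__dataclass_fields__[key].type.startswith("tuple"):
            kwargs[key] = tuple(val)
    return cls(**kwargs)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


# -------------------------------------------------------------------------
# Checkpoints
# -------------------------------------------------------------------------

def save_checkpoint(model: DFCClassifier, path: str | Path, phase: int,
                    extra_meta: dict | None = None) -> None:
    """Single-file parameter container with architecture metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"model_config": model.cfg.to_dict(), "phase": phase,
            "format_version": 1, **(extra_meta or {})}
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path, model: DFCClassifier | None = None):
    """Load a checkpoint; returns ``(model, meta)``.

    When ``model`` is given its architecture must match the checkpoint
    metadata exactly; with ``phase=1`` checkpoints only the VAE parameters
    are restored into a phase-2 model.
    """
    path = Path(path)
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    except Exception as exc:
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    cfg = ModelConfig.from_dict(meta["model_config"])
    if model is None:
        model = DFCClassifier(cfg, np.random.default_rng(0))
        model.load_state_dict(state)
        return model, meta
    if meta["phase"] == 1:
        # phase-1 checkpoints initialise only the VAE component
        if meta["model_config"]["vae"] != model.cfg.to_dict()["vae"]:
            raise ValueError("VAE architecture mismatch between checkpoint and model")
        vae_state = {k[len("vae."):]: v for k, v in state.items() if k.startswith("vae.")}
        model.vae.load_state_dict(vae_state)
        return model, meta
    if meta["model_config"] != model.cfg.to_dict():
        raise ValueError("architecture metadata mismatch between checkpoint and model")
    model.load_state_dict(state)
    return model, meta


# -------------------------------------------------------------------------
# Dataset validation
# -------------------------------------------------------------------------

def validate_dataset(data_dir: str | Path, labels_path: str | Path | None = None) -> dict:
    """Check shapes, finiteness, label coverage and session-subject
    consistency; returns a summary report with any violations listed."""
    data_dir = Path(data_dir)
    labels_path = Path(labels_path) if labels_path else data_dir / "labels.csv"
    problems: list[str] = []
    labels = pd.read_csv(labels_path)
    shapes = set()
    per_class: dict[int, int] = {}
    sub_class: dict[str, set[int]] = {}
    for row in labels.itertuples(index=False):
        label = int(row.class_label)
        per_class[label] = per_class.get(label, 0) + 1
        sub_class.setdefault(row.subject_id, set()).add(label)
        path = data_dir / f"{row.session_id}.csv"
        if not path.exists():
            problems.append(f"missing file: {path.name}")
            continue
        arr = pd.read_csv(path, header=None).to_numpy(dtype=float)
        shapes.add(arr.shape)
        bad = np.argwhere(~np.isfinite(arr))
        if bad.size:
            problems.append(f"{path.name}: non-finite value at row {int(bad[0, 0])}")
    for sub, classes in sub_class.items():
        if len(classes) > 1:
            problems.append(f"subject {sub} has inconsistent labels {sorted(classes)}")
    if len(shapes) > 1:
        problems.append(f"inconsistent matrix shapes: {sorted(shapes)}")
    return {
        "n_subjects": len(sub_class),
        "n_sessions": len(labels),
        "sessions_per_class": dict(sorted(per_class.items())),
        "shapes": sorted(shapes),
        "problems": problems,
        "ok": not problems,
    }


def aal116_names() -> list[str]:
    """The 116 region labels of the AAL atlas (for real-data runs)."""
    resource = Path(__file__).parent / "data" / "aal116_labels.txt"
    names = [line.strip() for line in resource.read_text().splitlines() if line.strip()]
    if len(names) != 116:
        raise RuntimeError(f"expected 116 AAL labels, found {len(names)}")
    return names
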