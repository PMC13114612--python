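"""Two-phase training, subject-level evaluation and multi-seed statistics.

Phase 1 pretrains the VAE alone on training-partition windows (no labels)
by minimising the negative ELBO.  Phase 2 fine-tunes the full pipeline on a
composite objective ``alpha * L_vae + beta * L_cls`` with differential
learning rates (VAE 1e-5, temporal encoder and head 1e-3); the VAE is kept
bit-frozen for the first warmup epochs so the downstream modules stabilise
before joint adaptation begins.

Evaluation is strictly subject-level: a subject's session probabilities are
averaged, the argmax is the subject prediction, and no subject ever spans
train/val/test partitions.  Multi-seed runs report mean +/- sd and a paired
t-test against a named baseline run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

from .autodiff import Tensor
from .dfc import DFCSequence
from .model import DFCClassifier, ModelConfig
from .nn import Adam

__all__ = [
    "TrainConfig",
    "EvalReport",
    "cross_entropy",
    "pretrain_vae",
    "joint_finetune",
    "aggregate_subject",
    "evaluate",
    "paired_t_test",
    "run_experiment",
    "multi_seed_run",
]


@dataclass
class TrainConfig:
    phase1_epochs: int = 100
    phase2_epochs: int = 100
    batch_size: int = 32
    lr_phase1: float = 1e-3
    lr_vae: float = 1e-5
    lr_mamba_kan: float = 1e-3
    alpha: float = 0.1  # weight of the VAE term in the joint objective
    cls_weight: float = 1.0  # beta: weight of the classification term
    warmup_epochs: int = 15
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    grid_update_every: int = 10
    grid_buffer_size: int = 1024
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])

    def __post_init__(self):
        if self.warmup_epochs > self.phase2_epochs:
            raise ValueError("warmup_epochs must not exceed phase2_epochs")
        for name in ("lr_phase1", "lr_vae", "lr_mamba_kan"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @staticmethod
    def desk() -> "TrainConfig":
        """Reduced schedule for single-CPU desk cohorts; same structure.

        The desk cohort has ~30 training sessions, so the batch size drops
        to 8 to keep a useful number of optimiser steps per epoch.
        """
        return TrainConfig(phase1_epochs=40, phase2_epochs=60, warmup_epochs=15,
                           batch_size=8)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Batch-mean negative log softmax probability of the true class."""
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    n_classes = logits.shape[-1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"label out of range [0, {n_classes})")
    logp = logits.log_softmax(axis=-1)
    if logp.ndim == 1:
        logp = logp.reshape((1, n_classes))
    picked = logp[np.arange(labels.size), labels]
    return -picked.mean()


# -------------------------------------------------------------------------
# Phase 1: unsupervised VAE pretraining on training-partition windows
# -------------------------------------------------------------------------

def _window_matrix(seqs: list[DFCSequence]) -> np.ndarray:
    return np.concatenate([s.vectors for s in seqs], axis=0)


def pretrain_vae(train_seqs: list[DFCSequence], val_seqs: list[DFCSequence],
                 model: DFCClassifier, cfg: TrainConfig, seed: int):
    """Train the VAE on all training windows; restore the lowest
    validation-reconstruction checkpoint.  Returns the loss history."""
    if not train_seqs:
        raise ValueError("empty training set")
    rng = np.random.default_rng([seed, 1])
    vae = model.vae
    windows = _window_matrix(train_seqs)
    val_windows = _window_matrix(val_seqs) if val_seqs else windows
    opt = Adam([{"params": vae.parameters(), "lr": cfg.lr_phase1}],
               beta1=cfg.adam_betas[0], beta2=cfg.adam_betas[1], eps=cfg.adam_eps)
    best = {"loss": np.inf, "state": vae.state_dict()}
    history = []
    n = windows.shape[0]
    for epoch in range(cfg.phase1_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            batch = windows[order[lo : lo + cfg.batch_size]]
            total, recon, kl = vae.loss(batch, rng, sample=True)
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_loss += total.item() * batch.shape[0]
        val_recon = _validation_recon(vae, val_windows, cfg.batch_size)
        history.append({"epoch": epoch, "train_loss": ep_loss / n, "val_recon": val_recon})
        if val_recon < best["loss"]:
            best = {"loss": val_recon, "state": vae.state_dict()}
    vae.load_state_dict(best["state"])
    return history


def _validation_recon(vae, windows: np.ndarray, batch_size: int) -> float:
    from .autodiff import no_grad

    total, count = 0.0, 0
    with no_grad():
        for lo in range(0, windows.shape[0], batch_size):
            batch = windows[lo : lo + batch_size]
            _, recon, _ = vae.loss(batch, np.random.default_rng(0), sample=False)
            total += recon.item() * batch.shape[0]
            count += batch.shape[0]
    return total / count


# -------------------------------------------------------------------------
# Phase 2: joint fine-tuning with differential learning rates + warmup freeze
# -------------------------------------------------------------------------

def joint_finetune(train_seqs: list[DFCSequence], val_seqs: list[DFCSequence],
                   model: DFCClassifier, cfg: TrainConfig, seed: int):
    """Optimise ``alpha * L_vae + beta * L_cls`` end to end.

    VAE parameters train at ``lr_vae`` and stay bit-frozen during the first
    ``warmup_epochs``; all other parameters train at ``lr_mamba_kan``.  The
    checkpoint with the highest validation subject-level accuracy (ties to
    lower validation loss) is restored.
    """
    if not train_seqs:
        raise ValueError("empty training set")
    rng = np.random.default_rng([seed, 2])
    vae_params = model.vae.parameters()
    vae_ids = {id(p) for p in vae_params}
    other_params = [p for p in model.parameters() if id(p) not in vae_ids]
    opt = Adam(
        [
            {"params": vae_params, "lr": cfg.lr_vae, "frozen": True},
            {"params": other_params, "lr": cfg.lr_mamba_kan},
        ],
        beta1=cfg.adam_betas[0], beta2=cfg.adam_betas[1], eps=cfg.adam_eps,
    )
    vectors = np.stack([s.vectors for s in train_seqs])  # (S, K, D)
    labels = np.array([s.label for s in train_seqs])
    best = {"acc": -1.0, "loss": np.inf, "state": model.state_dict()}
    history = []
    act_buffer: list[np.ndarray] = []
    n = vectors.shape[0]
    for epoch in range(cfg.phase2_epochs):
        opt.groups[0]["frozen"] = epoch < cfg.warmup_epochs
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            # posterior-mean latents: with KL-anchored sigma near 1 the
            # reparameterized samples drown the latent signal at this scale,
            # and evaluation uses means anyway
            res = model.forward(vectors[idx], train_mode=True, rng=rng, sample_latent=False)
            l_vae = res.recon + model.cfg.vae.kl_weight * res.kl
            l_cls = cross_entropy(res.logits, labels[idx])
            total = cfg.alpha * l_vae + cfg.cls_weight * l_cls
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_loss += total.item() * idx.size
            if model.cfg.head == "kan":
                act_buffer.append(res.context.data.reshape(-1, res.context.shape[-1]))
        refresh_window = epoch < cfg.phase2_epochs // 2  # grids settle early
        if (model.cfg.head == "kan" and cfg.grid_update_every > 0 and refresh_window
                and (epoch + 1) % cfg.grid_update_every == 0 and act_buffer):
            _refresh_kan_grids(model, act_buffer, cfg.grid_buffer_size)
            act_buffer = []
        val_report = evaluate(model, val_seqs) if val_seqs else None
        val_acc = val_report.accuracy if val_report else -1.0
        val_loss = _validation_cls_loss(model, val_seqs) if val_seqs else np.inf
        history.append({"epoch": epoch, "train_loss": ep_loss / n, "val_acc": val_acc,
                        "val_loss": val_loss, "vae_frozen": epoch < cfg.warmup_epochs})
        # checkpoints inside the warmup phase are not the trained
        # configuration (the VAE is still frozen) and are never selected
        eligible = epoch >= cfg.warmup_epochs or cfg.warmup_epochs >= cfg.phase2_epochs
        if eligible and val_report and (val_acc > best["acc"]
                                        or (val_acc == best["acc"] and val_loss < best["loss"])):
            best = {"acc": val_acc, "loss": val_loss, "state": model.state_dict()}
    if best["acc"] >= 0:
        model.load_state_dict(best["state"])
    return history


def _validation_cls_loss(model: DFCClassifier, val_seqs: list[DFCSequence]) -> float:
    """Session-level mean cross-entropy on the validation partition."""
    from .autodiff import no_grad

    vec = np.stack([s.vectors for s in val_seqs])
    labels = np.array([s.label for s in val_seqs])
    with no_grad():
        res = model.forward(vec, train_mode=False, sample_latent=False)
        return cross_entropy(res.logits, labels).item()


def _refresh_kan_grids(model: DFCClassifier, buffer: list[np.ndarray], cap: int) -> None:
    from .autodiff import no_grad

    acts = np.concatenate(buffer, axis=0)[-cap:]
    head = model.head
    head.layer1.update_grid(acts)
    with no_grad():
        hidden = head.hidden(acts).data
    head.layer2.update_grid(hidden)


# -------------------------------------------------------------------------
# Evaluation
# -------------------------------------------------------------------------

def aggregate_subject(session_probs: list[np.ndarray]) -> tuple[np.ndarray, int]:
    """Probability-average a subject's sessions; argmax label (ties -> first)."""
    if not session_probs:
        raise ValueError("subject has no sessions")
    mean = np.mean(np.stack(session_probs), axis=0)
    return mean, int(np.argmax(mean))


@dataclass
class EvalReport:
    accuracy: float  # all metrics in percent
    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion: np.ndarray
    n_subjects: int
    subject_probs: dict[str, np.ndarray] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "confusion": self.confusion.tolist(), "n_subjects": self.n_subjects,
        }


def evaluate(model: DFCClassifier, seqs: list[DFCSequence],
             split: dict[str, list[str]] | None = None) -> EvalReport:
    """Subject-level metrics on a set of sessions.

    If ``split`` is given, first asserts no subject appears in two
    partitions (leakage guard).
    """
    if split is not None:
        _assert_leak_free(split)
    if not seqs:
        raise ValueError("no sessions to evaluate")
    by_subject: dict[str, list[DFCSequence]] = {}
    for s in seqs:
        by_subject.setdefault(s.subject_id, []).append(s)
    truths, preds, probs, subject_probs = [], [], [], {}
    for subject in sorted(by_subject):
        sessions = by_subject[subject]
        label = sessions[0].label
        p, pred = aggregate_subject([model.predict_session(s) for s in sessions])
        truths.append(label)
        preds.append(pred)
        probs.append(p)
        subject_probs[subject] = p
    truths = np.array(truths)
    preds = np.array(preds)
    probs = np.stack(probs)
    n_classes = probs.shape[1]
    class_ids = np.arange(n_classes)
    acc = float(np.mean(truths == preds))
    if len(np.unique(preds)) < len(np.unique(truths)):
        warnings.warn("some classes never predicted; their precision counts as 0",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pre, rec, f1, _ = precision_recall_fscore_support(
            truths, preds, labels=class_ids, average="macro", zero_division=0
        )
    auc = None
    if n_classes == 2 and len(np.unique(truths)) == 2:
        auc = float(roc_auc_score(truths, probs[:, 1]))
    conf = _sk_confusion(truths, preds, labels=class_ids)
    return EvalReport(
        accuracy=100 * acc, precision=100 * float(pre), recall=100 * float(rec),
        f1=100 * float(f1), auc=auc, confusion=conf,
        n_subjects=len(truths), subject_probs=subject_probs,
    )


def _assert_leak_free(split: dict[str, list[str]]) -> None:
    parts = [set(split.get(k, [])) for k in ("train", "val", "test")]
    for i in range(len(parts)):
        for j in range(i + 1, len(parts)):
            inter = parts[i] & parts[j]
            if inter:
                raise ValueError(f"subject(s) {sorted(inter)} appear in two partitions")


def paired_t_test(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided paired t-test on run-level metric vectors.

    Zero-variance differences are flagged instead of producing NaN/inf:
    identical runs give t=0, p=1; constant nonzero differences are reported
    as degenerate with p=0.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("runs must share the same seed list")
    d = a - b
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        if np.allclose(d, 0.0):
            return {"t": 0.0, "p": 1.0, "significant": False, "degenerate": True}
        return {"t": float(np.inf) * np.sign(d.mean()), "p": 0.0,
                "significant": True, "degenerate": True}
    t, p = sps.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < 0.05),
            "degenerate": False}


# -------------------------------------------------------------------------
# Experiment drivers
# -------------------------------------------------------------------------

def split_sessions(seqs: list[DFCSequence], split: dict[str, list[str]]):
    _assert_leak_free(split)
    out = {}
    for part in ("train", "val", "test"):
        members = set(split[part])
        out[part] = [s for s in seqs if s.subject_id in members]
    return out["train"], out["val"], out["test"]


def run_experiment(seqs: list[DFCSequence], split: dict[str, list[str]],
                   model_cfg: ModelConfig, cfg: TrainConfig, seed: int,
                   variant: str = "full"):
    """Train one configuration end to end and evaluate on the test subjects.

    ``variant``: "full", "no_pretrain", "no_mamba"/"mean_pool", "mlp_head".
    """
    if variant in ("no_mamba", "mean_pool"):
        model_cfg = ModelConfig.from_dict({**model_cfg.to_dict(), "use_mamba": False})
    elif variant == "mlp_head":
        model_cfg = ModelConfig.from_dict({**model_cfg.to_dict(), "head": "mlp"})
    elif variant not in ("full", "no_pretrain"):
        raise ValueError(f"unknown variant {variant!r}")
    train_seqs, val_seqs, test_seqs = split_sessions(seqs, split)
    model = DFCClassifier(model_cfg, np.random.default_rng([seed, 0]))
    phase1_history = None
    if variant != "no_pretrain":
        phase1_history = pretrain_vae(train_seqs, val_seqs, model, cfg, seed)
    phase2_history = joint_finetune(train_seqs, val_seqs, model, cfg, seed)
    report = evaluate(model, test_seqs, split=split)
    return {
        "model": model,
        "report": report,
        "phase1_history": phase1_history,
        "phase2_history": phase2_history,
        "variant": variant,
        "seed": seed,
    }


def multi_seed_run(seqs, split, model_cfg: ModelConfig, cfg: TrainConfig,
                   variant: str = "full", seeds: list[int] | None = None):
    """Repeat an experiment over seeds; returns per-seed reports and summary."""
    seeds = list(cfg.seeds if seeds is None else seeds)
    if len(seeds) < 2:
        raise ValueError("multi-seed statistics need at least 2 seeds")
    runs = [run_experiment(seqs, split, model_cfg, cfg, s, variant) for s in seeds]
    accs = np.array([r["report"].accuracy for r in runs])
    return {
        "seeds": seeds,
        "runs": runs,
        "accuracies": accs,
        "mean": float(accs.mean()),
        "sd": float(accs.std(ddof=1)),
    }
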