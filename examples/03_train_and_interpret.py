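"""Train the full pipeline on a small synthetic cohort and interpret it.

Runs the two training phases (VAE pretraining, then joint fine-tuning with
differential learning rates and warmup freeze), evaluates at subject level,
and walks the three interpretability layers: temporal importance, KAN
activation curves and gradient attribution back to region pairs.

Takes a couple of minutes on one CPU.
"""

import warnings

import numpy as np

from dfcmamba import DFCConfig, ModelConfig, TrainConfig, build_dfc
from dfcmamba.interpret import (class_attribution, class_temporal_profile,
                                rank_activation_curves, region_ranking,
                                threshold_top_percent)
from dfcmamba.synth import desk_preset, generate_cohort
from dfcmamba.train import run_experiment

warnings.filterwarnings("ignore")

cfg = desk_preset(n_classes=2, delta_r=0.4, seed=0)
sessions, labels, split = generate_cohort(cfg)
seqs = [build_dfc(ts, DFCConfig()) for ts in sessions]

out = run_experiment(seqs, split, ModelConfig.desk(input_dim=190, n_classes=2),
                     TrainConfig.desk(), seed=0)
report = out["report"]
print(f"subject-level test accuracy: {report.accuracy:.1f}%  "
      f"(AUC {report.auc:.2f}, {report.n_subjects} subjects)")

model = out["model"]
test_seqs = [s for s in seqs if s.subject_id in set(split["test"])]

# layer 1: which scan windows mattered for the class with the transient state
prof = class_temporal_profile(model, test_seqs, class_label=1)
print(f"temporal importance (z): windows 10-20 mean {prof.mean_s[10:21].mean():+.2f} "
      f"vs elsewhere {np.delete(prof.mean_s, range(10, 21)).mean():+.2f} "
      "(the generator plants a coupling episode in windows 10-20)")

# layer 2: most influential latent dimensions and their learned curves
contexts = np.stack([model.forward(s.vectors).context.data for s in test_seqs])
curves = rank_activation_curves(model, contexts, top_k=3)
for c in curves:
    print(f"latent dim {c.i}: influence {c.influence:.3f}, curve {c.monotonic}")

# layer 3: attribution back to region pairs
att = class_attribution(model, test_seqs, target_class=1)
top = threshold_top_percent(att, percent=1.0)
print(f"top-1% attributed edges for class 1: {[(i, j) for i, j, _ in top]} "
      "(the planted discriminative edge is (2,7))")
print(region_ranking(att, top_n=4).to_string(index=False))
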