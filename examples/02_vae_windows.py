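"""Compress connectivity windows with the per-window variational autoencoder.

Builds a small cohort, pretrains the VAE on training-partition windows for a
few epochs, and prints the reconstruction improvement and the latent
sequence shape for one held-out session.
"""

import warnings

import numpy as np

from dfcmamba import DFCConfig, ModelConfig, TrainConfig, build_dfc
from dfcmamba.model import DFCClassifier
from dfcmamba.synth import desk_preset, generate_cohort
from dfcmamba.train import pretrain_vae, split_sessions

warnings.filterwarnings("ignore")

cfg = desk_preset(n_classes=2, seed=0)
sessions, labels, split = generate_cohort(cfg)
seqs = [build_dfc(ts, DFCConfig()) for ts in sessions]
train, val, test = split_sessions(seqs, split)

model = DFCClassifier(ModelConfig.desk(input_dim=190, n_classes=2),
                      np.random.default_rng(0))
tc = TrainConfig(phase1_epochs=10, phase2_epochs=1, warmup_epochs=1, batch_size=8)
history = pretrain_vae(train, val, model, tc, seed=0)

print(f"validation reconstruction: {history[0]['val_recon']:.3f} (epoch 0) -> "
      f"{min(h['val_recon'] for h in history):.3f} (best)")
latent = model.vae.encode_sequence(test[0])
print(f"latent sequence for one session: {latent.values.shape} "
      f"({latent.source}); each row encodes one connectivity window")
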