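"""Generate and inspect a synthetic multi-session cohort.

Writes per-session CSV matrices, a labels table and a subject-level split to
disk, then validates them — the exact on-disk layout the CLI and loaders
consume.
"""

import tempfile
from pathlib import Path

from dfcmamba.io import validate_dataset
from dfcmamba.synth import desk_preset, write_cohort

cfg = desk_preset(n_classes=2, seed=42)
cfg.subjects_per_class = 10

out_dir = Path(tempfile.mkdtemp()) / "cohort"
sessions, labels, split = write_cohort(cfg, out_dir)

print(f"wrote {len(sessions)} sessions for {labels.subject_id.nunique()} subjects to {out_dir}")
print("sessions per class:", labels.groupby("class_label").size().to_dict())
print("split sizes (subjects):", {k: len(v) for k, v in split.items()})

report = validate_dataset(out_dir)
print(f"validation: ok={report['ok']}, shapes={report['shapes']}")
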