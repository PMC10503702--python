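"""Generate a small synthetic two-cohort dataset and inspect its structure.

The generator emulates the behavioural testing session: per participant,
three mirror-game sessions of [Solo, 3 x Leader-Follower, Solo] one-minute
games plus six trail-making-task runs (parts A/B, three repetitions), with
variable sensor sampling rates and position saturation at the +/-0.5 rails.
"""

import numpy as np

from mirrortrail import generate_cohort_dataset, study_config, write_dataset

config = study_config(n_per_cohort=3, seed=7)
dataset = generate_cohort_dataset(config)

print(f"participants: {len(dataset.participants)}  "
      f"(config hash {dataset.provenance['synthetic_config_hash']})")
for p in dataset.participants:
    rates = {t.game_kind: round(1 / np.mean(np.diff(t.follower_series.timestamps)))
             for t in p.mg_trials}
    print(f"  {p.id}  cohort={p.cohort}  caarms={p.caarms}  "
          f"solo x{len(p.solo_trials())}, leader-follower x{len(p.lf_trials())}, "
          f"tmt x{len(p.tmt_logs)}; sensor rates ~{rates} Hz")

manifest = write_dataset(dataset, "scratch/example_dataset")
print(f"\nwritten to {manifest}")
print("Each mirror-game trial is a CSV of (time_s, position[, leader_position]);")
print("each TMT run is a CSV of (time_ms, target_index, on_target).")
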