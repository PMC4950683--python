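"""Simulate a small study group with known ground truth.

Generates rest, retest and task runs for a few synthetic subjects and
prints what the ground truth prescribes: per-subject hemodynamic delays
and the network geometry the connectivity stage should recover.
"""

import restex as rx

group = rx.generate_group(
    n_subjects=3, designs={"EDT": rx.edt_design()}, seed=7
)
truth = group.truth
print(f"grid {truth.grid}, {len(truth.network_masks)} network parcels, "
      f"noise sd {truth.noise_sd}, task amplitude {truth.task_amplitude}")
for sub, delay in sorted(truth.true_delays.items()):
    print(f"  {sub}: true hemodynamic delay {delay:.1f} s "
          f"({round(delay / truth.tr)} TRs)")
for sub in group.subjects:
    runs = {name: run.n_volumes for name, (run, _) in sub.runs.items()}
    print(f"  {sub.subject_id} runs (volumes): {runs}")

# Each network parcel shares a band-limited (0.009-0.08 Hz) latent signal;
# task runs add a delayed evoked response plus whole-brain nuisance
# structure, so every downstream stage has a known answer to recover.
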