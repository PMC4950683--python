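"""Per-subject hemodynamic delay from boxcar shifting.

The task boxcar is delayed in whole-TR steps (up to 7 TRs = 9.8 s) and
correlated with the mean response of an occipital region of interest;
the best-correlating shift is the subject's delay estimate. Here the
simulator knows each subject's true delay, so we can score the estimate.
"""

import restex as rx
from restex.pipeline import _estimate_subject_shift

edt = rx.edt_design()
truth = rx.default_ground_truth(subjects=4, seed=3)
roi = truth.network_masks["occipital"]

print("subject  true(TRs)  estimated(TRs)  peak r")
for sub in truth.subjects:
    run, _ = rx.generate_subject(edt, truth, sub, "task", run_label="EDT")
    est = _estimate_subject_shift(run, edt, roi)
    true_trs = round(truth.true_delays[sub] / edt.tr)
    print(f"{sub}   {true_trs}          {est.shift_trs} "
          f"({est.shift_seconds:.1f} s)      {est.peak_correlation:.3f}")

# The peak correlation is moderate (the ROI also carries spontaneous
# fluctuations and noise) but its argmax sits at or next to the true
# delay; noiseless inputs recover every delay 0-7 exactly.
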