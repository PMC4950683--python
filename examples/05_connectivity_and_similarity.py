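"""Seed connectivity maps and their similarity to continuous rest.

For one subject: run the connectivity stage (nuisance regression with
GSR, 0.009-0.08 Hz band-pass, 3x3x3 seed-cube correlation, Fisher z) on
the task-regression residuals and on a duration-matched rest run, then
score their agreement with ICC, Dice and R².
"""

import restex as rx
from restex.design import rest_design
from restex.extraction import ExtractionResult
from restex.pipeline import _estimate_subject_shift

truth = rx.default_ground_truth(subjects=2, seed=2)
edt = rx.edt_design()
task_run, task_conf = rx.generate_subject(edt, truth, "sub-01", "task", run_label="EDT")
rest_run, rest_conf = rx.generate_subject(
    rest_design(360), truth.zeroed(), "sub-01", "rest", run_label="rest"
)

shift = _estimate_subject_shift(task_run, edt, truth.network_masks["occipital"])
extraction = rx.apply_method("REG", task_run, task_conf, design=edt, shift=shift)

seeds = {name: truth.seed_voxel(name) for name in ("default_mode", "cuneus")}
task_maps = rx.run_connectivity(extraction, seeds, use_gsr=True)

rest_trimmed, conf_trimmed = rx.match_duration(
    rest_run, extraction.run.n_volumes, rest_conf
)
rest_ref = ExtractionResult(
    run=rest_trimmed, confounds=conf_trimmed, method="REST",
    retained_seconds=rest_trimmed.duration,
)
rest_maps = rx.run_connectivity(rest_ref, seeds, use_gsr=True)

for name in seeds:
    rec = rx.compare_maps(
        task_maps[name], rest_maps[name],
        subject="sub-01", method="REG", network=name, gsr=True,
    )
    print(f"{name:13s} ICC={rec.icc:.3f}  Dice={rec.dice:.3f}  R2={rec.r2:.3f} "
          f"({rec.n_voxels} voxels)")

# ICC and R² compare the unthresholded z maps (ICC also penalises mean
# offsets); Dice compares only the suprathreshold (z >= 0.3) voxel sets.
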