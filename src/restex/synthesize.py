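"""Synthetic multi-subject BOLD data with known ground truth.

The simulator emulates the statistical structure that the extraction and
connectivity stages rely on, on a desk-scale voxel grid (default
20 x 20 x 10):

* spatially contiguous networks whose voxels share a band-limited
  (0.009-0.08 Hz) latent fluctuation — the "coherent spontaneous
  activity" that seed-based connectivity detects;
* task-evoked responses, built from the paradigm boxcar shifted by a
  per-subject hemodynamic delay (an integer number of TRs) and dispersed
  by a zero-lag Gaussian kernel, so the recorded delay is the subject's
  total hemodynamic delay and is exactly what the boxcar-shift estimator
  measures (an alternative ``task_response="hrf"`` convolves with the
  canonical double-gamma instead, which adds that kernel's own lag on
  top). The response is strong and uniform on the designated activated
  parcels and weak but whole-brain through a fixed per-voxel gain field,
  the way block designs evoke focal activation plus distributed
  modulation;
* task-state modulation: ongoing network fluctuations are fractionally
  suppressed while the task is on (variability quenching), a
  multiplicative effect that task regression cannot remove;
* nuisance structure: a global fluctuation loading on every voxel,
  random-walk motion series leaking into a sparse voxel subset, and
  white-matter / ventricular components;
* additive white Gaussian noise.

Every random draw derives from ``GroundTruth.seed`` through named
substreams (subject, run label, component), so runs are bit-reproducible
and a task run differs from its amplitude-zero twin only by the task
component.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .bold import BoldRun, ConfoundSet
from .design import TaskDesign, boxcar, canonical_hrf, rest_design, write_events_tsv
from .filters import bandpass_timeseries

__all__ = [
    "GroundTruth",
    "SubjectData",
    "GroupData",
    "default_network_masks",
    "default_ground_truth",
    "draw_delays",
    "generate_subject",
    "generate_group",
    "save_group",
]

DEFAULT_GRID = (20, 20, 10)
#: network used both as the task-activated region and as the ROI for
#: hemodynamic-delay estimation (stands in for bilateral occipital spheres)
ACTIVATED_NETWORK = "occipital"


def default_network_masks(grid: tuple[int, int, int] = DEFAULT_GRID) -> dict[str, np.ndarray]:
    """Rectangular network parcels on the synthetic grid.

    Five connectivity networks mirror the seeded resting-state networks
    (default mode, cuneus, thalamus, sensorimotor, auditory); a sixth
    "occipital" parcel hosts the task activation and the delay-estimation
    ROI.
    """
    boxes = {
        "default_mode": (slice(2, 6), slice(2, 6), slice(2, 6)),
        "cuneus": (slice(8, 12), slice(2, 6), slice(2, 6)),
        "thalamus": (slice(14, 18), slice(2, 6), slice(2, 6)),
        "sensorimotor": (slice(2, 6), slice(8, 12), slice(4, 8)),
        "auditory": (slice(8, 12), slice(8, 12), slice(4, 8)),
        ACTIVATED_NETWORK: (slice(14, 18), slice(8, 12), slice(2, 6)),
    }
    masks = {}
    for name, box in boxes.items():
        mask = np.zeros(grid, dtype=bool)
        mask[box] = True
        masks[name] = mask
    return masks


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator needs, and everything a test may check against.

    ``true_delays`` maps subject id to the subject's total hemodynamic
    delay in seconds (an integer multiple of the TR, capped at 7 TRs).
    ``nuisance_weights`` holds per-voxel loadings (flattened over the
    brain mask) for the global, motion, white-matter and CSF components.
    """

    grid: tuple[int, int, int]
    network_masks: Mapping[str, np.ndarray]
    true_delays: Mapping[str, float]
    task_amplitude: float
    nuisance_weights: Mapping[str, np.ndarray]
    loadings: Mapping[str, np.ndarray]
    noise_sd: float
    seed: int
    tr: float = 1.4
    activated_networks: tuple[str, ...] = (ACTIVATED_NETWORK, "sensorimotor")
    dispersion_sd_s: float = 2.0
    task_response: str = "dispersed"  # or "hrf"
    #: sd of the weak whole-brain evoked gain field (fraction of task_amplitude)
    evoked_gain_sd: float = 0.3
    #: peak fractional suppression of network fluctuations during task blocks
    task_modulation: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.task_response not in ("dispersed", "hrf"):
            raise ValueError(f"unknown task_response {self.task_response!r}")
        for sub, delay in self.true_delays.items():
            steps = delay / self.tr
            if not np.isclose(steps, round(steps)) or not (0 <= round(steps) <= 7):
                raise ValueError(
                    f"true delay for {sub} must be an integer multiple of TR in [0, 7] TRs,"
                    f" got {delay}s"
                )

    @property
    def brain_mask(self) -> np.ndarray:
        return np.ones(self.grid, dtype=bool)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted(self.true_delays))

    def network_indices(self, name: str) -> np.ndarray:
        """Flat (mask-order) voxel indices of a network."""
        return np.flatnonzero(self.network_masks[name][self.brain_mask])

    def seed_voxel(self, name: str) -> tuple[int, int, int]:
        """Centroid voxel of a network mask, used as the seed-cube centre."""
        coords = np.argwhere(self.network_masks[name])
        return tuple(int(c) for c in np.floor(coords.mean(axis=0)))

    def zeroed(self) -> "GroundTruth":
        """Copy with the task amplitude explicitly zeroed (for rest runs)."""
        return replace(self, task_amplitude=0.0)


def draw_delays(
    subjects: list[str] | int,
    tr: float = 1.4,
    seed: int = 0,
    lo_trs: int = 2,
    hi_trs: int = 5,
) -> dict[str, float]:
    """Draw per-subject hemodynamic delays, uniform on {lo..hi} TR steps.

    The default 2-5 TRs (2.8-7.0 s at TR 1.4 s) brackets typical
    whole-response delays while staying under the 7-TR estimation cap.
    """
    if isinstance(subjects, int):
        subjects = [f"sub-{i + 1:02d}" for i in range(subjects)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE1A]))
    steps = rng.integers(lo_trs, hi_trs + 1, size=len(subjects))
    return {sub: float(k * tr) for sub, k in zip(subjects, steps)}


def default_ground_truth(
    subjects: list[str] | int = 8,
    seed: int = 0,
    grid: tuple[int, int, int] = DEFAULT_GRID,
    tr: float = 1.4,
    task_amplitude: float = 2.0,
    noise_sd: float = 1.0,
    **overrides,
) -> GroundTruth:
    """Build the default study conditions: masks, loadings, weights, delays."""
    if isinstance(subjects, int):
        subjects = [f"sub-{i + 1:02d}" for i in range(subjects)]
    masks = default_network_masks(grid)
    n_vox = int(np.prod(grid))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10AD]))
    loadings = {
        name: rng.uniform(0.8, 1.2, size=int(mask.sum()))
        for name, mask in sorted(masks.items())
    }
    motion_w = np.zeros((n_vox, 6))
    leak = rng.random(n_vox) < 0.2  # motion contaminates a sparse voxel subset
    motion_w[leak] = rng.normal(0.3, 0.05, size=(int(leak.sum()), 6))
    weights = {
        "global": rng.normal(0.6, 0.1, size=n_vox),
        "motion": motion_w,
        "white_matter": rng.normal(0.2, 0.05, size=n_vox),
        "csf": rng.normal(0.2, 0.05, size=n_vox),
        # unit-variance whole-brain evoked gain field; scaled by
        # task_amplitude * evoked_gain_sd at generation time
        "evoked_gain": rng.standard_normal(n_vox),
    }
    delays = draw_delays(subjects, tr=tr, seed=seed)
    return GroundTruth(
        grid=grid,
        network_masks=masks,
        true_delays=delays,
        task_amplitude=task_amplitude,
        nuisance_weights=weights,
        loadings=loadings,
        noise_sd=noise_sd,
        seed=seed,
        tr=tr,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------


def _stream(truth: GroundTruth, subject_id: str, run_label: str, component: str):
    key = [
        truth.seed,
        zlib.crc32(subject_id.encode()) & 0x7FFFFFFF,
        zlib.crc32(run_label.encode()) & 0x7FFFFFFF,
        zlib.crc32(component.encode()) & 0x7FFFFFFF,
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def _band_limited(rng, n: int, tr: float) -> np.ndarray:
    """Unit-variance noise with power concentrated in 0.009-0.08 Hz."""
    x = bandpass_timeseries(rng.standard_normal(n), tr)
    sd = x.std()
    return x / sd if sd > 0 else x


def _random_walk(rng, n: int) -> np.ndarray:
    x = np.cumsum(rng.standard_normal(n))
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def task_component(
    design: TaskDesign, truth: GroundTruth, subject_id: str
) -> np.ndarray:
    """Noise-free evoked time course for one subject (unit amplitude).

    Sum over task conditions of the boxcar delayed by the subject's true
    delay, then dispersed. ``task_response="dispersed"`` uses a
    symmetric (zero-lag) Gaussian kernel of sd ``dispersion_sd_s``;
    ``"hrf"`` uses causal convolution with the canonical double-gamma.
    """
    n = design.n_volumes
    d_trs = int(round(truth.true_delays[subject_id] / design.tr))
    total = np.zeros(n)
    for label in design.task_labels:
        box = boxcar(design, label).values
        delayed = np.zeros(n)
        delayed[d_trs:] = box[: n - d_trs]
        if truth.task_response == "dispersed":
            radius = max(1, int(np.ceil(3 * truth.dispersion_sd_s / design.tr)))
            k = np.arange(-radius, radius + 1) * design.tr
            g = np.exp(-0.5 * (k / truth.dispersion_sd_s) ** 2)
            g /= g.sum()
            total += np.convolve(delayed, g, mode="same")
        else:
            kernel = canonical_hrf(tr=design.tr)
            total += np.convolve(delayed, kernel)[:n]
    return total


def generate_subject(
    design: TaskDesign,
    truth: GroundTruth,
    subject_id: str,
    run_kind: str,
    run_label: str | None = None,
) -> tuple[BoldRun, ConfoundSet]:
    """Simulate one run (``run_kind`` "rest" or "task") for one subject.

    Returns the 4-D run and the generating confound series (six motion
    parameters, white matter, CSF, and the measured global mean of the
    simulated data). A rest run demands an explicitly zeroed task
    amplitude so that study conditions are never silently ignored.
    """
    if run_kind not in ("rest", "task"):
        raise ValueError(f"run_kind must be 'rest' or 'task', got {run_kind!r}")
    if subject_id not in truth.true_delays:
        raise KeyError(f"unknown subject {subject_id!r}")
    if run_kind == "rest" and truth.task_amplitude != 0:
        raise ValueError(
            "rest run requested with nonzero task_amplitude; "
            "zero it explicitly (GroundTruth.zeroed()) to confirm intent"
        )
    if run_kind == "task" and not design.task_labels:
        raise ValueError("task run requested but the design has no task events")

    label = run_label if run_label is not None else run_kind
    n = design.n_volumes
    tr = design.tr
    mask = truth.brain_mask
    n_vox = int(mask.sum())
    series = np.zeros((n, n_vox))

    evoked = None
    if run_kind == "task" and truth.task_amplitude != 0:
        evoked = task_component(design, truth, subject_id)

    # ongoing fluctuations are fractionally quenched while the task is on
    quench = 1.0
    if evoked is not None and truth.task_modulation > 0 and evoked.max() > 0:
        quench = 1.0 - truth.task_modulation * (evoked / evoked.max())

    for name in sorted(truth.network_masks):
        rng = _stream(truth, subject_id, label, f"latent:{name}")
        latent = _band_limited(rng, n, tr) * quench
        idx = truth.network_indices(name)
        series[:, idx] += latent[:, None] * truth.loadings[name][None, :]

    w = truth.nuisance_weights
    global_comp = _band_limited(_stream(truth, subject_id, label, "global"), n, tr)
    series += global_comp[:, None] * w["global"][None, :]
    motion = np.column_stack(
        [
            _random_walk(_stream(truth, subject_id, label, f"motion:{j}"), n)
            for j in range(6)
        ]
    )
    series += motion @ w["motion"].T
    wm = _band_limited(_stream(truth, subject_id, label, "white_matter"), n, tr)
    csf = _band_limited(_stream(truth, subject_id, label, "csf"), n, tr)
    series += wm[:, None] * w["white_matter"][None, :]
    series += csf[:, None] * w["csf"][None, :]

    if evoked is not None:
        focal = truth.task_amplitude * evoked
        for name in truth.activated_networks:
            series[:, truth.network_indices(name)] += focal[:, None]
        gains = truth.nuisance_weights.get("evoked_gain")
        if gains is not None and truth.evoked_gain_sd > 0:
            series += np.outer(focal, truth.evoked_gain_sd * gains)

    if truth.noise_sd > 0:
        noise_rng = _stream(truth, subject_id, label, "noise")
        series += truth.noise_sd * noise_rng.standard_normal(series.shape)

    data = np.zeros(truth.grid + (n,))
    data[mask] = series.T
    run = BoldRun(data=data, tr=tr, mask=mask)
    confounds = ConfoundSet(
        motion=motion,
        white_matter=wm,
        csf=csf,
        global_signal=series.mean(axis=1),
    )
    return run, confounds


# ---------------------------------------------------------------------------
# Group generation
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    subject_id: str
    runs: dict[str, tuple[BoldRun, ConfoundSet]] = field(default_factory=dict)


@dataclass
class GroupData:
    truth: GroundTruth
    designs: dict[str, TaskDesign]
    subjects: list[SubjectData]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def manifest(self) -> dict:
        return {
            "n_subjects": len(self.subjects),
            "seed": self.truth.seed,
            "tr": self.truth.tr,
            "designs": {
                name: {"n_volumes": d.n_volumes, "tr": d.tr}
                for name, d in self.designs.items()
            },
            "runs": {
                s.subject_id: sorted(s.runs) for s in self.subjects
            },
            "true_delays_s": {k: v for k, v in sorted(self.truth.true_delays.items())},
        }


def generate_group(
    n_subjects: int = 8,
    designs: Mapping[str, TaskDesign] | None = None,
    truth: GroundTruth | None = None,
    seed: int = 0,
    rest_duration_s: float = 360.0,
    n_rest_runs: int = 2,
    tr: float = 1.4,
) -> GroupData:
    """Simulate a study group: per subject, rest run(s) plus one task run
    per requested design.

    Rest runs are named ``rest`` and ``retest`` (then ``rest3``, ...);
    the second rest run is the test-retest reference condition.
    """
    if n_subjects < 2:
        raise ValueError("group statistics need n_subjects >= 2")
    if designs is None:
        from .design import edt_design, rft_design

        designs = {"EDT": edt_design(tr), "RFT": rft_design(tr)}
    if truth is None:
        truth = default_ground_truth(n_subjects, seed=seed, tr=tr)
    truth_rest = truth.zeroed()
    rest = rest_design(rest_duration_s, tr)
    rest_names = ["rest", "retest"] + [f"rest{i + 1}" for i in range(2, n_rest_runs)]
    all_designs = dict(designs)
    subjects = []
    for sub in truth.subjects:
        data = SubjectData(subject_id=sub)
        for rest_name in rest_names[:n_rest_runs]:
            data.runs[rest_name] = generate_subject(
                rest, truth_rest, sub, "rest", run_label=rest_name
            )
            all_designs[rest_name] = rest
        for design_name, design in designs.items():
            data.runs[design_name] = generate_subject(
                design, truth, sub, "task", run_label=design_name
            )
        subjects.append(data)
    return GroupData(truth=truth, designs=all_designs, subjects=subjects)


def save_group(group: GroupData, out_dir: str | Path) -> Path:
    """Write a group to disk: NIfTI runs, events/confounds TSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sub in group.subjects:
        sub_dir = out / sub.subject_id
        sub_dir.mkdir(exist_ok=True)
        for run_name, (run, confounds) in sub.runs.items():
            run.save(sub_dir / f"{run_name}_bold.nii")
            confounds.save(sub_dir / f"{run_name}_confounds.tsv")
            design = group.designs[run_name]
            if design.events:
                write_events_tsv(design, sub_dir / f"{run_name}_events.tsv")
    truth = group.truth
    truth_json = {
        "seed": truth.seed,
        "tr": truth.tr,
        "grid": list(truth.grid),
        "task_amplitude": truth.task_amplitude,
        "noise_sd": truth.noise_sd,
        "true_delays_s": dict(sorted(truth.true_delays.items())),
        "network_voxels": {
            name: np.argwhere(mask).tolist()
            for name, mask in sorted(truth.network_masks.items())
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json, indent=2))
    (out / "manifest.json").write_text(json.dumps(group.manifest(), indent=2))
    return out
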