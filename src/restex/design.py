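"""Block-design paradigms and hemodynamic response modelling.

A :class:`TaskDesign` is the timing skeleton of one fMRI run: labelled
blocks (task conditions and explicit baseline/crosshair blocks) on a
continuous time axis, plus the sampling grid (``tr``, ``n_volumes``).
Volume ``i`` is assigned the acquisition-onset time ``i * tr`` (0-based)
and block membership is decided on half-open intervals
``[onset, onset + duration)``.

The module also provides the canonical double-gamma hemodynamic response
function (the SPM-style default: response peak at 6 s, undershoot at
16 s, unit dispersions, undershoot ratio 1/6, 32 s support) and causal
convolution of boxcar regressors with it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "Event",
    "TaskDesign",
    "HrfParams",
    "Regressor",
    "boxcar",
    "canonical_hrf",
    "convolve_regressor",
    "rft_design",
    "edt_design",
    "rest_design",
    "read_events_tsv",
    "write_events_tsv",
    "design_from_json",
    "design_to_json",
]

BASELINE = "baseline"


@dataclass(frozen=True)
class Event:
    """One block: condition label, onset and duration in seconds."""

    label: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration}")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class TaskDesign:
    """Timing of a block-design run on the volume acquisition grid.

    Events are stored sorted by onset and must not overlap; every event
    must end within the sampled run (``onset + duration <= n_volumes * tr``).
    Baseline (crosshair) periods are either explicit events carrying
    ``baseline_label`` or, if none are present, the gaps between task
    blocks (including a leading/trailing gap).
    """

    events: tuple[Event, ...]
    tr: float
    n_volumes: int
    baseline_label: str = BASELINE

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if self.n_volumes <= 0:
            raise ValueError(f"n_volumes must be > 0, got {self.n_volumes}")
        events = tuple(sorted(self.events, key=lambda e: e.onset))
        object.__setattr__(self, "events", events)
        for prev, nxt in zip(events, events[1:]):
            if nxt.onset < prev.end - 1e-9:
                raise ValueError(
                    f"events overlap: {prev.label}@{prev.onset}s and {nxt.label}@{nxt.onset}s"
                )
        run_end = self.n_volumes * self.tr
        for ev in events:
            if ev.end > run_end + 1e-9:
                raise ValueError(
                    f"event {ev.label}@{ev.onset}s ends at {ev.end}s, past run end {run_end}s"
                )

    # -- basic geometry -------------------------------------------------

    @property
    def duration(self) -> float:
        """Sampled run length in seconds (``n_volumes * tr``)."""
        return self.n_volumes * self.tr

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition-onset time of each volume, ``i * tr``."""
        return np.arange(self.n_volumes) * self.tr

    @property
    def labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.label, None)
        return tuple(seen)

    @property
    def task_labels(self) -> tuple[str, ...]:
        """Condition labels excluding the baseline label."""
        return tuple(l for l in self.labels if l != self.baseline_label)

    def task_events(self) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.label != self.baseline_label)

    def baseline_periods(self) -> tuple[tuple[float, float], ...]:
        """Baseline ``(onset, end)`` windows in seconds.

        Explicit baseline events win; otherwise the gaps around/between
        task events are the implicit baseline.
        """
        explicit = [
            (e.onset, e.end) for e in self.events if e.label == self.baseline_label
        ]
        if explicit:
            return tuple(explicit)
        periods: list[tuple[float, float]] = []
        cursor = 0.0
        for ev in self.task_events():
            if ev.onset > cursor + 1e-9:
                periods.append((cursor, ev.onset))
            cursor = ev.end
        if self.duration > cursor + 1e-9:
            periods.append((cursor, self.duration))
        return tuple(periods)

    def with_events(self, events: Iterable[Event]) -> "TaskDesign":
        return replace(self, events=tuple(events))


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma hemodynamic response parameters (seconds where dimensional)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay",
            "undershoot_delay",
            "peak_dispersion",
            "undershoot_dispersion",
            "undershoot_ratio",
            "length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"HrfParams.{name} must be > 0")
        if self.length < self.undershoot_delay:
            raise ValueError("HrfParams.length must cover the undershoot delay")


@dataclass(frozen=True)
class Regressor:
    """A per-volume model time course with a condition label."""

    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("regressor values must be a 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("regressor values must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]


def boxcar(design: TaskDesign, label: str, *, strict: bool = True) -> Regressor:
    """Binary indicator of a condition on the volume grid.

    Volume ``i`` is 1 iff its acquisition time ``i * tr`` falls inside
    ``[onset, onset + duration)`` of any event carrying ``label``.

    With ``strict`` (default) an unknown label raises; with
    ``strict=False`` it yields an all-zero regressor.
    """
    if strict and label not in design.labels:
        raise KeyError(
            f"unknown condition label {label!r}; available labels: {sorted(design.labels)}"
        )
    t = design.frame_times
    values = np.zeros(design.n_volumes)
    for ev in design.events:
        if ev.label == label:
            values[(t >= ev.onset - 1e-12) & (t < ev.end - 1e-12)] = 1.0
    return Regressor(values=values, label=label)


def double_gamma(t: np.ndarray, params: HrfParams = HrfParams()) -> np.ndarray:
    """Unnormalised double-gamma response evaluated at times ``t`` (s).

    Difference of two gamma densities: a positive response lobe and a
    scaled undershoot, each parameterised by delay (mean-shape product)
    and dispersion (scale).
    """
    t = np.asarray(t, dtype=float)
    peak = _gamma_dist.pdf(
        t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion
    )
    under = _gamma_dist.pdf(
        t,
        params.undershoot_delay / params.undershoot_dispersion,
        scale=params.undershoot_dispersion,
    )
    return peak - params.undershoot_ratio * under


def canonical_hrf(params: HrfParams = HrfParams(), tr: float = 1.4) -> np.ndarray:
    """Double-gamma HRF kernel sampled on the TR grid, peak normalised to 1."""
    if tr <= 0:
        raise ValueError(f"tr must be > 0, got {tr}")
    n = math.ceil(params.length / tr)
    kernel = double_gamma(np.arange(n) * tr, params)
    peak = kernel.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel / peak


def convolve_regressor(box: Regressor, kernel: np.ndarray) -> Regressor:
    """Causal convolution of a regressor with an HRF kernel, truncated to run length."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0:
        raise ValueError("empty convolution kernel")
    out = np.convolve(box.values, kernel)[: len(box)]
    return Regressor(values=out, label=box.label)


# ---------------------------------------------------------------------------
# Paradigm templates
# ---------------------------------------------------------------------------


def _alternating(
    block_s: float,
    task_blocks: Sequence[str],
    baseline_s: float,
    *,
    lead_baseline: bool,
    trail_baseline: bool,
) -> list[Event]:
    events: list[Event] = []
    t = 0.0
    if lead_baseline:
        events.append(Event(BASELINE, t, baseline_s))
        t += baseline_s
    for i, label in enumerate(task_blocks):
        events.append(Event(label, t, block_s))
        t += block_s
        last = i == len(task_blocks) - 1
        if not last or trail_baseline:
            events.append(Event(BASELINE, t, baseline_s))
            t += baseline_s
    return events


def rft_design(tr: float = 1.4) -> TaskDesign:
    """Right-finger-tapping paradigm: 6 x 10 s tapping blocks interleaved
    with 7 x 10 s crosshair baselines (130 s paradigm)."""
    events = _alternating(
        10.0, ["tap"] * 6, 10.0, lead_baseline=True, trail_baseline=True
    )
    n_volumes = math.ceil(130.0 / tr)
    return TaskDesign(events=tuple(events), tr=tr, n_volumes=n_volumes)


def edt_design(tr: float = 1.4) -> TaskDesign:
    """Emotion-discrimination paradigm: 4 emotion + 4 object 20 s blocks,
    alternating, interleaved with 20 s crosshair baselines plus a final
    baseline block (block list totals 340 s)."""
    task_blocks = ["emotion", "object"] * 4
    events = _alternating(
        20.0, task_blocks, 20.0, lead_baseline=True, trail_baseline=True
    )
    total = events[-1].end
    n_volumes = math.ceil(total / tr)
    return TaskDesign(events=tuple(events), tr=tr, n_volumes=n_volumes)


def rest_design(duration_s: float = 360.0, tr: float = 1.4) -> TaskDesign:
    """An event-free design describing a continuous resting-state run."""
    return TaskDesign(events=(), tr=tr, n_volumes=int(duration_s // tr))


# ---------------------------------------------------------------------------
# I/O: BIDS-events-style TSV and JSON templates
# ---------------------------------------------------------------------------


def read_events_tsv(
    path: str | Path,
    tr: float,
    n_volumes: int,
    baseline_label: str = BASELINE,
) -> TaskDesign:
    """Read a BIDS-events-style TSV (columns onset, duration, trial_type)."""
    table = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"events table {path} lacks columns {sorted(missing)}")
    events = tuple(
        Event(str(row.trial_type), float(row.onset), float(row.duration))
        for row in table.itertuples()
    )
    return TaskDesign(
        events=events, tr=tr, n_volumes=n_volumes, baseline_label=baseline_label
    )


def write_events_tsv(design: TaskDesign, path: str | Path) -> None:
    table = pd.DataFrame(
        {
            "onset": [e.onset for e in design.events],
            "duration": [e.duration for e in design.events],
            "trial_type": [e.label for e in design.events],
        }
    )
    table.to_csv(path, sep="\t", index=False)


def design_to_json(design: TaskDesign) -> dict:
    return {
        "tr": design.tr,
        "n_volumes": design.n_volumes,
        "baseline_label": design.baseline_label,
        "events": [
            {"label": e.label, "onset": e.onset, "duration": e.duration}
            for e in design.events
        ],
    }


def design_from_json(obj: dict | str | Path) -> TaskDesign:
    if not isinstance(obj, dict):
        obj = json.loads(Path(obj).read_text())
    events = tuple(
        Event(e["label"], float(e["onset"]), float(e["duration"]))
        for e in obj["events"]
    )
    return TaskDesign(
        events=events,
        tr=float(obj["tr"]),
        n_volumes=int(obj["n_volumes"]),
        baseline_label=obj.get("baseline_label", BASELINE),
    )
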