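"""The five task-to-rest extraction methods.

* ``ORIG`` — the unmodified task run.
* ``BLOCK`` — concatenation of baseline (crosshair) blocks with fixed
  conservative cuts: ~15 s discarded after each task block for the
  hemodynamic response to settle, and the first 5 s of each task block
  still counted as rest.
* ``BLOCKVAR`` — concatenation with subject-specific cuts: each baseline
  window is the crosshair onset plus the subject's estimated
  hemodynamic delay, lasting the full crosshair duration.
* ``REG`` — voxelwise least-squares regression against HRF-convolved
  task regressors; the residuals are the task-cleaned series.
* ``BLOCKREG`` — regression first, then baseline concatenation with the
  subject-specific (``BLOCKVAR``) windows.

Confound series are cut and concatenated identically to the data so the
downstream nuisance regression stays temporally consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .bold import BoldRun, ConfoundSet
from .delay import ShiftEstimate
from .design import HrfParams, TaskDesign, boxcar, canonical_hrf, convolve_regressor

__all__ = [
    "METHODS",
    "SegmentList",
    "ExtractionResult",
    "InsufficientDataError",
    "segments_fixed",
    "segments_var",
    "shifted_baseline_windows",
    "concatenate_run",
    "ols_residuals",
    "apply_method",
]

METHODS = ("ORIG", "BLOCK", "BLOCKVAR", "REG", "BLOCKREG")

_EPS = 1e-9


class InsufficientDataError(RuntimeError):
    """Raised when concatenation retains less data than the configured minimum."""


@dataclass(frozen=True)
class SegmentList:
    """Half-open, 0-based volume-index intervals selected as resting data."""

    intervals: tuple[tuple[int, int], ...]
    tr: float
    n_volumes: int | None = None

    def __post_init__(self) -> None:
        intervals = tuple((int(a), int(b)) for a, b in self.intervals)
        object.__setattr__(self, "intervals", intervals)
        prev_end = -1
        for start, end in intervals:
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval [{start}, {end})")
            if start < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = end
            if self.n_volumes is not None and end > self.n_volumes:
                raise ValueError(
                    f"interval [{start}, {end}) exceeds run length {self.n_volumes}"
                )

    def indices(self) -> np.ndarray:
        if not self.intervals:
            return np.empty(0, dtype=int)
        return np.concatenate([np.arange(a, b) for a, b in self.intervals])

    @property
    def total_volumes(self) -> int:
        return sum(b - a for a, b in self.intervals)

    @property
    def total_seconds(self) -> float:
        return self.total_volumes * self.tr

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "intervals": [[a, b] for a, b in self.intervals],
            "tr": self.tr,
            "n_volumes": self.n_volumes,
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2))
        return obj


@dataclass(frozen=True)
class ExtractionResult:
    """A (possibly shortened) run plus identically cut confounds."""

    run: BoldRun
    confounds: ConfoundSet
    method: str
    retained_seconds: float
    segments: SegmentList | None = None

    def __post_init__(self) -> None:
        if self.run.n_volumes != self.confounds.n_volumes:
            raise ValueError("run and confounds must have equal length")
        expected = self.run.n_volumes * self.run.tr
        if not math.isclose(self.retained_seconds, expected, rel_tol=1e-9):
            raise ValueError("retained_seconds must equal n_volumes * tr")


def _volume_interval(start_s: float, end_s: float, tr: float, n_volumes: int):
    """Seconds to half-open volume indices: start rounds up, end rounds down."""
    a = max(0, math.ceil(start_s / tr - _EPS))
    b = min(n_volumes, math.floor(end_s / tr + _EPS))
    return (a, b) if b > a else None


def segments_fixed(
    design: TaskDesign,
    post_gap: float = 15.0,
    pre_extension: float = 5.0,
    pre_extension_mode: str = "into_task",
) -> SegmentList:
    """Fixed-cut baseline windows (the conservative concatenation rule).

    Per baseline period the retained window runs from the end of the
    preceding task block plus ``post_gap`` (or the baseline onset when
    nothing precedes) up to the following task onset plus
    ``pre_extension`` (the first seconds of a task block are still
    hemodynamically rest). ``pre_extension_mode="baseline_head"``
    instead caps the window at ``baseline onset + pre_extension``, the
    alternative reading in which only the head of the baseline itself
    counts. Windows are converted to volumes conservatively (start
    rounds up, end rounds down) and empty ones are dropped.
    """
    if pre_extension_mode not in ("into_task", "baseline_head"):
        raise ValueError(f"unknown pre_extension_mode {pre_extension_mode!r}")
    periods = design.baseline_periods()
    if not periods:
        raise ValueError("design has no baseline periods")
    tasks = design.task_events()
    intervals = []
    for b_onset, b_end in periods:
        preceding = [e for e in tasks if e.end <= b_onset + _EPS]
        following = [e for e in tasks if e.onset >= b_end - _EPS]
        start_s = preceding[-1].end + post_gap if preceding else b_onset
        if following:
            if pre_extension_mode == "into_task":
                end_s = following[0].onset + pre_extension
            else:
                end_s = min(b_onset + pre_extension, b_end)
        else:
            end_s = b_end
        end_s = min(end_s, design.duration)
        iv = _volume_interval(start_s, end_s, design.tr, design.n_volumes)
        if iv is not None:
            intervals.append(iv)
    return SegmentList(
        intervals=tuple(intervals), tr=design.tr, n_volumes=design.n_volumes
    )


def shifted_baseline_windows(
    design: TaskDesign, shift_seconds: float
) -> list[tuple[float, float]]:
    """Delay-adjusted baseline windows in seconds, truncated at the run end.

    Each window starts at the crosshair onset plus the subject's
    hemodynamic delay and lasts the full crosshair duration.
    """
    windows = []
    for b_onset, b_end in design.baseline_periods():
        start = b_onset + shift_seconds
        end = min(start + (b_end - b_onset), design.duration)
        if end > start:
            windows.append((start, end))
    return windows


def segments_var(
    design: TaskDesign, shift: ShiftEstimate | float
) -> SegmentList:
    """Subject-specific baseline windows from an estimated hemodynamic delay."""
    shift_s = shift.shift_seconds if isinstance(shift, ShiftEstimate) else float(shift)
    intervals = []
    for start_s, end_s in shifted_baseline_windows(design, shift_s):
        iv = _volume_interval(start_s, end_s, design.tr, design.n_volumes)
        if iv is not None:
            intervals.append(iv)
    return SegmentList(
        intervals=tuple(intervals), tr=design.tr, n_volumes=design.n_volumes
    )


def concatenate_run(
    run: BoldRun,
    confounds: ConfoundSet,
    segments: SegmentList,
    min_duration_s: float = 30.0,
    method: str = "BLOCK",
) -> ExtractionResult:
    """Slice data and confounds at the same volume indices and concatenate.

    Values are preserved exactly; only selection (in temporal order)
    happens here. Raises :class:`InsufficientDataError` when less than
    ``min_duration_s`` of data would remain — the concatenation methods
    are not meaningful on a handful of volumes.
    """
    if run.n_volumes != confounds.n_volumes:
        raise ValueError("run and confounds must have equal length")
    if not segments.intervals:
        raise InsufficientDataError(f"{method}: no baseline segments survive cutting")
    if segments.n_volumes is not None and segments.n_volumes != run.n_volumes:
        raise ValueError("segment list was built for a different run length")
    retained = segments.total_seconds
    if retained < min_duration_s:
        raise InsufficientDataError(
            f"{method}: only {retained:.1f} s of baseline data retained, "
            f"below the {min_duration_s:.0f} s minimum"
        )
    idx = segments.indices()
    return ExtractionResult(
        run=run.select_volumes(idx),
        confounds=confounds.select_volumes(idx),
        method=method,
        retained_seconds=retained,
        segments=segments,
    )


def ols_residuals(
    series_matrix: np.ndarray, regressors: np.ndarray, add_intercept: bool = True
) -> np.ndarray:
    """Least-squares residuals of each channel against the regressors.

    ``series_matrix`` is (time, channels); ``regressors`` is (time, k).
    An intercept is always part of the fit, so residuals are mean-free
    and orthogonal to every regressor column. A rank-deficient design
    raises with the offending (collinear) column indices.
    """
    y = np.asarray(series_matrix, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.shape[0] != x.shape[0]:
        raise ValueError("series and regressors must share the time dimension")
    design = np.column_stack([np.ones(y.shape[0]), x]) if add_intercept else x
    if y.shape[0] <= design.shape[1]:
        raise ValueError(
            f"need more time points ({y.shape[0]}) than regressors ({design.shape[1]})"
        )
    _, r_diag, pivots = scipy.linalg.qr(design, mode="economic", pivoting=True)[0:3]
    diag = np.abs(np.diag(r_diag))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    deficient = pivots[diag < tol]
    if deficient.size:
        offset = 1 if add_intercept else 0
        cols = sorted(int(c) - offset for c in deficient)
        raise ValueError(
            f"rank-deficient regressor matrix; collinear columns (0-based, "
            f"-1 = intercept): {cols}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _task_regressors(design: TaskDesign, hrf: HrfParams) -> np.ndarray:
    kernel = canonical_hrf(hrf, design.tr)
    cols = [
        convolve_regressor(boxcar(design, label), kernel).values
        for label in design.task_labels
    ]
    if not cols:
        raise ValueError("design has no task conditions to regress out")
    return np.column_stack(cols)


def apply_method(
    method: str,
    run: BoldRun,
    confounds: ConfoundSet,
    design: TaskDesign | None = None,
    hrf: HrfParams = HrfParams(),
    shift: ShiftEstimate | float | None = None,
    min_retained_s: float = 30.0,
    post_gap: float = 15.0,
    pre_extension: float = 5.0,
    pre_extension_mode: str = "into_task",
    blockreg_intervals: str = "var",
) -> ExtractionResult:
    """Run one extraction method end to end.

    ``BLOCK``/``BLOCKVAR``/``BLOCKREG`` need a block ``design``;
    ``BLOCKVAR``/``BLOCKREG`` additionally need the subject's ``shift``
    estimate. ``blockreg_intervals`` selects whether ``BLOCKREG`` reuses
    the delay-adjusted (``"var"``, default) or the fixed (``"fixed"``)
    cutting windows.
    """
    name = method.upper()
    if name not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if name != "ORIG" and design is None:
        raise ValueError(f"{name} requires a task design")
    if name in ("BLOCKVAR", "BLOCKREG") and shift is None:
        raise ValueError(f"{name} requires a hemodynamic shift estimate")

    if name == "ORIG":
        return ExtractionResult(
            run=run,
            confounds=confounds,
            method=name,
            retained_seconds=run.duration,
        )
    if name == "BLOCK":
        segments = segments_fixed(
            design, post_gap, pre_extension, pre_extension_mode
        )
        return concatenate_run(run, confounds, segments, min_retained_s, name)
    if name == "BLOCKVAR":
        segments = segments_var(design, shift)
        return concatenate_run(run, confounds, segments, min_retained_s, name)

    # REG and BLOCKREG start from task-regression residuals
    residuals = ols_residuals(run.timeseries(), _task_regressors(design, hrf))
    cleaned = run.with_timeseries(residuals)
    if name == "REG":
        return ExtractionResult(
            run=cleaned,
            confounds=confounds,
            method=name,
            retained_seconds=cleaned.duration,
        )
    if blockreg_intervals == "var":
        segments = segments_var(design, shift)
    elif blockreg_intervals == "fixed":
        segments = segments_fixed(design, post_gap, pre_extension, pre_extension_mode)
    else:
        raise ValueError(f"unknown blockreg_intervals {blockreg_intervals!r}")
    return concatenate_run(cleaned, confounds, segments, min_retained_s, name)
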