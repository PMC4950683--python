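"""Per-subject hemodynamic delay estimation by boxcar shifting.

The theoretical task boxcar is delayed in whole-TR steps (zero-padded at
the front, truncated at the run end) and correlated with a measured
region-of-interest response; the shift with the highest Pearson
correlation is the subject's delay estimate. The search is capped at
7 TRs (9.8 s at TR 1.4 s); ties resolve to the smaller shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .bold import BoldRun
from .design import Regressor

__all__ = ["ShiftEstimate", "roi_mean_timecourse", "estimate_shift"]

MAX_SHIFT_TRS = 7


@dataclass(frozen=True)
class ShiftEstimate:
    """Result of the shift search: best shift and the full correlation profile."""

    shift_trs: int
    shift_seconds: float
    peak_correlation: float
    correlation_profile: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        profile = np.asarray(self.correlation_profile, dtype=float)
        object.__setattr__(self, "correlation_profile", profile)
        if self.shift_trs < 0 or self.shift_trs >= profile.size:
            raise ValueError("shift_trs outside the searched range")
        if not np.isclose(self.shift_seconds, self.shift_trs * self.tr):
            raise ValueError("shift_seconds must equal shift_trs * tr")
        if not np.isclose(self.peak_correlation, profile.max()):
            raise ValueError("peak_correlation must be the profile maximum")

    def to_json(self, path: str | Path | None = None) -> dict:
        obj = {
            "shift_trs": int(self.shift_trs),
            "shift_seconds": float(self.shift_seconds),
            "peak_correlation": float(self.peak_correlation),
            "correlation_profile": [float(v) for v in self.correlation_profile],
            "tr": float(self.tr),
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2))
        return obj

    @classmethod
    def from_json(cls, obj: dict | str | Path) -> "ShiftEstimate":
        if not isinstance(obj, dict):
            obj = json.loads(Path(obj).read_text())
        return cls(
            shift_trs=int(obj["shift_trs"]),
            shift_seconds=float(obj["shift_seconds"]),
            peak_correlation=float(obj["peak_correlation"]),
            correlation_profile=np.asarray(obj["correlation_profile"], dtype=float),
            tr=float(obj["tr"]),
        )


def roi_mean_timecourse(run: BoldRun, roi_mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean series over a region of interest."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != run.mask.shape:
        raise ValueError(
            f"ROI mask shape {roi_mask.shape} does not match volume {run.mask.shape}"
        )
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    if np.any(roi_mask & ~run.mask):
        raise ValueError("ROI mask extends outside the brain mask")
    return run.data[roi_mask].mean(axis=0)


def _delayed(values: np.ndarray, shift: int) -> np.ndarray:
    out = np.zeros_like(values)
    if shift == 0:
        return values.copy()
    out[shift:] = values[:-shift]
    return out


def estimate_shift(
    roi_ts: np.ndarray,
    box: Regressor | np.ndarray,
    tr: float,
    max_shift_trs: int = MAX_SHIFT_TRS,
    kernel: np.ndarray | None = None,
) -> ShiftEstimate:
    """Find the whole-TR delay maximising correlation with the ROI response.

    For every candidate shift ``s`` in ``0..max_shift_trs`` the boxcar is
    delayed by ``s`` volumes (front-padded with zeros, truncated at the
    run end) and Pearson-correlated with ``roi_ts`` over the full run.
    Optionally each delayed boxcar is first convolved with ``kernel``
    (e.g. a canonical HRF) — the response-model variant of the search.

    Ties in the profile resolve to the smaller shift.
    """
    roi_ts = np.asarray(roi_ts, dtype=float)
    values = box.values if isinstance(box, Regressor) else np.asarray(box, dtype=float)
    if roi_ts.shape != values.shape:
        raise ValueError(
            f"ROI series (n={roi_ts.size}) and boxcar (n={values.size}) lengths differ"
        )
    if roi_ts.size < max_shift_trs + 2:
        raise ValueError(
            f"series too short ({roi_ts.size}) for a {max_shift_trs}-TR shift search"
        )
    if np.ptp(values) == 0:
        raise ValueError("boxcar is constant; correlation undefined")
    if np.ptp(roi_ts) == 0:
        raise ValueError("ROI series is constant; correlation undefined")

    profile = np.empty(max_shift_trs + 1)
    for s in range(max_shift_trs + 1):
        candidate = _delayed(values, s)
        if kernel is not None:
            candidate = np.convolve(candidate, np.asarray(kernel, float))[: values.size]
        if np.ptp(candidate) == 0:
            profile[s] = -np.inf  # shift pushed every event off the run
            continue
        profile[s] = np.corrcoef(roi_ts, candidate)[0, 1]
    best = int(np.argmax(profile))  # argmax takes the first (smallest) maximiser
    return ShiftEstimate(
        shift_trs=best,
        shift_seconds=best * tr,
        peak_correlation=float(profile[best]),
        correlation_profile=profile,
        tr=tr,
    )
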