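"""In-memory containers for 4-D BOLD runs and their confound series.

``BoldRun`` keeps the voxel grid as an ``(x, y, z, t)`` array with a 3-D
brain mask and TR; the masked 2-D view ``timeseries()`` (time x voxel)
is what the numerical stages operate on. ``ConfoundSet`` carries the
standard nuisance series (six rigid-body motion parameters, white
matter, ventricular/CSF, global mean), one value per volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["BoldRun", "ConfoundSet", "MOTION_COLUMNS", "CONFOUND_COLUMNS"]

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
CONFOUND_COLUMNS = MOTION_COLUMNS + ("white_matter", "csf", "global_signal")


@dataclass(frozen=True)
class BoldRun:
    """One 4-D BOLD run: ``data[x, y, z, t]``, brain mask, TR and affine."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D (x, y, z, t), got shape {data.shape}")
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {data.shape[:3]}"
            )
        if not mask.any():
            raise ValueError("brain mask is empty")
        if data.shape[3] < 2:
            raise ValueError("a BOLD run needs at least 2 volumes")
        if self.tr <= 0:
            raise ValueError(f"tr must be > 0, got {self.tr}")
        if not np.all(np.isfinite(data[mask])):
            raise ValueError("non-finite values inside the brain mask")
        affine = self.affine if self.affine is not None else np.eye(4)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", np.asarray(affine, dtype=float))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def duration(self) -> float:
        return self.n_volumes * self.tr

    def timeseries(self) -> np.ndarray:
        """Masked series as a (time, voxel) matrix; voxel order follows the mask."""
        return self.data[self.mask].T.copy()

    def with_timeseries(self, series: np.ndarray) -> "BoldRun":
        """Rebuild a run from a (time, voxel) matrix over the same mask.

        Voxels outside the mask are zeroed; the number of volumes may change.
        """
        series = np.asarray(series, dtype=float)
        if series.ndim != 2 or series.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"expected (time, {int(self.mask.sum())}) matrix, got {series.shape}"
            )
        data = np.zeros(self.mask.shape + (series.shape[0],))
        data[self.mask] = series.T
        return replace(self, data=data)

    def select_volumes(self, indices: np.ndarray) -> "BoldRun":
        return replace(self, data=self.data[..., np.asarray(indices, dtype=int)])

    # -- NIfTI I/O ------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (self.tr,))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path | nib.Nifti1Image,
        tr: float | None = None,
        mask: np.ndarray | None = None,
    ) -> "BoldRun":
        img = path if isinstance(path, nib.Nifti1Image) else nib.load(str(path))
        data = np.asarray(img.get_fdata())
        if tr is None:
            zooms = img.header.get_zooms()
            tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
        if tr <= 0:
            raise ValueError("TR not recorded in the NIfTI header; pass tr explicitly")
        if mask is None:
            mask = np.ones(data.shape[:3], dtype=bool)
        return cls(data=data, tr=float(tr), mask=mask, affine=img.affine)


@dataclass(frozen=True)
class ConfoundSet:
    """Per-volume nuisance series: motion (6), white matter, CSF, global mean."""

    motion: np.ndarray
    white_matter: np.ndarray
    csf: np.ndarray
    global_signal: np.ndarray

    def __post_init__(self) -> None:
        motion = np.asarray(self.motion, dtype=float)
        if motion.ndim != 2 or motion.shape[1] != 6:
            raise ValueError(f"motion must be (time, 6), got shape {motion.shape}")
        n = motion.shape[0]
        cols = {}
        for name in ("white_matter", "csf", "global_signal"):
            col = np.asarray(getattr(self, name), dtype=float).ravel()
            if col.shape[0] != n:
                raise ValueError(f"confound column {name} has length {col.shape[0]}, expected {n}")
            cols[name] = col
        stacked = np.column_stack([motion] + list(cols.values()))
        if not np.all(np.isfinite(stacked)):
            raise ValueError("confound series must be finite")
        object.__setattr__(self, "motion", motion)
        for name, col in cols.items():
            object.__setattr__(self, name, col)

    @property
    def n_volumes(self) -> int:
        return self.motion.shape[0]

    def select_volumes(self, indices: np.ndarray) -> "ConfoundSet":
        idx = np.asarray(indices, dtype=int)
        return ConfoundSet(
            motion=self.motion[idx],
            white_matter=self.white_matter[idx],
            csf=self.csf[idx],
            global_signal=self.global_signal[idx],
        )

    def design_matrix(self, use_gsr: bool) -> np.ndarray:
        """Nuisance regressor matrix (no intercept): motion, WM, CSF [, global]."""
        cols = [self.motion, self.white_matter[:, None], self.csf[:, None]]
        if use_gsr:
            cols.append(self.global_signal[:, None])
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.motion, columns=list(MOTION_COLUMNS))
        frame["white_matter"] = self.white_matter
        frame["csf"] = self.csf
        frame["global_signal"] = self.global_signal
        return frame

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfoundSet":
        frame = pd.read_csv(path, sep="\t")
        missing = set(CONFOUND_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"confounds table {path} lacks columns {sorted(missing)}")
        return cls(
            motion=frame[list(MOTION_COLUMNS)].to_numpy(),
            white_matter=frame["white_matter"].to_numpy(),
            csf=frame["csf"].to_numpy(),
            global_signal=frame["global_signal"].to_numpy(),
        )
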