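"""Seed-based functional connectivity.

The processing order is fixed: nuisance regression (six motion
parameters, white matter, ventricular signal, optionally the global
mean), then zero-phase band-pass filtering (0.009-0.08 Hz), then
seed-cube correlation and Fisher z-transform. For concatenated
(baseline-block) inputs the filter runs on the concatenated series, not
per segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .bold import BoldRun, ConfoundSet
from .extraction import ExtractionResult, ols_residuals
from .filters import MIN_VOLUMES, bandpass_timeseries

__all__ = [
    "Z_CLIP",
    "ConnectivityMap",
    "nuisance_regress",
    "bandpass",
    "seed_timecourse",
    "correlation_zmap",
    "run_connectivity",
    "PAPER_SEEDS_MM",
]

#: correlations are clipped to +/-(1 - Z_CLIP) before atanh so that the
#: seed's own voxels stay finite in the map
Z_CLIP = 1e-7

#: seed coordinates (mm, MNI) of the five reference resting-state networks
PAPER_SEEDS_MM = {
    "default_mode": (4.0, -52.0, 29.0),
    "cuneus": (-24.0, -80.0, 18.0),
    "thalamus": (-12.0, -19.0, 8.0),
    "sensorimotor": (0.0, -12.0, 50.0),
    "auditory": (-60.0, -4.0, 2.0),
}


@dataclass(frozen=True)
class ConnectivityMap:
    """Voxelwise Fisher-z seed-correlation map for one run and one seed."""

    z_values: np.ndarray
    mask: np.ndarray
    seed_center: tuple[int, int, int]
    seed_edge: int = 3
    method: str = ""
    network: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if z.shape != mask.shape:
            raise ValueError("z map and mask shapes differ")
        if not np.all(np.isfinite(z[mask])):
            raise ValueError("non-finite z values inside the mask")
        object.__setattr__(self, "z_values", z)
        object.__setattr__(self, "mask", mask)

    def masked(self) -> np.ndarray:
        """z values flattened over the mask (the comparison domain)."""
        return self.z_values[self.mask]

    def save(self, path: str | Path, affine: np.ndarray | None = None) -> None:
        img = nib.Nifti1Image(
            self.z_values.astype(np.float32),
            np.eye(4) if affine is None else affine,
        )
        nib.save(img, str(path))
        sidecar = {
            "seed_center": list(self.seed_center),
            "seed_edge": self.seed_edge,
            "method": self.method,
            "network": self.network,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def nuisance_regress(
    run: BoldRun, confounds: ConfoundSet, use_gsr: bool = True
) -> BoldRun:
    """Remove motion, white-matter, ventricular (and optionally global)
    signal from every voxel by least squares."""
    if confounds.n_volumes != run.n_volumes:
        raise ValueError(
            f"confounds length {confounds.n_volumes} does not match run "
            f"length {run.n_volumes}"
        )
    residuals = ols_residuals(run.timeseries(), confounds.design_matrix(use_gsr))
    return run.with_timeseries(residuals)


def bandpass(run: BoldRun, low: float = 0.009, high: float = 0.08) -> BoldRun:
    """Zero-phase band-pass per voxel; removes DC along with out-of-band power."""
    filtered = bandpass_timeseries(run.timeseries(), run.tr, low, high)
    return run.with_timeseries(filtered)


def seed_timecourse(
    run: BoldRun, center: tuple[int, int, int], edge: int = 3
) -> np.ndarray:
    """Mean series over the edge^3 voxel cube centred on ``center``."""
    if edge < 1 or edge % 2 == 0:
        raise ValueError("seed cube edge must be a positive odd voxel count")
    half = edge // 2
    lo = np.asarray(center, dtype=int) - half
    hi = lo + edge
    shape = np.asarray(run.mask.shape)
    if np.any(lo < 0) or np.any(hi > shape):
        raise ValueError(
            f"seed cube (edge {edge}) around voxel {tuple(center)} exceeds "
            f"volume bounds {tuple(shape)}"
        )
    cube = run.data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2], :]
    return cube.reshape(-1, run.n_volumes).mean(axis=0)


def correlation_zmap(
    run: BoldRun,
    seed_ts: np.ndarray,
    seed_center: tuple[int, int, int] = (0, 0, 0),
    seed_edge: int = 3,
    method: str = "",
    network: str = "",
) -> ConnectivityMap:
    """Pearson correlation of every voxel with the seed, Fisher z-transformed.

    Correlations are clipped to ``+/-(1 - Z_CLIP)`` so ``atanh`` stays
    finite at the seed itself.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if run.n_volumes < 3:
        raise ValueError("correlation map needs at least 3 volumes")
    if seed_ts.shape != (run.n_volumes,):
        raise ValueError("seed series length does not match the run")
    if np.ptp(seed_ts) == 0:
        raise ValueError("seed series is constant; correlation undefined")
    series = run.timeseries()
    centred = series - series.mean(axis=0)
    seed_c = seed_ts - seed_ts.mean()
    denom = np.sqrt((centred**2).sum(axis=0)) * np.sqrt((seed_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centred.T @ seed_c) / denom
    r = np.nan_to_num(r, nan=0.0)  # constant voxels carry no signal
    z = np.arctanh(np.clip(r, -(1 - Z_CLIP), 1 - Z_CLIP))
    z_vol = np.zeros(run.mask.shape)
    z_vol[run.mask] = z
    return ConnectivityMap(
        z_values=z_vol,
        mask=run.mask,
        seed_center=tuple(int(c) for c in seed_center),
        seed_edge=seed_edge,
        method=method,
        network=network,
    )


def run_connectivity(
    extraction: ExtractionResult,
    seeds: dict[str, tuple[int, int, int]],
    use_gsr: bool = True,
    band: tuple[float, float] = (0.009, 0.08),
    seed_edge: int = 3,
) -> dict[str, ConnectivityMap]:
    """Full connectivity stage for one extracted run: regress, filter, map.

    Returns one Fisher-z map per named seed/network.
    """
    if extraction.run.n_volumes < MIN_VOLUMES:
        raise ValueError(
            f"extracted run too short for filtering "
            f"({extraction.run.n_volumes} < {MIN_VOLUMES} volumes)"
        )
    cleaned = nuisance_regress(extraction.run, extraction.confounds, use_gsr)
    filtered = bandpass(cleaned, *band)
    maps = {}
    for network, center in seeds.items():
        ts = seed_timecourse(filtered, center, seed_edge)
        maps[network] = correlation_zmap(
            filtered,
            ts,
            seed_center=center,
            seed_edge=seed_edge,
            method=extraction.method,
            network=network,
        )
    return maps
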