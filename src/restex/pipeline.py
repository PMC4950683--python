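"""End-to-end experiment orchestration.

``run_experiment`` simulates a study group, estimates each subject's
hemodynamic delay, applies every requested extraction method to every
task design, computes seed connectivity, scores each method's maps
against the duration-matched continuous rest run, and adds the
test-retest ceiling (two independently simulated rest runs). Methods
that retain too little data for a design are skipped with a logged
reason rather than failing the experiment — the fixed-cut concatenation
on the short finger-tapping paradigm is the canonical case.

Everything is a deterministic function of the configuration (including
its master seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bold import BoldRun
from .connectivity import run_connectivity
from .delay import ShiftEstimate, estimate_shift, roi_mean_timecourse
from .design import TaskDesign, boxcar, edt_design, rft_design
from .extraction import (
    METHODS,
    ExtractionResult,
    InsufficientDataError,
    apply_method,
)
from .similarity import compare_maps, group_compare, match_duration
from .synthesize import ACTIVATED_NETWORK, GroupData, generate_group

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "write_tables"]

logger = logging.getLogger("restex")

TESTRETEST = "TESTRETEST"
DESIGN_TEMPLATES = {"EDT": edt_design, "RFT": rft_design}


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one synthetic experiment."""

    n_subjects: int = 8
    designs: tuple[str, ...] = ("EDT", "RFT")
    methods: tuple[str, ...] = METHODS
    gsr: str = "on"  # "on" | "off" | "both"
    seed: int = 0
    tr: float = 1.4
    band: tuple[float, float] = (0.009, 0.08)
    dice_threshold: float = 0.3
    icc_form: str = "agreement"
    min_retained_s: float = 30.0
    rest_duration_s: float = 360.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = [m for m in self.methods if m.upper() not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {METHODS}")
        unknown = [d for d in self.designs if d.upper() not in DESIGN_TEMPLATES]
        if unknown:
            raise ValueError(
                f"unknown designs {unknown}; choose from {tuple(DESIGN_TEMPLATES)}"
            )
        if self.gsr not in ("on", "off", "both"):
            raise ValueError("gsr must be 'on', 'off' or 'both'")
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")
        object.__setattr__(self, "methods", tuple(m.upper() for m in self.methods))
        object.__setattr__(self, "designs", tuple(d.upper() for d in self.designs))

    @classmethod
    def from_dict(cls, obj: dict) -> "ExperimentConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(obj) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        obj = dict(obj)
        for key in ("designs", "methods", "band"):
            if key in obj and isinstance(obj[key], list):
                obj[key] = tuple(obj[key])
        return cls(**obj)

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @property
    def gsr_flags(self) -> tuple[bool, ...]:
        return {"on": (True,), "off": (False,), "both": (True, False)}[self.gsr]


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    records: pd.DataFrame
    stats: pd.DataFrame
    manifest: dict
    group: GroupData | None = None
    skipped: list[dict] = field(default_factory=list)


def _task_boxcar(design: TaskDesign) -> np.ndarray:
    """Task-versus-baseline indicator: union of all task-condition boxcars."""
    values = np.zeros(design.n_volumes)
    for label in design.task_labels:
        values = np.maximum(values, boxcar(design, label).values)
    return values


def _estimate_subject_shift(
    run: BoldRun, design: TaskDesign, roi_mask: np.ndarray
) -> ShiftEstimate:
    roi_ts = roi_mean_timecourse(run, roi_mask)
    return estimate_shift(roi_ts, _task_boxcar(design), design.tr)


def run_experiment(
    config: ExperimentConfig, group: GroupData | None = None
) -> ExperimentResult:
    """Run the full comparison; see the module docstring for the stages.

    A pre-generated ``group`` may be supplied (e.g. to share one
    simulation across analyses); by default the group implied by the
    configuration is simulated.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if group is None:
        designs = {name: DESIGN_TEMPLATES[name](config.tr) for name in config.designs}
        group = generate_group(
            n_subjects=config.n_subjects,
            designs=designs,
            seed=config.seed,
            rest_duration_s=config.rest_duration_s,
            tr=config.tr,
        )
    truth = group.truth
    timings["simulate"] = time.perf_counter() - t0

    networks = [n for n in sorted(truth.network_masks) if n != ACTIVATED_NETWORK]
    seeds = {n: truth.seed_voxel(n) for n in networks}
    roi_mask = truth.network_masks[ACTIVATED_NETWORK]

    t0 = time.perf_counter()
    shifts: dict[tuple[str, str], ShiftEstimate] = {}
    for sub in group.subjects:
        for design_name in config.designs:
            run, _ = sub.runs[design_name]
            shifts[(sub.subject_id, design_name)] = _estimate_subject_shift(
                run, group.designs[design_name], roi_mask
            )
    timings["estimate_shift"] = time.perf_counter() - t0

    records: list[dict] = []
    skipped: list[dict] = []
    t0 = time.perf_counter()
    for use_gsr in config.gsr_flags:
        for sub in group.subjects:
            rest_run, rest_conf = sub.runs["rest"]
            rest_maps_cache: dict[int, dict] = {}

            def rest_maps(n_volumes: int):
                if n_volumes not in rest_maps_cache:
                    trimmed, conf = match_duration(rest_run, n_volumes, rest_conf)
                    reference = ExtractionResult(
                        run=trimmed,
                        confounds=conf,
                        method="REST",
                        retained_seconds=trimmed.duration,
                    )
                    rest_maps_cache[n_volumes] = run_connectivity(
                        reference, seeds, use_gsr, config.band
                    )
                return rest_maps_cache[n_volumes]

            # test-retest ceiling: an independent rest run against the first
            retest_run, retest_conf = sub.runs["retest"]
            retest_ex = ExtractionResult(
                run=retest_run,
                confounds=retest_conf,
                method=TESTRETEST,
                retained_seconds=retest_run.duration,
            )
            retest_maps = run_connectivity(retest_ex, seeds, use_gsr, config.band)
            for network in networks:
                rec = compare_maps(
                    retest_maps[network],
                    rest_maps(retest_run.n_volumes)[network],
                    subject=sub.subject_id,
                    method=TESTRETEST,
                    network=network,
                    gsr=use_gsr,
                    dice_threshold=config.dice_threshold,
                    icc_form=config.icc_form,
                ).as_dict()
                rec["design"] = "REST"
                records.append(rec)

            for design_name in config.designs:
                design = group.designs[design_name]
                run, conf = sub.runs[design_name]
                shift = shifts[(sub.subject_id, design_name)]
                for method in config.methods:
                    try:
                        extraction = apply_method(
                            method,
                            run,
                            conf,
                            design=design,
                            shift=shift,
                            min_retained_s=config.min_retained_s,
                        )
                    except InsufficientDataError as err:
                        logger.warning(
                            "skipping %s on %s for %s: insufficient data (%s)",
                            method,
                            design_name,
                            sub.subject_id,
                            err,
                        )
                        skipped.append(
                            {
                                "method": method,
                                "design": design_name,
                                "subject": sub.subject_id,
                                "reason": f"insufficient data: {err}",
                            }
                        )
                        continue
                    maps = run_connectivity(extraction, seeds, use_gsr, config.band)
                    reference = rest_maps(extraction.run.n_volumes)
                    for network in networks:
                        rec = compare_maps(
                            maps[network],
                            reference[network],
                            subject=sub.subject_id,
                            method=method,
                            network=network,
                            gsr=use_gsr,
                            dice_threshold=config.dice_threshold,
                            icc_form=config.icc_form,
                        ).as_dict()
                        rec["design"] = design_name
                        records.append(rec)
    timings["extract_and_connect"] = time.perf_counter() - t0

    records_df = pd.DataFrame(records)
    t0 = time.perf_counter()
    stats_frames = []
    for use_gsr in config.gsr_flags:
        for design_name in config.designs:
            subset = records_df[
                (records_df["gsr"] == use_gsr)
                & (records_df["design"].isin([design_name, "REST"]))
            ]
            if subset.empty:
                continue
            stats = group_compare(subset, reference=TESTRETEST)
            stats.insert(0, "design", design_name)
            stats.insert(1, "gsr", use_gsr)
            stats_frames.append(stats)
    stats_df = (
        pd.concat(stats_frames, ignore_index=True) if stats_frames else pd.DataFrame()
    )
    timings["statistics"] = time.perf_counter() - t0

    manifest = {
        "restex_version": __version__,
        "config": config.as_dict(),
        "config_hash": config.digest(),
        "stage_runtimes_s": {k: round(v, 3) for k, v in timings.items()},
        "skipped": skipped,
        "group": group.manifest(),
        "shift_estimates_trs": {
            f"{sub}:{design}": est.shift_trs for (sub, design), est in shifts.items()
        },
    }
    result = ExperimentResult(
        config=config,
        records=records_df,
        stats=stats_df,
        manifest=manifest,
        group=group,
        skipped=skipped,
    )
    if config.out_dir is not None:
        _write_outputs(result, Path(config.out_dir))
    return result


def write_tables(records: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    """Wide per-metric summary tables: rows = methods (+ test-retest),
    columns = networks, cells = group means; one CSV per metric, design
    and GSR condition. Missing cells are rendered as NA."""
    if records.empty:
        raise ValueError("no similarity records to tabulate")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for metric in ("icc", "r2", "dice"):
        for (design, gsr), subset in records.groupby(["design", "gsr"], sort=True):
            if design == "REST":
                continue
            block = records[
                (records["gsr"] == gsr) & (records["design"].isin([design, "REST"]))
            ]
            wide = block.pivot_table(
                index="method",
                columns="network",
                values=metric,
                aggfunc="mean",
                dropna=False,
            )
            order = [m for m in list(METHODS) + [TESTRETEST] if m in wide.index]
            wide = wide.loc[order]
            gsr_tag = "gsr-on" if gsr else "gsr-off"
            path = out / f"table_{metric}_{design}_{gsr_tag}.csv"
            wide.to_csv(path, na_rep="NA")
            written.append(path)
    return written


def _write_outputs(result: ExperimentResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "similarity_records.csv", index=False)
    if not result.stats.empty:
        result.stats.to_csv(out / "statistics.csv", index=False)
    write_tables(result.records, out / "tables")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    log_lines = [
        f"restex {__version__} config={result.config.digest()}",
    ]
    for entry in result.skipped:
        log_lines.append(
            "SKIP {method} on {design} ({subject}): {reason}".format(**entry)
        )
    (out / "experiment.log").write_text("\n".join(log_lines) + "\n")
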