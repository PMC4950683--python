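"""Agreement between connectivity maps and group-level comparison.

Three voxelwise similarity metrics against the duration-matched rest
reference:

* **ICC** — intraclass correlation across voxels, two-way
  absolute-agreement single-measures (voxels are targets, the two maps
  are the raters). Sensitive to mean offsets between maps, unlike R².
* **Dice** — overlap of the suprathreshold (z >= 0.3) voxel sets.
* **R²** — squared Pearson correlation across voxels; affine-invariant.

``group_compare`` Fisher-transforms the correlation-type metrics, runs a
one-way repeated-measures ANOVA on the method factor and Welch t-tests
of each method against the test-retest reference, reporting two-sided
uncorrected p-values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .bold import BoldRun, ConfoundSet
from .connectivity import ConnectivityMap

__all__ = [
    "SimilarityRecord",
    "icc_maps",
    "dice_maps",
    "map_correlation",
    "r2_maps",
    "match_duration",
    "compare_maps",
    "group_compare",
]

DICE_THRESHOLD = 0.3


@dataclass(frozen=True)
class SimilarityRecord:
    """One subject x method x network row of the similarity table."""

    subject: str
    method: str
    network: str
    icc: float
    dice: float
    r: float
    r2: float
    gsr: bool
    n_voxels: int
    dice_empty: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def _paired(map_a: ConnectivityMap, map_b: ConnectivityMap) -> tuple[np.ndarray, np.ndarray]:
    if map_a.mask.shape != map_b.mask.shape or not np.array_equal(
        map_a.mask, map_b.mask
    ):
        raise ValueError("maps must share an identical voxel mask")
    return map_a.masked(), map_b.masked()


def icc_maps(
    map_a: ConnectivityMap, map_b: ConnectivityMap, form: str = "agreement"
) -> float:
    """Intraclass correlation across voxels between two maps.

    Two-way ANOVA with voxels as rows (random targets) and the two maps
    as columns (k = 2 raters). ``form="agreement"`` (default) is the
    absolute-agreement single-measures coefficient
    ``(MSR - MSE) / (MSR + MSE + (k/n)(MSC - MSE))``; ``"consistency"``
    drops the between-map variance term and is offset-invariant.
    """
    if form not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    x, y = _paired(map_a, map_b)
    n = x.size
    if n <= 2:
        raise ValueError("ICC needs more than 2 voxels")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("both maps are constant across voxels; ICC undefined")
    table = np.column_stack([x, y])
    k = 2
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    else:
        denom = msr + (k - 1) * mse
    if denom == 0:
        raise ValueError("zero denominator; ICC undefined")
    return float((msr - mse) / denom)


def dice_maps(
    map_a: ConnectivityMap, map_b: ConnectivityMap, threshold: float = DICE_THRESHOLD
) -> float:
    """Dice overlap of the suprathreshold voxel sets (z >= threshold).

    Returns 0 when both sets are empty; callers that need to flag that
    degenerate case should check set sizes (see :func:`compare_maps`).
    """
    x, y = _paired(map_a, map_b)
    a = x >= threshold
    b = y >= threshold
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return float(2.0 * np.sum(a & b) / total)


def map_correlation(map_a: ConnectivityMap, map_b: ConnectivityMap) -> float:
    """Signed Pearson correlation between two maps across masked voxels."""
    x, y = _paired(map_a, map_b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant map; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def r2_maps(map_a: ConnectivityMap, map_b: ConnectivityMap) -> float:
    """Squared Pearson correlation across voxels (affine-invariant)."""
    return map_correlation(map_a, map_b) ** 2


def match_duration(
    rest_run: BoldRun,
    target_volumes: int,
    confounds: ConfoundSet | None = None,
):
    """Trim a continuous rest run to the duration left after task removal.

    Keeps the first ``target_volumes`` volumes (and, when given, the
    matching confound rows). Returns the run, or a (run, confounds) pair.
    """
    if target_volumes <= 0:
        raise ValueError("target_volumes must be > 0")
    if rest_run.n_volumes < target_volumes:
        raise ValueError(
            f"rest run ({rest_run.n_volumes} volumes) shorter than the "
            f"requested {target_volumes}"
        )
    idx = np.arange(target_volumes)
    trimmed = rest_run.select_volumes(idx)
    if confounds is None:
        return trimmed
    return trimmed, confounds.select_volumes(idx)


def compare_maps(
    map_a: ConnectivityMap,
    map_b: ConnectivityMap,
    subject: str,
    method: str,
    network: str,
    gsr: bool,
    dice_threshold: float = DICE_THRESHOLD,
    icc_form: str = "agreement",
) -> SimilarityRecord:
    """All three metrics for one map pair, as a similarity-table row."""
    x, y = _paired(map_a, map_b)
    r = map_correlation(map_a, map_b)
    both_empty = not (np.any(x >= dice_threshold) or np.any(y >= dice_threshold))
    return SimilarityRecord(
        subject=subject,
        method=method,
        network=network,
        icc=icc_maps(map_a, map_b, icc_form),
        dice=dice_maps(map_a, map_b, dice_threshold),
        r=r,
        r2=r * r,
        gsr=gsr,
        n_voxels=int(x.size),
        dice_empty=both_empty,
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------


def _transformed(frame: pd.DataFrame, metric: str) -> pd.Series:
    """Variance-stabilising transform: atanh for correlation-type metrics.

    ICC is transformed directly; R² through its signed correlation so
    the sign survives; Dice is left on its native scale.
    """
    if metric == "icc":
        return np.arctanh(frame["icc"].clip(-0.999999, 0.999999))
    if metric == "r2":
        return np.arctanh(frame["r"].clip(-0.999999, 0.999999))
    if metric == "dice":
        return frame["dice"].astype(float)
    raise ValueError(f"unknown metric {metric!r}")


def group_compare(
    records: pd.DataFrame,
    reference: str = "TESTRETEST",
    metrics: tuple[str, ...] = ("icc", "r2", "dice"),
) -> pd.DataFrame:
    """Method-factor statistics per metric and network.

    ``records`` is the long similarity table (columns subject, method,
    network, icc, dice, r, r2, ...) including the test-retest condition
    as one more "method". Per metric x network this computes a one-way
    repeated-measures ANOVA across methods and Welch two-sample t-tests
    of every method against ``reference``; p-values are two-sided and
    uncorrected.
    """
    if records["subject"].nunique() < 2:
        raise ValueError("group statistics need at least 2 subjects")
    rows = []
    for metric in metrics:
        for network, net_df in records.groupby("network", sort=True):
            df = net_df.copy()
            df["value"] = _transformed(df, metric)
            means = df.groupby("method")["value"].mean()
            if np.ptp(means.to_numpy()) < 1e-12:
                f_stat, f_p = 0.0, 1.0
            else:
                balanced = df.groupby("method").filter(
                    lambda g: g["subject"].nunique() == df["subject"].nunique()
                )
                res = AnovaRM(
                    balanced, depvar="value", subject="subject", within=["method"]
                ).fit()
                f_stat = float(res.anova_table.loc["method", "F Value"])
                f_p = float(res.anova_table.loc["method", "Pr > F"])
            rows.append(
                {
                    "metric": metric,
                    "network": network,
                    "contrast": "anova:method",
                    "statistic": f_stat,
                    "p_value": f_p,
                    "n_subjects": int(df["subject"].nunique()),
                }
            )
            if reference in set(df["method"]):
                ref_values = df.loc[df["method"] == reference, "value"].to_numpy()
                for method, method_df in df.groupby("method", sort=True):
                    if method == reference:
                        continue
                    vals = method_df["value"].to_numpy()
                    degenerate = np.ptp(vals) < 1e-12 and np.ptp(ref_values) < 1e-12
                    if degenerate and abs(vals.mean() - ref_values.mean()) < 1e-12:
                        t_stat, t_p = 0.0, 1.0
                    elif degenerate:
                        t_stat = np.inf * np.sign(vals.mean() - ref_values.mean())
                        t_p = 0.0
                    else:
                        t_stat, t_p = stats.ttest_ind(
                            vals, ref_values, equal_var=False
                        )
                    rows.append(
                        {
                            "metric": metric,
                            "network": network,
                            "contrast": f"{method} vs {reference}",
                            "statistic": float(t_stat),
                            "p_value": float(t_p),
                            "n_subjects": int(method_df["subject"].nunique()),
                        }
                    )
    return pd.DataFrame(rows)
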