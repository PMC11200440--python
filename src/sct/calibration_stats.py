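"""Statistics over single-cell transfer and capture trial tables.

Two table kinds circulate in the pipeline, both carried as pandas
DataFrames and exchanged as CSV with fixed headers:

* **transfer** tables, ``trial_id,target,captured,released`` — one row per
  picking run of ``target`` cells, of which ``captured`` adhered to the tip
  and ``released`` made it into the destination medium;
* **capture** tables, ``trial_id,spiked,device_captured`` — one row per
  spiked blood sample of ``spiked`` cells, of which ``device_captured`` were
  recovered by the microfluidic device.  An optional ``target`` column (the
  nominal spike count the run aimed for) is preserved when present and used
  to group replicates.

Transfer efficiency is ``100 * released / target`` (percent).  The
calibration regression (device-captured against spiked) is ordinary least
squares computed from the closed-form normal equations, with the coefficient
of determination ``R^2 = 1 - SS_res/SS_tot``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import RankDeficiencyError, TrialError

__all__ = [
    "TRANSFER_COLUMNS",
    "CAPTURE_COLUMNS",
    "EfficiencySummary",
    "RegressionResult",
    "transfer_efficiency",
    "validate_transfer_table",
    "validate_capture_table",
    "read_trial_table",
    "write_trial_table",
    "summarize_efficiency",
    "fit_line",
    "calibration_curve",
]

TRANSFER_COLUMNS = ("trial_id", "target", "captured", "released")
CAPTURE_COLUMNS = ("trial_id", "spiked", "device_captured")


@dataclass(frozen=True)
class EfficiencySummary:
    """Per-target-count transfer-efficiency summary (percent)."""

    target: int
    n: int
    mean: float
    sd: Optional[float]  #: sample SD (n-1); None for a single replicate
    range_low: float
    range_high: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def transfer_efficiency(released: int, target: int) -> float:
    """Percent of targeted cells delivered: ``100 * released / target``."""
    if target <= 0:
        raise TrialError("target count must be positive")
    if not 0 <= released <= target:
        raise TrialError("released must lie in [0, target]")
    return 100.0 * released / target


def validate_transfer_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a transfer table against its count invariants
    (0 <= released <= captured <= target, target > 0)."""
    missing = set(TRANSFER_COLUMNS) - set(df.columns)
    if missing:
        raise TrialError(f"transfer table missing columns {sorted(missing)}")
    if (df["target"] <= 0).any():
        raise TrialError("target counts must be positive")
    bad = ~((0 <= df["released"]) & (df["released"] <= df["captured"])
            & (df["captured"] <= df["target"]))
    if bad.any():
        raise TrialError(
            f"rows violate 0 <= released <= captured <= target: "
            f"{df.index[bad].tolist()}")
    return df


def validate_capture_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a capture table (0 <= device_captured <= spiked)."""
    missing = set(CAPTURE_COLUMNS) - set(df.columns)
    if missing:
        raise TrialError(f"capture table missing columns {sorted(missing)}")
    if (df["spiked"] < 0).any():
        raise TrialError("spiked counts must be non-negative")
    bad = ~((0 <= df["device_captured"])
            & (df["device_captured"] <= df["spiked"]))
    if bad.any():
        raise TrialError(
            f"rows violate 0 <= device_captured <= spiked: "
            f"{df.index[bad].tolist()}")
    return df


def read_trial_table(path) -> pd.DataFrame:
    """Read a trial CSV, infer its kind from the header, validate it."""
    df = pd.read_csv(path)
    if set(TRANSFER_COLUMNS).issubset(df.columns):
        return validate_transfer_table(df)
    if set(CAPTURE_COLUMNS).issubset(df.columns):
        return validate_capture_table(df)
    raise TrialError(
        f"unrecognized trial table header {list(df.columns)}; expected "
        f"{list(TRANSFER_COLUMNS)} or {list(CAPTURE_COLUMNS)}")


def write_trial_table(df: pd.DataFrame, path) -> None:
    """Write a trial table with the canonical column order (extra columns
    such as a capture table's nominal ``target`` are dropped)."""
    for cols in (TRANSFER_COLUMNS, CAPTURE_COLUMNS):
        if set(cols).issubset(df.columns):
            df.loc[:, list(cols)].to_csv(path, index=False)
            return
    raise TrialError(f"unrecognized trial table columns {list(df.columns)}")


def summarize_efficiency(df: pd.DataFrame) -> list[EfficiencySummary]:
    """Per-target-count mean / sample-SD / range of transfer efficiency.

    SD uses the n-1 divisor and is reported as ``None`` (absent, not zero)
    when a count has a single replicate.
    """
    validate_transfer_table(df)
    out = []
    eff = 100.0 * df["released"] / df["target"]
    for target, idx in df.groupby("target").groups.items():
        vals = eff.loc[idx].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out.append(EfficiencySummary(
            target=int(target), n=len(vals), mean=float(vals.mean()),
            sd=sd, range_low=float(vals.min()), range_high=float(vals.max())))
    return out


def fit_line(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares through the closed-form normal equations.

    slope = S_xy / S_xx, intercept = ybar - slope * xbar,
    R^2 = 1 - SS_res / SS_tot.  Requires at least three points and
    non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise RankDeficiencyError("x and y must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise RankDeficiencyError("at least three points required")
    xbar, ybar = x.mean(), y.mean()
    s_xx = float(((x - xbar) ** 2).sum())
    if s_xx == 0.0 or not math.isfinite(s_xx):
        raise RankDeficiencyError("degenerate abscissae: all x equal")
    s_xy = float(((x - xbar) * (y - ybar)).sum())
    slope = s_xy / s_xx
    intercept = ybar - slope * xbar
    ss_res = float(((y - intercept - slope * x) ** 2).sum())
    ss_tot = float(((y - ybar) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RegressionResult(slope=slope, intercept=intercept,
                            r_squared=r2, n=n)


def calibration_curve(df: pd.DataFrame,
                      on: str = "means") -> RegressionResult:
    """Fit the spike-in calibration line (device-captured vs spiked).

    Parameters
    ----------
    on : {"means", "rows"}
        ``"means"`` (default) regresses the per-group replicate means — the
        convention of a calibration plot showing mean +/- SD per nominal
        spike count; groups are the ``target`` column when present, else
        distinct spiked values.  ``"rows"`` regresses every trial row.
    """
    validate_capture_table(df)
    if on == "rows":
        return fit_line(df["spiked"], df["device_captured"])
    if on != "means":
        raise ValueError("on must be 'means' or 'rows'")
    key = "target" if "target" in df.columns else "spiked"
    g = df.groupby(key)[["spiked", "device_captured"]].mean()
    return fit_line(g["spiked"], g["device_captured"])
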