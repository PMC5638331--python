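"""Percent variability error (PVE), error bounds, and interval comparison.

PVE quantifies scan-rescan measurement variability for one pipeline step
and one ROI. With T_ik the TBV-corrected measurement of participant i on
scan k (k = 1..n, scan 1 the reference), the statistic is

    PVE = 100 * (1/N) * sum_i sum_{k=2}^{n} 2|T_i1 - T_ik|
                                     / ((T_i1 + T_ik) * (n - 1))

i.e. the mean, over participants and rescans, of the absolute scan-rescan
difference normalized by the pair mean — a symmetric percent difference.
For small multiplicative log-normal noise of sd sigma per scan this
statistic concentrates around 100 * 2*sigma/sqrt(pi) (half-normal mean).

The PVE converts a point estimate into an error band: a corrected volume X
with a PVE of p percent should be read as X ± (p/100)·X when comparing
groups, pipelines or time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "pve",
    "pve_table",
    "IntervalEstimate",
    "pve_bounds",
    "interval_to_volume",
    "intervals_overlap",
    "worked_example",
]


def pve(values, reference: int = 1) -> float:
    """Percent variability error of per-participant repeated measurements.

    Parameters
    ----------
    values
        Array of shape (participants, scans); all entries strictly positive,
        every participant with the same scan count n >= 2.
    reference
        1-based index of the reference scan (default: the first scan).

    Returns
    -------
    float
        PVE in percent.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(
            "values must be a (participants x scans) matrix; ragged scan counts are not allowed"
        )
    n_participants, n_scans = arr.shape
    if n_participants < 1:
        raise ValueError("at least one participant is required")
    if n_scans < 2:
        raise ValueError(f"at least 2 scans per participant are required, got {n_scans}")
    if not np.all(arr > 0):
        raise ValueError("all measurements must be strictly positive")
    if not 1 <= reference <= n_scans:
        raise ValueError(f"reference scan {reference} outside 1..{n_scans}")
    ref = arr[:, reference - 1]
    others = np.delete(arr, reference - 1, axis=1)
    terms = 2.0 * np.abs(ref[:, None] - others) / (ref[:, None] + others)
    per_participant = terms.sum(axis=1) / (n_scans - 1)
    return float(100.0 * per_participant.mean())


def pve_table(
    ratios: pd.DataFrame,
    reference_scan: int = 1,
    run_index: int = 1,
) -> pd.DataFrame:
    """PVE per (step, ROI) cell from a long-format ratio table.

    Uses a single pipeline run (default run 1; repeated runs of a
    deterministic pipeline carry no extra scan-level information) and the
    TBV-corrected ratios, so the returned values are percentages of the
    regional fraction of total brain volume.

    Returns a DataFrame with columns ``step, roi, pve_percent,
    n_participants, n_scans`` preserving the order of appearance of steps
    and ROIs in the input.
    """
    required = {"participant_id", "scan_index", "run_index", "step", "roi", "ratio"}
    missing = required - set(ratios.columns)
    if missing:
        raise ValueError(f"ratio table missing columns: {sorted(missing)}")
    sub = ratios[ratios["run_index"] == run_index]
    if sub.empty:
        raise ValueError(f"no records with run_index == {run_index}")
    steps = list(dict.fromkeys(ratios["step"]))
    rois = list(dict.fromkeys(ratios["roi"]))
    rows = []
    for step in steps:
        for roi in rois:
            cell = sub[(sub["step"] == step) & (sub["roi"] == roi)]
            wide = cell.pivot(index="participant_id", columns="scan_index", values="ratio")
            if wide.isna().any().any():
                raise ValueError(f"incomplete scans for cell ({step}, {roi})")
            wide = wide.sort_index(axis=1)
            rows.append(
                {
                    "step": step,
                    "roi": roi,
                    "pve_percent": pve(wide.to_numpy(), reference=reference_scan),
                    "n_participants": wide.shape[0],
                    "n_scans": wide.shape[1],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class IntervalEstimate:
    """Symmetric multiplicative error band around a ratio point estimate."""

    center: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.center <= self.upper:
            raise ValueError(
                f"interval must satisfy lower <= center <= upper, got "
                f"({self.lower}, {self.center}, {self.upper})"
            )


def pve_bounds(center: float, pve_percent: float) -> IntervalEstimate:
    """Error band center * (1 ± pve/100) around a TBV-corrected ratio.

    ``center`` is a fraction (e.g. 0.0022 for 0.22% of TBV); ``pve_percent``
    is the percent variability error for that (step, ROI) cell. A PVE of
    100% or more would produce a non-positive lower bound and is rejected.
    """
    if center <= 0:
        raise ValueError(f"center must be strictly positive, got {center}")
    if pve_percent < 0:
        raise ValueError(f"pve_percent must be >= 0, got {pve_percent}")
    if pve_percent >= 100:
        raise ValueError(f"pve_percent >= 100 gives a degenerate bound, got {pve_percent}")
    frac = pve_percent / 100.0
    return IntervalEstimate(center=center, lower=center * (1 - frac), upper=center * (1 + frac))


def interval_to_volume(interval: IntervalEstimate, tbv: float) -> tuple[float, float, float]:
    """Convert a ratio interval to physical volume bounds at a given TBV.

    Returns ``(lower_mm3, upper_mm3, range_mm3)`` with range = upper − lower.
    """
    if tbv <= 0:
        raise ValueError(f"tbv must be strictly positive, got {tbv}")
    lower = interval.lower * tbv
    upper = interval.upper * tbv
    return lower, upper, upper - lower


def intervals_overlap(a: IntervalEstimate, b: IntervalEstimate) -> bool:
    """True iff the closed intervals [a.lower, a.upper] and [b.lower, b.upper] intersect.

    Touching endpoints count as overlap (closed-interval convention).
    """
    return a.lower <= b.upper and b.lower <= a.upper


def worked_example(
    center: float,
    pve_percent: float,
    tbv: float,
    percent_decimals: int = 3,
) -> dict:
    """End-to-end error-band example for one (step, ROI) cell.

    Applies the PVE band to a ratio, reports the band in percent rounded to
    the conventional reporting precision, and converts the rounded percent
    bounds to physical volumes at the given TBV. Returned dict keys:
    ``half_width_percent, lower_percent, upper_percent, lower_mm3,
    upper_mm3, range_mm3``.
    """
    interval = pve_bounds(center, pve_percent)
    half_width_percent = round((interval.upper - interval.center) * 100.0, percent_decimals)
    lower_percent = round(interval.lower * 100.0, percent_decimals)
    upper_percent = round(interval.upper * 100.0, percent_decimals)
    # Round center through the same reporting precision so the rounded
    # bounds always bracket it (rounding is monotone).
    reported = IntervalEstimate(
        center=round(center * 100.0, percent_decimals) / 100.0,
        lower=lower_percent / 100.0,
        upper=upper_percent / 100.0,
    )
    lower_mm3, upper_mm3, range_mm3 = interval_to_volume(reported, tbv)
    return {
        "center_percent": round(center * 100.0, percent_decimals),
        "pve_percent": pve_percent,
        "half_width_percent": half_width_percent,
        "lower_percent": lower_percent,
        "upper_percent": upper_percent,
        "lower_mm3": lower_mm3,
        "upper_mm3": upper_mm3,
        "range_mm3": range_mm3,
        "tbv_mm3": tbv,
    }
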