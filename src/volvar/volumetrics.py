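"""Measurement data model, TBV ratio correction, and crossing validation.

The long-format measurement table keys every ROI volume by participant,
scan, pipeline run, pre-processing step and ROI, and carries the total
brain volume (TBV) produced by that record's own pipeline step. Analyses
run on the dimensionless ratio volume/TBV, which absorbs global confounds
such as head size, hydration and scanner warmth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ROIS, STEPS

__all__ = [
    "KEY_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "validate_measurements",
    "ratio_correct",
    "CrossingReport",
    "validate_crossing",
]

KEY_COLUMNS = ["participant_id", "scan_index", "run_index", "step", "roi"]
MEASUREMENT_COLUMNS = KEY_COLUMNS + ["volume_mm3", "tbv_mm3"]


def validate_measurements(table: pd.DataFrame) -> None:
    """Validate schema, closed label vocabularies and positivity.

    Step and ROI labels are closed vocabularies checked strictly: a typo'd
    label would silently corrupt the factorial structure, so unknown labels
    are errors, not warnings.
    """
    missing_cols = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"measurement table missing columns: {missing_cols}")
    bad_steps = set(table["step"].unique()) - set(STEPS)
    if bad_steps:
        raise ValueError(f"unknown step labels: {sorted(bad_steps)} (expected subset of {STEPS})")
    bad_rois = set(table["roi"].unique()) - set(ROIS)
    if bad_rois:
        raise ValueError(f"unknown ROI labels: {sorted(bad_rois)} (expected subset of {ROIS})")
    if (table["volume_mm3"] <= 0).any():
        raise ValueError("volume_mm3 must be strictly positive in every record")
    if (table["tbv_mm3"] <= 0).any():
        raise ValueError("tbv_mm3 must be strictly positive in every record")
    if (table["volume_mm3"] >= table["tbv_mm3"]).any():
        raise ValueError("every ROI volume must be smaller than its record's TBV")


def read_measurements(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={
            "participant_id": str,
            "scan_index": int,
            "run_index": int,
            "step": str,
            "roi": str,
            "volume_mm3": float,
            "tbv_mm3": float,
        },
    )
    validate_measurements(table)
    return table


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    validate_measurements(table)
    table.to_csv(path, index=False)


def ratio_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Convert each volume to a fraction of its own record's TBV.

    Each record is divided by the TBV extracted by the *same* pipeline step
    (FS volumes by the FS brain volume, registration-based volumes by the
    extraction-mask volume), so the correction is internally consistent per
    pipeline. Ratios are carried as fractions; multiply by 100 for percent
    only at reporting time.
    """
    validate_measurements(table)
    out = table[KEY_COLUMNS].copy()
    out["ratio"] = table["volume_mm3"].to_numpy() / table["tbv_mm3"].to_numpy()
    return out


@dataclass
class CrossingReport:
    """Completeness report over the participant × scan × run × step × ROI crossing."""

    missing: list[tuple] = field(default_factory=list)
    duplicates: list[tuple] = field(default_factory=list)

    @property
    def is_complete(self) -> bool:
        return not self.missing and not self.duplicates

    def summary(self) -> str:
        if self.is_complete:
            return "complete crossing: no missing cells, no duplicate keys"
        return f"{len(self.missing)} missing cell(s), {len(self.duplicates)} duplicate key(s)"


def validate_crossing(table: pd.DataFrame) -> CrossingReport:
    """Check that the table is a complete, duplicate-free factorial crossing.

    The expected crossing is the Cartesian product of the level sets
    observed in the table. Returns a report listing missing cells and
    duplicated keys; the report is empty iff the crossing is complete.
    """
    for col in KEY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"table missing key column {col!r}")
    keys = table[KEY_COLUMNS]
    counts = keys.value_counts()
    duplicates = [tuple(k) for k, c in counts.items() if c > 1]
    levels = [sorted(keys[c].unique()) for c in KEY_COLUMNS]
    expected = pd.MultiIndex.from_product(levels, names=KEY_COLUMNS)
    present = pd.MultiIndex.from_frame(keys)
    missing = [tuple(k) for k in expected.difference(present)]
    return CrossingReport(missing=sorted(missing), duplicates=sorted(duplicates))
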