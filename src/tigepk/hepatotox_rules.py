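"""Rule-based three-level liver-status classification.

Labels, in increasing severity (ULN = upper limit of normal, 40 U/L for
ALT; bilirubin ULN configurable, default 17.1 umol/L):

* ``NONE`` — no qualifying pattern.
* ``INJURY`` ("abnormal liver function") — ALT measured twice in a row in
  the interval (ULN, 3*ULN], i.e. (40, 120] U/L at defaults.
* ``HEPATOTOXICITY`` — two consecutive ALT strictly > 3*ULN, OR two
  consecutive bilirubin > 1.5*ULN_bili, OR — when the pre-treatment
  baseline ALT is itself abnormal (> ULN) — two consecutive ALT
  > 1.5*baseline.

"Twice in a row" means consecutive measurements in time order regardless
of the calendar gap between them. The highest-severity rule triggered
anywhere in the series wins; boundary values use strict ">" (ALT exactly
3*ULN twice is INJURY, not HEPATOTOXICITY).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "LiverLabel",
    "LabSeries",
    "LiverStatus",
    "classify_liver_status",
    "classify_cohort",
    "group_cohort",
    "GROUP_NAMES",
]

GROUP_NAMES = {0: "No hepatotoxicity", 1: "Liver function injury", 2: "Hepatotoxicity"}


class LiverLabel(IntEnum):
    NONE = 0
    INJURY = 1
    HEPATOTOXICITY = 2


@dataclass(frozen=True)
class LabSeries:
    """Time-ordered ALT (and optionally bilirubin) measurements for one patient."""

    alt_days: tuple[float, ...]
    alt_values: tuple[float, ...]
    bili_days: tuple[float, ...] = ()
    bili_values: tuple[float, ...] = ()
    baseline_alt: float | None = None

    def __post_init__(self) -> None:
        for days, values, name in (
            (self.alt_days, self.alt_values, "ALT"),
            (self.bili_days, self.bili_values, "bilirubin"),
        ):
            if len(days) != len(values):
                raise ValueError(f"{name} days and values differ in length")
            if any(b < a for a, b in zip(days, days[1:])):
                raise ValueError(f"{name} measurement times must be non-decreasing")
            if any(v <= 0 for v in values):
                raise ValueError(f"{name} values must be positive")


@dataclass(frozen=True)
class LiverStatus:
    label: LiverLabel
    triggering_rule: str = ""
    trigger_index: int | None = None   # index of the 2nd value of the qualifying pair
    note: str = ""

    def __post_init__(self) -> None:
        if (self.label == LiverLabel.NONE) != (self.triggering_rule == ""):
            raise ValueError("triggering_rule must be empty iff label is NONE")


def _consecutive_pair(values, predicate):
    """Index of the second element of the first consecutive pair where both qualify."""
    for i in range(len(values) - 1):
        if predicate(values[i]) and predicate(values[i + 1]):
            return i + 1
    return None


def classify_liver_status(
    series: LabSeries,
    uln_alt: float = 40.0,
    uln_bili: float = 17.1,
) -> LiverStatus:
    """Classify one patient's series; highest-severity triggered rule wins."""
    alt = series.alt_values
    if len(alt) == 0:
        raise ValueError("at least one ALT measurement is required")
    if len(alt) == 1 and len(series.bili_values) <= 1:
        return LiverStatus(LiverLabel.NONE, note="insufficient-series")

    # hepatotoxicity rules, checked first (severity precedence)
    idx = _consecutive_pair(alt, lambda v: v > 3.0 * uln_alt)
    if idx is not None:
        return LiverStatus(LiverLabel.HEPATOTOXICITY, f"ALT > 3xULN ({3.0 * uln_alt:g} U/L) twice in a row", idx)
    idx = _consecutive_pair(series.bili_values, lambda v: v > 1.5 * uln_bili)
    if idx is not None:
        return LiverStatus(LiverLabel.HEPATOTOXICITY, f"bilirubin > 1.5xULN ({1.5 * uln_bili:g}) twice in a row", idx)
    if series.baseline_alt is not None and series.baseline_alt > uln_alt:
        idx = _consecutive_pair(alt, lambda v: v > 1.5 * series.baseline_alt)
        if idx is not None:
            return LiverStatus(
                LiverLabel.HEPATOTOXICITY,
                f"ALT > 1.5x abnormal baseline ({1.5 * series.baseline_alt:g} U/L) twice in a row",
                idx,
            )

    idx = _consecutive_pair(alt, lambda v: uln_alt < v <= 3.0 * uln_alt)
    if idx is not None:
        return LiverStatus(
            LiverLabel.INJURY, f"ALT in ({uln_alt:g}, {3.0 * uln_alt:g}] U/L twice in a row", idx
        )
    return LiverStatus(LiverLabel.NONE)


def classify_cohort(
    labs: pd.DataFrame,
    uln_alt: float = 40.0,
    uln_bili: float = 17.1,
) -> pd.DataFrame:
    """Classify every patient in a long-format lab table.

    ``labs`` columns: patient_id, day, alt, optional bilirubin, optional
    baseline_alt (constant per patient). Returns one row per patient with
    label (int), label_name, triggering_rule.
    """
    rows = []
    for pid, grp in labs.sort_values(["patient_id", "day"]).groupby("patient_id", sort=True):
        has_bili = "bilirubin" in grp.columns and grp["bilirubin"].notna().any()
        baseline = None
        if "baseline_alt" in grp.columns and grp["baseline_alt"].notna().any():
            baseline = float(grp["baseline_alt"].dropna().iloc[0])
        series = LabSeries(
            alt_days=tuple(grp["day"]),
            alt_values=tuple(grp["alt"]),
            bili_days=tuple(grp["day"]) if has_bili else (),
            bili_values=tuple(grp["bilirubin"]) if has_bili else (),
            baseline_alt=baseline,
        )
        status = classify_liver_status(series, uln_alt=uln_alt, uln_bili=uln_bili)
        rows.append(
            {
                "patient_id": pid,
                "label": int(status.label),
                "label_name": status.label.name,
                "triggering_rule": status.triggering_rule,
            }
        )
    return pd.DataFrame(rows)


def group_cohort(labels, days) -> pd.DataFrame:
    """Per-group descriptive statistics of hospitalization days.

    ``labels`` are integer liver-status labels (0/1/2), ``days`` the
    matching hospitalization days. Returns a three-row summary (n, mean,
    median, SD) in severity order; groups with n=0 carry NaN statistics.
    """
    labels = np.asarray(labels, dtype=int)
    days = np.asarray(days, dtype=float)
    if labels.shape != days.shape:
        raise ValueError("labels and days must align")
    rows = []
    for level in (0, 1, 2):
        sel = days[labels == level]
        rows.append(
            {
                "group": GROUP_NAMES[level],
                "label": level,
                "n": int(sel.size),
                "mean_days": float(np.mean(sel)) if sel.size else float("nan"),
                "median_days": float(np.median(sel)) if sel.size else float("nan"),
                "sd_days": float(np.std(sel, ddof=1)) if sel.size > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
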