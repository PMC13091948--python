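"""Reading, compliance filtering, smoothing and missingness reporting for daily EMA panels.

The daily diary data arrive as a long table: one row per (subject, study day,
item) with a value on a 0-100 visual-analogue scale; an unanswered prompt is
simply an absent row.  Analyses downstream operate on a seven-day centered
moving average of each subject's series, after restricting to subjects who
answered at least a given fraction of the scheduled prompts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PANEL_COLUMNS = ("subject_id", "day", "item", "value")
VAS_MIN, VAS_MAX = 0.0, 100.0


class PanelValidationError(ValueError):
    """Raised when a long-format EMA table violates the panel contract."""


@dataclass
class EMAPanel:
    """Long-format daily EMA observations with explicit missingness.

    ``data`` holds one row per observed (subject_id, day, item) triple with a
    ``value`` in [0, 100].  Missing prompts are absent rows, never NaN rows.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _validate_long(self.data)

    @property
    def subjects(self) -> np.ndarray:
        return self.data["subject_id"].unique()

    @property
    def items(self) -> np.ndarray:
        return self.data["item"].unique()

    def n_observations(self, item: str | None = None) -> pd.Series:
        """Observed-day count per subject, optionally for a single item."""
        d = self.data if item is None else self.data[self.data["item"] == item]
        return d.groupby("subject_id", sort=True)["day"].nunique()

    def item_wide(self, item: str, days_total: int) -> pd.DataFrame:
        """Subjects x days matrix for one item; NaN where unobserved."""
        d = self.data[self.data["item"] == item]
        wide = d.pivot(index="subject_id", columns="day", values="value")
        return wide.reindex(columns=range(days_total))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _validate_long(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelValidationError(f"panel is missing columns {missing}")
    df = df.loc[:, list(PANEL_COLUMNS)].copy()
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna()].tolist()
    if bad:
        raise PanelValidationError(f"non-numeric value in rows {bad[:5]}")
    df["value"] = values.astype(float)
    out = df.index[(df["value"] < VAS_MIN) | (df["value"] > VAS_MAX)].tolist()
    if out:
        raise PanelValidationError(
            f"values outside [{VAS_MIN:g}, {VAS_MAX:g}] in rows {out[:5]}"
        )
    df["day"] = pd.to_numeric(df["day"], errors="raise").astype(int)
    if (df["day"] < 0).any():
        raise PanelValidationError("negative study day")
    dup = df.duplicated(subset=["subject_id", "day", "item"], keep=False)
    if dup.any():
        key = df.loc[dup.idxmax(), ["subject_id", "day", "item"]].tolist()
        raise PanelValidationError(f"duplicate (subject, day, item) key: {key}")
    return df.sort_values(["subject_id", "item", "day"], kind="stable").reset_index(
        drop=True
    )


def read_ema_long(path) -> EMAPanel:
    """Read a long-format EMA CSV (header subject_id,day,item,value)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "item": str})
    return EMAPanel(df)


def min_observations(fraction: float, days_total: int) -> int:
    """Compliance threshold in observed days: floor(fraction * days_total).

    Rounding down reconciles a 50% threshold of 42 observations and a 10%
    threshold of 8 observations over an 84-day study window.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"compliance fraction must be in (0, 1], got {fraction}")
    return math.floor(fraction * days_total)


def compliance_filter(
    panel: EMAPanel, item: str, fraction: float, days_total: int
) -> tuple[EMAPanel, list]:
    """Keep subjects with at least the threshold number of observed days for ``item``.

    Returns the filtered panel (all items, compliant subjects only) and the
    list of excluded subject ids for reporting.
    """
    if item not in panel.items:
        raise KeyError(f"unknown item {item!r}")
    threshold = min_observations(fraction, days_total)
    counts = panel.n_observations(item)
    all_ids = pd.Index(panel.subjects)
    counts = counts.reindex(all_ids, fill_value=0)
    keep = counts.index[counts >= threshold]
    excluded = sorted(counts.index.difference(keep).tolist())
    kept = panel.data[panel.data["subject_id"].isin(keep)]
    return EMAPanel(kept), excluded


@dataclass
class SmoothedSeries:
    """A subject's moving-average series on the full day grid.

    ``values`` is NaN exactly where the window contained no raw observation;
    ``n_raw`` counts the raw observations contributing at each day.
    """

    subject_id: object
    days: np.ndarray
    values: np.ndarray
    n_raw: np.ndarray


def moving_average(values, window: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average over a gapped daily series.

    ``values`` is a length-``days_total`` float array with NaN marking missing
    days.  The window is centered (days t-3..t+3 for window 7) and truncated
    at the study edges; the output at t is the mean of the available raw
    values in the window, NaN if the window holds none.

    Returns ``(smoothed, n_contributing)``.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    s = pd.Series(np.asarray(values, dtype=float))
    roll = s.rolling(window=window, center=True, min_periods=1)
    smoothed = roll.mean().to_numpy()
    n_raw = roll.count().to_numpy().astype(int)
    smoothed[n_raw == 0] = np.nan
    return smoothed, n_raw


def smooth_panel(
    panel: EMAPanel, days_total: int, window: int = 7, items=None
) -> pd.DataFrame:
    """Apply the moving average per subject and item.

    Returns a long DataFrame (subject_id, item, day, value, n_raw) covering
    every day of the grid; ``value`` is NaN where the window was empty.
    """
    items = panel.items if items is None else items
    frames = []
    for item in items:
        wide = panel.item_wide(item, days_total)
        for sid, row in wide.iterrows():
            sm, n_raw = moving_average(row.to_numpy(), window=window)
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "item": item,
                        "day": np.arange(days_total),
                        "value": sm,
                        "n_raw": n_raw,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def flag_outlier_subjects(
    smoothed: pd.DataFrame, item: str, k: float = 4.0
) -> list:
    """Flag subjects whose smoothed-series median is an outlier under a MAD rule.

    A subject is flagged when its per-subject median lies more than ``k``
    robust deviations from the cohort median of those medians, where one
    robust deviation is the normal-consistent scaled MAD (1.4826 x median
    absolute deviation, the convention of R's ``mad()``).  The rule replaces
    the irreproducible visual screening step; flagged ids are reported, not
    removed.
    """
    d = smoothed[(smoothed["item"] == item) & smoothed["value"].notna()]
    medians = d.groupby("subject_id")["value"].median()
    if len(medians) < 3:
        raise ValueError("outlier rule needs at least 3 subjects")
    center = medians.median()
    mad = 1.4826 * (medians - center).abs().median()
    flagged = medians.index[(medians - center).abs() > k * mad]
    return sorted(flagged.tolist())


def missingness_report(
    panel: EMAPanel, smoothed: pd.DataFrame, item: str, days_total: int
) -> dict:
    """Fraction of undefined subject-days before and after smoothing.

    Denominator is subjects x days_total for the subjects present in the raw
    panel.  Smoothing can only fill gaps, so smoothed <= raw always.
    """
    n_subjects = len(panel.subjects)
    denom = n_subjects * days_total
    raw_obs = int(panel.n_observations(item).sum())
    d = smoothed[smoothed["item"] == item]
    sm_obs = int(d["value"].notna().sum())
    return {
        "raw_fraction": (denom - raw_obs) / denom if denom else 0.0,
        "smoothed_fraction": (denom - sm_obs) / denom if denom else 0.0,
        "n_subjects": n_subjects,
        "days_total": days_total,
    }


def write_missingness_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
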