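"""Derived symptom dynamics: class trajectories, weekly correlations, and the
intra-individually standardized loudness-distress difference.

The headline derived quantity is d = maximum tinnitus loudness - daily
tinnitus distress, z-scored within each subject: z = (d - mean{d}) / sd{d}.
Rising class-mean z over the study indicates distress decoupling from
loudness (a desired treatment effect); falling z the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def reverse_code(values, scale_max: float = 100.0):
    """Reverse-code a VAS series: value -> scale_max - value."""
    v = np.asarray(values, float)
    finite = v[np.isfinite(v)]
    if finite.size and (finite.min() < 0 or finite.max() > scale_max):
        raise ValueError(f"values outside [0, {scale_max:g}]")
    return scale_max - v


@dataclass
class StandardizedDiffSeries:
    subject_id: object
    days: np.ndarray
    d: np.ndarray  # raw difference where both streams defined, else NaN
    z: np.ndarray  # intra-individually standardized difference
    degenerate: bool  # constant d: z undefined


def standardized_difference(
    smoothed: pd.DataFrame,
    item_loudness: str = "maximum_tinnitus_loudness",
    item_distress: str = "daily_tinnitus_distress",
) -> list[StandardizedDiffSeries]:
    """Per-subject standardized difference series from a smoothed long panel.

    d is computed per day where both items are defined; z uses the subject's
    own mean and sample (n-1) standard deviation of d.  Subjects with a
    constant d are flagged degenerate (z undefined) and should be excluded
    from class-level summaries.
    """
    for item in (item_loudness, item_distress):
        if item not in set(smoothed["item"]):
            raise KeyError(f"unknown item {item!r}")
    wide = smoothed.pivot_table(
        index=["subject_id", "day"], columns="item", values="value", observed=True
    )
    out = []
    for sid, sub in wide.groupby(level="subject_id"):
        days = sub.index.get_level_values("day").to_numpy()
        d = (sub[item_loudness] - sub[item_distress]).to_numpy(float)
        valid = np.isfinite(d)
        z = np.full_like(d, np.nan)
        degenerate = True
        if valid.sum() >= 2:
            sd = d[valid].std(ddof=1)
            if sd > 0:
                z[valid] = (d[valid] - d[valid].mean()) / sd
                degenerate = False
        out.append(StandardizedDiffSeries(sid, days, d, z, degenerate))
    return out


def class_mean_standardized_difference(
    series: list[StandardizedDiffSeries], assignments: pd.Series
) -> pd.DataFrame:
    """Daily class means of z over non-degenerate subjects (class, day, mean_z, n)."""
    rows = []
    for s in series:
        if s.degenerate:
            continue
        g = assignments.get(s.subject_id)
        if g is None:
            continue
        rows.append(pd.DataFrame({"class": g, "day": s.days, "z": s.z}))
    if not rows:
        return pd.DataFrame(columns=["class", "day", "mean_z", "n"])
    long = pd.concat(rows, ignore_index=True).dropna(subset=["z"])
    out = (
        long.groupby(["class", "day"])["z"]
        .agg(mean_z="mean", n="size")
        .reset_index()
    )
    return out


def smoothed_z_trend(class_means: pd.DataFrame, window: int = 14) -> pd.DataFrame:
    """Local (rolling-mean) trend of the daily class-mean z, per class."""
    parts = []
    for g, sub in class_means.groupby("class"):
        sub = sub.sort_values("day").copy()
        sub["trend"] = (
            sub["mean_z"].rolling(window, center=True, min_periods=1).mean()
        )
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def weekly_class_correlation(
    smoothed: pd.DataFrame,
    item_a: str,
    item_b: str,
    assignments: pd.Series,
    days_per_week: int = 7,
    per_subject: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of two symptom streams per class and week.

    By default all (subject, day) pairs within a class-week with both items
    defined are pooled; with ``per_subject=True`` correlations are computed
    per subject and averaged.  r is absent when fewer than 3 pairs exist or
    either stream is constant.  Week 1 covers days 0..6.
    """
    items = set(smoothed["item"])
    for item in (item_a, item_b):
        if item not in items:
            raise KeyError(f"unknown item {item!r}")
    wide = smoothed.pivot_table(
        index=["subject_id", "day"], columns="item", values="value", observed=True
    )[[item_a, item_b]].dropna()
    wide = wide.reset_index()
    wide["class"] = wide["subject_id"].map(assignments)
    wide = wide.dropna(subset=["class"])
    wide["week"] = wide["day"] // days_per_week + 1

    rows = []
    for (g, wk), sub in wide.groupby(["class", "week"]):
        a, b = sub[item_a].to_numpy(), sub[item_b].to_numpy()
        if per_subject:
            rs = []
            for _, ss in sub.groupby("subject_id"):
                x, y = ss[item_a].to_numpy(), ss[item_b].to_numpy()
                if len(x) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
                    rs.append(np.corrcoef(x, y)[0, 1])
            r = float(np.mean(rs)) if rs else None
        else:
            r = None
            if len(a) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
                r = float(np.corrcoef(a, b)[0, 1])
        rows.append({"class": g, "week": int(wk), "r": r, "n_pairs": len(sub)})
    return pd.DataFrame(rows)


def class_mean_trajectories(
    smoothed: pd.DataFrame, assignments: pd.Series, item: str
) -> pd.DataFrame:
    """Per class and day: mean smoothed value with a pointwise 95% CI.

    The CI is mean +/- 1.96 * sd / sqrt(n_day) over subjects with a defined
    smoothed value that day; empty class-days are absent from the output.
    """
    if item not in set(smoothed["item"]):
        raise KeyError(f"unknown item {item!r}")
    d = smoothed[(smoothed["item"] == item) & smoothed["value"].notna()].copy()
    d["class"] = d["subject_id"].map(assignments)
    d = d.dropna(subset=["class"])
    grp = d.groupby(["class", "day"])["value"]
    out = grp.agg(mean="mean", sd="std", n="size").reset_index()
    sem = out["sd"].fillna(0.0) / np.sqrt(out["n"])
    out["ci_low"] = out["mean"] - 1.96 * sem
    out["ci_high"] = out["mean"] + 1.96 * sem
    return out
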