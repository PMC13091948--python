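"""Baseline and outcome contrasts between latent trajectory classes.

Categorical baseline variables are compared across classes with chi-square
tests of independence, continuous ones with one-way ANOVA; all p-values in
the family are Holm-Bonferroni adjusted.  Pre-to-post questionnaire changes
(THI, TFI, PHQ-9) are evaluated per class with paired t-tests and compared
against minimal clinically important differences (MCID: THI 11, TFI 9,
PHQ-9 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MCID = {"THI": 11.0, "TFI": 9.0, "PHQ9": 6.0}

DEFAULT_CATEGORICAL = ("gender", "education")
DEFAULT_CONTINUOUS = (
    "age",
    "THI_pre",
    "TFI_pre",
    "PHQ9_pre",
    "tinnitus_duration",
    "extraversion",
    "agreeableness",
    "conscientiousness",
    "neuroticism",
    "openness",
    "n_comorbidities",
    "n_prior_treatments",
)


@dataclass
class ContrastResult:
    variable: str
    test: str  # "chi-square" | "anova"
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None
    note: str = ""


@dataclass
class MCIDResult:
    class_label: int
    instrument: str
    n: int
    mean_change: float
    t_statistic: float | None
    p_raw: float | None
    p_adjusted: float | None
    mcid_threshold: float
    clinically_relevant: bool
    note: str = ""


def holm_adjust(p_values) -> list:
    """Holm-Bonferroni step-down adjustment, returned in the input order.

    The i-th smallest p-value is multiplied by (m - i + 1); running maxima
    enforce monotonicity and results are capped at 1.
    """
    p = np.asarray(list(p_values), float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, p[idx] * (m - rank))
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def _assignment_series(assignments, subject_ids=None) -> pd.Series:
    if isinstance(assignments, pd.Series):
        return assignments
    if subject_ids is None:
        raise ValueError("subject ids required with an array of assignments")
    return pd.Series(np.asarray(assignments), index=np.asarray(subject_ids))


def contrast_baseline(
    baseline: pd.DataFrame,
    assignments,
    categorical=DEFAULT_CATEGORICAL,
    continuous=DEFAULT_CONTINUOUS,
) -> list[ContrastResult]:
    """Chi-square / ANOVA contrasts of baseline variables across classes.

    One test per variable (a multi-level categorical is a single chi-square);
    all testable variables form one Holm family.  Constant variables are
    reported as untestable and excluded from the family.
    """
    assign = _assignment_series(assignments)
    tab = baseline.set_index("subject_id")
    cls = assign.reindex(tab.index)
    if cls.isna().any():
        raise ValueError("every subject in the baseline table must be assigned")
    if (np.bincount(cls.astype(int) - 1).min() if len(cls) else 0) == 0:
        raise ValueError("a latent class has zero subjects")

    results: list[ContrastResult] = []
    for var in categorical:
        counts = pd.crosstab(tab[var], cls)
        if counts.shape[0] < 2:
            results.append(
                ContrastResult(var, "chi-square", np.nan, np.nan, np.nan, None, "constant variable: untestable")
            )
            continue
        chi2, p, dof, _ = stats.chi2_contingency(counts)
        results.append(ContrastResult(var, "chi-square", float(chi2), float(dof), float(p)))
    for var in continuous:
        groups = [tab.loc[cls == g, var].dropna().to_numpy() for g in sorted(cls.unique())]
        pooled = np.concatenate(groups)
        if np.ptp(pooled) == 0:
            results.append(
                ContrastResult(var, "anova", 0.0, np.nan, np.nan, None, "constant variable: untestable")
            )
            continue
        if all(np.ptp(x) == 0 for x in groups) and len({x[0] for x in groups if len(x)}) == 1:
            results.append(ContrastResult(var, "anova", 0.0, float(len(groups) - 1), 1.0))
            continue
        f, p = stats.f_oneway(*groups)
        results.append(ContrastResult(var, "anova", float(f), float(len(groups) - 1), float(p)))

    testable = [r for r in results if np.isfinite(r.p_raw)]
    adjusted = holm_adjust([r.p_raw for r in testable])
    for r, a in zip(testable, adjusted):
        r.p_adjusted = a
    return results


def prom_change_by_class(
    baseline: pd.DataFrame,
    assignments,
    mcid: dict | None = None,
) -> list[MCIDResult]:
    """Per class and instrument: mean pre-to-post change, paired t-test, MCID flag.

    Change is post - pre; a class is flagged clinically relevant when its mean
    improvement reaches the instrument's MCID (boundary counts as relevant).
    Subjects missing either score are excluded; classes with fewer than two
    paired observations are reported untestable.  Holm adjustment is applied
    within each instrument's family of class-level tests.
    """
    mcid = dict(DEFAULT_MCID if mcid is None else mcid)
    assign = _assignment_series(assignments)
    tab = baseline.set_index("subject_id")
    cls = assign.reindex(tab.index)

    results: list[MCIDResult] = []
    for instrument, threshold in mcid.items():
        pre, post = f"{instrument}_pre", f"{instrument}_post"
        family: list[MCIDResult] = []
        for g in sorted(cls.dropna().unique()):
            sub = tab.loc[cls == g, [pre, post]].dropna()
            change = (sub[post] - sub[pre]).to_numpy()
            if len(change) < 2:
                results.append(
                    MCIDResult(int(g), instrument, len(change), float(np.mean(change)) if len(change) else np.nan,
                               None, None, None, threshold, False, "fewer than 2 paired observations")
                )
                continue
            mean_change = float(change.mean())
            if np.ptp(change) == 0:
                t, p = (0.0, 1.0) if mean_change == 0 else (np.inf, 0.0)
            else:
                t, p = stats.ttest_rel(sub[post], sub[pre])
            res = MCIDResult(
                class_label=int(g),
                instrument=instrument,
                n=len(change),
                mean_change=mean_change,
                t_statistic=float(t),
                p_raw=float(p),
                p_adjusted=None,
                mcid_threshold=threshold,
                clinically_relevant=bool(-mean_change >= threshold),
            )
            family.append(res)
            results.append(res)
        adjusted = holm_adjust([r.p_raw for r in family])
        for r, a in zip(family, adjusted):
            r.p_adjusted = a
    return results


def class_by_arm_table(arms: pd.Series, assignments) -> pd.DataFrame:
    """Count table of latent class by treatment arm (descriptive only)."""
    assign = _assignment_series(assignments)
    return pd.crosstab(assign.rename("class"), arms.rename("arm"))


def contrasts_frame(results) -> pd.DataFrame:
    """Tidy DataFrame view of a list of contrast or MCID results."""
    return pd.DataFrame([vars(r) for r in results])
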