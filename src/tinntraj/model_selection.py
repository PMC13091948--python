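"""Class enumeration and triangulated model selection.

Fits the latent-class model for a range of class counts and tabulates, per G:
log-likelihood, parameter count, AIC/BIC, relative entropy, per-class mean
posterior probability of membership (PPM), class proportions and convergence.
The final recommendation encodes the triangulation explicitly: candidates
with any class below a minimum size are flagged, and the remaining preferred
solutions are ranked by entropy, then mean PPM, then BIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lcgmm_core import LCGMMFit, LCGMMSpec, ModelData, grid_search_fit


def information_criteria(loglik: float, npar: int, n_subjects: int) -> tuple[float, float]:
    """AIC = -2 ll + 2 k; BIC = -2 ll + ln(N) k with N = number of subjects."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    aic = -2.0 * loglik + 2.0 * npar
    bic = -2.0 * loglik + np.log(n_subjects) * npar
    return aic, bic


def relative_entropy(posterior: np.ndarray) -> float:
    """Normalized classification entropy: 1 - sum(-p log p) / (N ln G).

    1 means perfectly separated classes, 0 a completely uninformative
    classification; undefined for a single class.
    """
    P = np.asarray(posterior, float)
    N, G = P.shape
    if G < 2:
        raise ValueError("relative entropy is undefined for G = 1")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log(P), 0.0)
    return float(1.0 - terms.sum() / (N * np.log(G)))


def ppm(posterior: np.ndarray, assignment: np.ndarray) -> list:
    """Per-class mean posterior probability among subjects assigned to the class.

    Empty classes yield None (reported as absent, never zero).
    """
    P = np.asarray(posterior, float)
    a = np.asarray(assignment)
    if not np.array_equal(a, P.argmax(axis=1) + 1):
        raise ValueError("assignments must be the row-argmax of the posterior")
    out = []
    for g in range(P.shape[1]):
        members = a == g + 1
        out.append(float(P[members, g].mean()) if members.any() else None)
    return out


@dataclass
class SelectionTable:
    """One row of diagnostics per candidate class count."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)  # G -> LCGMMFit

    def to_csv(self, path) -> None:
        df = self.table.copy()
        for col in ("ppm_per_class", "class_proportions"):
            df[col] = df[col].map(
                lambda v: ";".join("" if x is None else f"{x:.6g}" for x in v)
            )
        df.to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.table.to_dict(orient="records"), fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def summarize_fit(fit: LCGMMFit) -> dict:
    aic, bic = information_criteria(fit.loglik, fit.npar, fit.n_subjects)
    G = fit.params.n_classes
    props = fit.class_proportions
    return {
        "G": G,
        "loglik": fit.loglik,
        "npar": fit.npar,
        "AIC": aic,
        "BIC": bic,
        "entropy": relative_entropy(fit.posterior) if G >= 2 else None,
        "ppm_per_class": ppm(fit.posterior, fit.assignment),
        "class_proportions": props.tolist(),
        "min_class_n": int(np.bincount(fit.assignment - 1, minlength=G).min()),
        "converged": bool(fit.converged),
    }


def enumerate_classes(
    data: ModelData,
    basis=None,
    g_range=range(1, 11),
    seed: int = 0,
    n_starts: int = 30,
    burn_iters: int = 30,
    keep_fits: bool = True,
    **fit_kwargs,
) -> SelectionTable:
    """Fit every class count in ``g_range`` and assemble the diagnostics table.

    Non-convergent rows are flagged, never dropped.  The per-G grid searches
    derive their random starts from ``seed`` deterministically.
    """
    rows, fits = [], {}
    for G in g_range:
        spec = LCGMMSpec(G, data.basis, data.time_scale)
        fit = grid_search_fit(
            data, spec, n_starts=n_starts, burn_iters=burn_iters, seed=seed, **fit_kwargs
        )
        rows.append(summarize_fit(fit))
        if keep_fits:
            fits[G] = fit
    return SelectionTable(pd.DataFrame(rows), fits)


def select_model(
    table: SelectionTable | pd.DataFrame,
    min_class_fraction: float = 0.05,
    preferred_solutions: tuple = (3, 4, 5),
    tie_decimals: int = 3,
) -> dict:
    """Rule-encoded triangulation over the enumeration table.

    Rows with any class below ``min_class_fraction`` (or non-convergent) are
    flagged; among the unflagged candidates whose G is in
    ``preferred_solutions``, rank by entropy, then mean PPM, then BIC.
    Entropy and PPM are compared at ``tie_decimals`` decimals so that
    numerically indistinguishable classifications fall through to the next
    criterion rather than being decided by float noise.  The report lists
    every row with reasons; it never silently returns a single answer.
    """
    df = table.table if isinstance(table, SelectionTable) else table
    if df.empty:
        raise ValueError("empty selection table")
    report = {"criteria": [], "ranked_candidates": [], "recommended_G": None}
    candidates = []
    for _, row in df.iterrows():
        flags = []
        if not row["converged"]:
            flags.append("did not converge")
        small = [p for p in row["class_proportions"] if p < min_class_fraction]
        if small:
            flags.append(
                f"class below minimum fraction {min_class_fraction:g}: "
                + ", ".join(f"{p:.3f}" for p in small)
            )
        entry = {
            "G": int(row["G"]),
            "BIC": row["BIC"],
            "AIC": row["AIC"],
            "entropy": row["entropy"],
            "mean_ppm": _mean_ppm(row["ppm_per_class"]),
            "flags": flags,
        }
        report["criteria"].append(entry)
        if not flags and (len(df) == 1 or int(row["G"]) in preferred_solutions):
            candidates.append(entry)
    if len(df) == 1 and not report["criteria"][0]["flags"]:
        candidates = [report["criteria"][0]]
    # undefined entropy/PPM (the one-class model) ranks below any defined value
    def _defined(v):
        return v is not None and np.isfinite(v)

    candidates.sort(
        key=lambda e: (
            -round(e["entropy"] if _defined(e["entropy"]) else -1.0, tie_decimals),
            -round(e["mean_ppm"] if _defined(e["mean_ppm"]) else -1.0, tie_decimals),
            e["BIC"],
        )
    )
    report["ranked_candidates"] = candidates
    if candidates:
        report["recommended_G"] = candidates[0]["G"]
        report["reason"] = (
            "highest entropy among unflagged preferred solutions, ties broken "
            "by mean PPM then BIC"
        )
    else:
        report["reason"] = "no unflagged candidate among the preferred solutions"
    return report


def _mean_ppm(values) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None
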