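"""Latent-class linear mixed models for daily-diary trajectories.

The model: subject i with latent class g has observations

    y_ij = x(t_ij)' beta_g + b_i + eps_ij,
    b_i ~ N(0, sigma_b^2),   eps_ij ~ N(0, sigma_eps^2),
    P(class = g) = pi_g,

where x(t) = (1, natural-cubic-spline basis of time).  The random-intercept
and residual variances are shared across classes, so each subject's marginal
covariance is compound-symmetric: Sigma_i = sigma_b^2 J + sigma_eps^2 I.
Estimation is by EM with a generalized-least-squares M-step for the class
coefficients and direct numeric maximization for the two variance
components; multi-start grid search around the one-class solution guards
against local maxima.

Likelihood evaluations use the rank-one (Sherman-Morrison) closed form

    Sigma^{-1} = sigma_eps^{-2} [I - c J],  c = sigma_b^2/(sigma_eps^2 + n sigma_b^2)
    det Sigma  = (sigma_eps^2)^{n-1} (sigma_eps^2 + n sigma_b^2)

so no dense matrix is ever built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, minimize
from scipy.special import logsumexp

_LOG2PI = np.log(2.0 * np.pi)
SIGMA_EPS_FLOOR = 1e-4
DEGENERATE_MASS = 1.0  # minimum posterior subject-equivalents per class


# ---------------------------------------------------------------------------
# spline basis
# ---------------------------------------------------------------------------


@dataclass
class SplineBasisSpec:
    """Natural cubic spline basis of time with ``df`` columns (no intercept).

    ``df`` basis columns require df+1 knots in total: two boundary knots and
    df-1 interior knots.  Interior knots default to terciles (quantiles) of
    the pooled observed times; boundary knots to the observed min/max.
    """

    df: int = 3
    interior_knots: np.ndarray | None = None
    boundary_knots: tuple | None = None

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError(f"spline df must be >= 1, got {self.df}")
        if self.interior_knots is not None:
            self.interior_knots = np.asarray(self.interior_knots, float)
            if len(self.interior_knots) != self.df - 1:
                raise ValueError(
                    f"df={self.df} needs {self.df - 1} interior knots, "
                    f"got {len(self.interior_knots)}"
                )

    def resolve(self, times: np.ndarray) -> "SplineBasisSpec":
        """Fill in data-driven knots from the pooled observed times."""
        times = np.asarray(times, float)
        boundary = self.boundary_knots or (times.min(), times.max())
        interior = self.interior_knots
        if interior is None:
            qs = np.linspace(0, 1, self.df + 1)[1:-1]
            interior = np.quantile(times, qs)
        lo, hi = boundary
        if np.any((np.asarray(interior) <= lo) | (np.asarray(interior) >= hi)):
            raise ValueError("interior knots must lie strictly inside the boundary")
        return SplineBasisSpec(self.df, np.asarray(interior, float), (lo, hi))

    @property
    def all_knots(self) -> np.ndarray:
        if self.boundary_knots is None:
            raise ValueError("basis not resolved: boundary knots unknown")
        interior = self.interior_knots if self.interior_knots is not None else []
        return np.sort(np.r_[self.boundary_knots[0], interior, self.boundary_knots[1]])


def ncs_basis(times, spec: SplineBasisSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis (truncated-power construction).

    With knots xi_1 < ... < xi_K (K = df + 1) define
    ``d_k(x) = ((x - xi_k)^3_+ - (x - xi_K)^3_+) / (xi_K - xi_k)``;
    the returned columns are ``x`` and ``d_k - d_{K-1}`` for k = 1..K-2.
    Each column is C^2 inside and linear beyond the boundary knots.
    """
    times = np.asarray(times, float)
    knots = spec.all_knots
    lo, hi = knots[0], knots[-1]
    span = hi - lo
    if np.any(times < lo - 0.05 * span) or np.any(times > hi + 0.05 * span):
        raise ValueError("time outside the tolerated boundary-knot range")
    K = len(knots)
    cols = [times]

    def d(k):
        num = np.maximum(times - knots[k], 0.0) ** 3 - np.maximum(
            times - knots[K - 1], 0.0
        ) ** 3
        return num / (knots[K - 1] - knots[k])

    if K >= 3:
        d_last = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - d_last)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# model definition and data container
# ---------------------------------------------------------------------------


@dataclass
class LCGMMSpec:
    """Model definition: class count, spline basis, shared random intercept."""

    n_classes: int
    basis: SplineBasisSpec = field(default_factory=SplineBasisSpec)
    time_scale: float = 1.0  # day values are divided by this before the basis

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


@dataclass
class LCGMMParams:
    """One parameter point: class coefficients, variances, mixing proportions."""

    beta: np.ndarray  # (G, 1+df), intercept first
    sigma_b: float
    sigma_eps: float
    pi: np.ndarray  # (G,)
    se_beta: np.ndarray | None = None  # (G, 1+df) approximate standard errors

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, float))
        self.pi = np.asarray(self.pi, float)
        if abs(self.pi.sum() - 1.0) > 1e-8 or (self.pi < 0).any():
            raise ValueError("pi must be a probability vector")
        if self.sigma_b < 0 or self.sigma_eps <= 0:
            raise ValueError("need sigma_b >= 0 and sigma_eps > 0")

    @property
    def n_classes(self) -> int:
        return len(self.pi)


@dataclass
class ModelData:
    """Stacked per-subject observations plus cached sufficient statistics."""

    subject_ids: np.ndarray  # (N,)
    y: np.ndarray  # (M,)
    X: np.ndarray  # (M, p) design incl. intercept column
    subj_idx: np.ndarray  # (M,) in 0..N-1
    n_i: np.ndarray  # (N,)
    basis: SplineBasisSpec
    time_scale: float
    # cached cross-products, fixed across EM iterations
    XtX: np.ndarray = field(init=False)  # (N, p, p)
    Xty: np.ndarray = field(init=False)  # (N, p)
    X1: np.ndarray = field(init=False)  # (N, p) = X_i' 1
    y1: np.ndarray = field(init=False)  # (N,) = 1' y_i

    def __post_init__(self) -> None:
        N, p = len(self.subject_ids), self.X.shape[1]
        self.XtX = np.zeros((N, p, p))
        self.Xty = np.zeros((N, p))
        self.X1 = np.zeros((N, p))
        self.y1 = np.bincount(self.subj_idx, weights=self.y, minlength=N)
        for a in range(p):
            self.X1[:, a] = np.bincount(self.subj_idx, weights=self.X[:, a], minlength=N)
            self.Xty[:, a] = np.bincount(
                self.subj_idx, weights=self.X[:, a] * self.y, minlength=N
            )
            for b in range(a, p):
                v = np.bincount(
                    self.subj_idx, weights=self.X[:, a] * self.X[:, b], minlength=N
                )
                self.XtX[:, a, b] = v
                self.XtX[:, b, a] = v

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_model_data(
    smoothed: pd.DataFrame,
    item: str,
    basis: SplineBasisSpec | None = None,
    time_scale: float | None = None,
) -> ModelData:
    """Assemble estimation-ready data from a smoothed long panel.

    ``smoothed`` must have columns subject_id, item, day, value (NaN where the
    series is undefined).  Time is rescaled to [0, 1] before constructing the
    spline basis, for conditioning; knots are resolved on the scaled axis.
    """
    d = smoothed[(smoothed["item"] == item) & smoothed["value"].notna()]
    if d.empty:
        raise ValueError(f"no observations for item {item!r}")
    ids, subj_idx = np.unique(d["subject_id"].to_numpy(), return_inverse=True)
    days = d["day"].to_numpy(float)
    scale = time_scale if time_scale is not None else max(days.max(), 1.0)
    t = days / scale
    basis = (basis or SplineBasisSpec()).resolve(t)
    B = ncs_basis(t, basis)
    X = np.column_stack([np.ones(len(t)), B])
    n_i = np.bincount(subj_idx, minlength=len(ids))
    return ModelData(
        subject_ids=ids,
        y=d["value"].to_numpy(float),
        X=X,
        subj_idx=subj_idx,
        n_i=n_i,
        basis=basis,
        time_scale=scale,
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def cs_loglik(y, mu, sigma_b: float, sigma_eps: float) -> float:
    """Gaussian log-density of one subject under compound symmetry.

    Covariance is ``sigma_b^2 J + sigma_eps^2 I``; evaluated with the
    rank-one closed form for the inverse and determinant.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have matching length")
    if sigma_eps <= 0:
        raise ValueError("sigma_eps must be positive")
    n = len(y)
    r = y - mu
    ve, vb = sigma_eps**2, sigma_b**2
    S, T = float(r @ r), float(r.sum())
    c = vb / (ve + n * vb)
    quad = (S - c * T * T) / ve
    logdet = (n - 1) * np.log(ve) + np.log(ve + n * vb)
    return -0.5 * (n * _LOG2PI + logdet + quad)


def _residual_stats(data: ModelData, beta: np.ndarray):
    """Per-subject, per-class residual sums: S_ig = sum r^2, T_ig = sum r."""
    R = data.y[:, None] - data.X @ beta.T  # (M, G)
    N, G = data.n_subjects, beta.shape[0]
    S = np.empty((N, G))
    T = np.empty((N, G))
    for g in range(G):
        S[:, g] = np.bincount(data.subj_idx, weights=R[:, g] ** 2, minlength=N)
        T[:, g] = np.bincount(data.subj_idx, weights=R[:, g], minlength=N)
    return S, T


def _loglik_matrix_from_stats(S, T, n_i, sigma_b, sigma_eps) -> np.ndarray:
    ve, vb = sigma_eps**2, sigma_b**2
    n = n_i[:, None]
    c = vb / (ve + n * vb)
    quad = (S - c * T**2) / ve
    logdet = (n - 1) * np.log(ve) + np.log(ve + n * vb)
    return -0.5 * (n * _LOG2PI + logdet + quad)


def _loglik_matrix(data: ModelData, params: LCGMMParams) -> np.ndarray:
    S, T = _residual_stats(data, params.beta)
    return _loglik_matrix_from_stats(S, T, data.n_i, params.sigma_b, params.sigma_eps)


def mixture_loglik(data: ModelData, params: LCGMMParams) -> float:
    """Observed-data log-likelihood of the finite mixture (log-sum-exp stabilized)."""
    if data.n_obs == 0:
        raise ValueError("empty data")
    L = _loglik_matrix(data, params)
    with np.errstate(divide="ignore"):
        return float(logsumexp(L + np.log(params.pi), axis=1).sum())


def posterior_probs(data: ModelData, params: LCGMMParams) -> np.ndarray:
    """Per-subject posterior class probabilities p_ig, rows summing to 1."""
    L = _loglik_matrix(data, params)
    with np.errstate(divide="ignore"):
        A = L + np.log(params.pi)
    A -= A.max(axis=1, keepdims=True)
    W = np.exp(A)
    return W / W.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class LCGMMFit:
    """A fitted model: parameters, likelihood, classification, diagnostics."""

    spec: LCGMMSpec
    params: LCGMMParams
    loglik: float
    posterior: np.ndarray  # (N, G)
    assignment: np.ndarray  # (N,) in 1..G
    subject_ids: np.ndarray
    n_subjects: int
    n_obs: int
    npar: int
    converged: bool
    n_iterations: int
    best_start_index: int = 0
    message: str = ""
    beta_cov: np.ndarray | None = None  # (G, p, p) asymptotic covariance blocks
    history: list = field(default_factory=list)  # observed log-likelihood per iteration

    @property
    def class_proportions(self) -> np.ndarray:
        G = self.params.n_classes
        counts = np.bincount(self.assignment - 1, minlength=G)
        return counts / max(self.n_subjects, 1)

    def to_dict(self) -> dict:
        return {
            "n_classes": self.spec.n_classes,
            "spline_df": self.spec.basis.df,
            "interior_knots": _aslist(self.spec.basis.interior_knots),
            "boundary_knots": _aslist(self.spec.basis.boundary_knots),
            "time_scale": self.spec.time_scale,
            "beta": self.params.beta.tolist(),
            "sigma_b": self.params.sigma_b,
            "sigma_eps": self.params.sigma_eps,
            "pi": self.params.pi.tolist(),
            "loglik": self.loglik,
            "npar": self.npar,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "n_iterations": self.n_iterations,
            "best_start_index": self.best_start_index,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def posterior_frame(self) -> pd.DataFrame:
        G = self.params.n_classes
        out = pd.DataFrame({"subject_id": self.subject_ids})
        for g in range(G):
            out[f"p_class{g + 1}"] = self.posterior[:, g]
        out["assignment"] = self.assignment
        return out


def _aslist(x):
    if x is None:
        return None
    return np.asarray(x, float).tolist()


def count_parameters(spec: LCGMMSpec) -> int:
    """Free parameters: G*(1+df) coefficients + (G-1) mixing + 2 variances."""
    G, df = spec.n_classes, spec.basis.df
    return G * (1 + df) + (G - 1) + 2


def _update_beta(data: ModelData, W: np.ndarray, sigma_b, sigma_eps) -> np.ndarray:
    """Posterior-weighted GLS solve for each class's coefficient vector."""
    ve, vb = sigma_eps**2, sigma_b**2
    c = vb / (ve + data.n_i * vb)  # (N,)
    G = W.shape[1]
    p = data.X.shape[1]
    beta = np.empty((G, p))
    for g in range(G):
        w = W[:, g]
        A = np.einsum("i,ipq->pq", w, data.XtX) - np.einsum(
            "i,ip,iq->pq", w * c, data.X1, data.X1
        )
        b = data.Xty.T @ w - data.X1.T @ (w * c * data.y1)
        beta[g] = np.linalg.solve(A, b)
    return beta


def _optimize_variances(S, T, n_i, log_pi, sigma_b, sigma_eps, maxiter=60):
    """Maximize the observed mixture log-likelihood over the two variances.

    Residual statistics S, T are fixed (beta held), so each evaluation is a
    cheap array expression; optimization is over log variances, Nelder-Mead.
    """

    def neg_ll(x):
        x = np.clip(x, -40.0, 40.0)  # keep exp() finite under optimizer excursions
        sb = np.sqrt(np.exp(x[0]))
        se = np.sqrt(np.exp(x[1]))
        L = _loglik_matrix_from_stats(S, T, n_i, sb, se)
        return -float(logsumexp(L + log_pi, axis=1).sum())

    x0 = np.array(
        [np.log(max(sigma_b, 1e-3) ** 2), np.log(max(sigma_eps, SIGMA_EPS_FLOOR) ** 2)]
    )
    f0 = neg_ll(x0)
    res = minimize(neg_ll, x0, method="Nelder-Mead", options={"maxiter": maxiter})
    if res.fun < f0:
        sb = float(np.sqrt(np.exp(res.x[0])))
        se = float(np.sqrt(np.exp(res.x[1])))
        return max(sb, 0.0), max(se, SIGMA_EPS_FLOOR)
    return sigma_b, sigma_eps


def fit_em(
    data: ModelData,
    spec: LCGMMSpec,
    start: LCGMMParams,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LCGMMFit:
    """Run EM from ``start`` until the relative log-likelihood change < tol.

    E-step: posterior class probabilities.  M-step: mixing proportions as mean
    posteriors, class coefficients by weighted GLS under the compound-symmetry
    covariance, then the two variance components by direct numeric
    maximization of the observed likelihood (accepted only if improving, so
    the log-likelihood is non-decreasing across iterations).
    """
    beta = start.beta.copy()
    sigma_b, sigma_eps = start.sigma_b, start.sigma_eps
    pi = start.pi.copy()
    G = spec.n_classes
    ll_old = -np.inf
    converged = False
    message = ""
    n_iter = 0
    history: list[float] = []
    W = np.full((data.n_subjects, G), 1.0 / G)

    for n_iter in range(1, max_iter + 1):
        S, T = _residual_stats(data, beta)
        L = _loglik_matrix_from_stats(S, T, data.n_i, sigma_b, sigma_eps)
        with np.errstate(divide="ignore"):
            A = L + np.log(pi)
        ll = float(logsumexp(A, axis=1).sum())
        history.append(ll)
        A -= A.max(axis=1, keepdims=True)
        W = np.exp(A)
        W /= W.sum(axis=1, keepdims=True)

        mass = W.sum(axis=0)
        if G > 1 and mass.min() < DEGENERATE_MASS:
            message = (
                f"degenerate class: posterior mass {mass.min():.3f} < "
                f"{DEGENERATE_MASS} subject-equivalents"
            )
            break

        if ll_old > -np.inf and abs(ll - ll_old) <= tol * max(abs(ll_old), 1.0):
            converged = True
            ll_old = ll
            break
        ll_old = ll

        pi = mass / data.n_subjects
        beta = _update_beta(data, W, sigma_b, sigma_eps)
        S, T = _residual_stats(data, beta)
        with np.errstate(divide="ignore"):
            sigma_b, sigma_eps = _optimize_variances(
                S, T, data.n_i, np.log(pi), sigma_b, sigma_eps
            )

    params = LCGMMParams(beta=beta, sigma_b=sigma_b, sigma_eps=sigma_eps, pi=pi)
    if not converged and not message:
        ll_old = mixture_loglik(data, params)  # report the post-update likelihood
    posterior = posterior_probs(data, params)
    assignment = posterior.argmax(axis=1) + 1
    return LCGMMFit(
        spec=spec,
        params=params,
        loglik=float(ll_old),
        posterior=posterior,
        assignment=assignment,
        subject_ids=data.subject_ids,
        n_subjects=data.n_subjects,
        n_obs=data.n_obs,
        npar=count_parameters(spec),
        converged=converged,
        n_iterations=n_iter,
        message=message,
        beta_cov=_beta_covariance(data, posterior, sigma_b, sigma_eps),
        history=history,
    )


def _beta_covariance(data, W, sigma_b, sigma_eps) -> np.ndarray:
    """Per-class asymptotic covariance of beta_g from the weighted GLS information."""
    ve, vb = sigma_eps**2, sigma_b**2
    c = vb / (ve + data.n_i * vb)
    G = W.shape[1]
    p = data.X.shape[1]
    cov = np.empty((G, p, p))
    for g in range(G):
        w = W[:, g]
        info = (
            np.einsum("i,ipq->pq", w, data.XtX)
            - np.einsum("i,ip,iq->pq", w * c, data.X1, data.X1)
        ) / ve
        cov[g] = np.linalg.pinv(info)
    return cov


def fit_one_class(
    data: ModelData,
    spec: LCGMMSpec | None = None,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> LCGMMFit:
    """Maximum-likelihood fit of the one-class (plain LMM) model.

    Alternates GLS for beta with numeric maximization over the variances; the
    fit carries approximate standard errors of beta for use as grid-search
    perturbation scales.
    """
    if spec is None:
        spec = LCGMMSpec(1, data.basis, data.time_scale)
    if spec.n_classes != 1:
        raise ValueError("fit_one_class requires a one-class spec")
    p = data.X.shape[1]
    if data.n_subjects < p:
        raise ValueError("fewer subjects than fixed-effect parameters")
    # OLS start, residual split half-and-half
    beta0 = np.linalg.lstsq(data.X, data.y, rcond=None)[0]
    resid = data.y - data.X @ beta0
    s2 = float(resid @ resid) / max(data.n_obs - p, 1)
    start = LCGMMParams(
        beta=beta0[None, :],
        sigma_b=np.sqrt(s2 / 2) or 1.0,
        sigma_eps=max(np.sqrt(s2 / 2), SIGMA_EPS_FLOOR),
        pi=np.array([1.0]),
    )
    fit = fit_em(data, spec, start, max_iter=max_iter, tol=tol)
    se = np.sqrt(np.maximum(np.diagonal(fit.beta_cov, axis1=1, axis2=2), 0.0))
    fit.params.se_beta = se
    return fit


def grid_search_fit(
    data: ModelData,
    spec: LCGMMSpec,
    n_starts: int = 30,
    burn_iters: int = 30,
    seed: int | None = 0,
    perturb_scale: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    retry_starts: int = 50,
    _is_retry: bool = False,
) -> LCGMMFit:
    """Multi-start EM: perturb the one-class solution, burn in, refine the best.

    ``n_starts`` starting points are drawn by adding Normal(0, perturb_scale *
    SE) noise per class to the one-class coefficients, with uniform mixing
    proportions; each runs ``burn_iters`` EM iterations, and the start with
    the highest log-likelihood is run to full convergence.  On failure the
    search is retried once with ``retry_starts`` starts.  Deterministic given
    ``seed``.
    """
    one = fit_one_class(data)
    if spec.n_classes == 1:
        return one
    G = spec.n_classes
    beta1 = one.params.beta[0]
    se = one.params.se_beta[0]
    rng = np.random.default_rng(
        np.random.SeedSequence([0 if seed is None else seed, G, int(_is_retry)])
    )
    pi0 = np.full(G, 1.0 / G)

    best_ll, best_params, best_idx = -np.inf, None, -1
    for s in range(n_starts):
        beta_s = beta1[None, :] + rng.normal(0.0, perturb_scale * se, size=(G, len(beta1)))
        start = LCGMMParams(
            beta=beta_s,
            sigma_b=max(one.params.sigma_b, 1e-3),
            sigma_eps=max(one.params.sigma_eps, SIGMA_EPS_FLOOR),
            pi=pi0.copy(),
        )
        burned = fit_em(data, spec, start, max_iter=burn_iters, tol=0.0)
        if burned.message:  # degenerate during burn-in: discard this start
            continue
        if burned.loglik > best_ll:
            best_ll = burned.loglik
            best_params = burned.params
            best_idx = s

    if best_params is None:
        if not _is_retry:
            return grid_search_fit(
                data,
                spec,
                n_starts=retry_starts,
                burn_iters=burn_iters,
                seed=seed,
                perturb_scale=perturb_scale,
                max_iter=max_iter,
                tol=tol,
                _is_retry=True,
            )
        raise RuntimeError("all grid-search starts degenerate")

    fit = fit_em(data, spec, best_params, max_iter=max_iter, tol=tol)
    fit.best_start_index = best_idx
    if not fit.converged and not _is_retry:
        retry = grid_search_fit(
            data,
            spec,
            n_starts=retry_starts,
            burn_iters=burn_iters,
            seed=seed,
            perturb_scale=perturb_scale,
            max_iter=max_iter,
            tol=tol,
            _is_retry=True,
        )
        if retry.converged or retry.loglik > fit.loglik:
            return retry
    return fit


# ---------------------------------------------------------------------------
# prediction and labeling
# ---------------------------------------------------------------------------


def predict_class_trajectory(fit: LCGMMFit, days) -> pd.DataFrame:
    """Per-class mean curve with pointwise 95% confidence bands.

    The mean at day d is ``[1, basis(d/time_scale)] beta_g``; the band is the
    delta-method pointwise interval from the asymptotic covariance of beta_g.
    """
    if not fit.converged:
        raise RuntimeError("cannot predict from a non-converged fit")
    days = np.asarray(days, float)
    t = days / fit.spec.time_scale
    B = ncs_basis(t, fit.spec.basis)
    Xg = np.column_stack([np.ones(len(t)), B])
    rows = []
    for g in range(fit.params.n_classes):
        mean = Xg @ fit.params.beta[g]
        if fit.beta_cov is not None:
            var = np.einsum("dp,pq,dq->d", Xg, fit.beta_cov[g], Xg)
            se = np.sqrt(np.maximum(var, 0.0))
        else:
            se = np.zeros(len(days))
        rows.append(
            pd.DataFrame(
                {
                    "class": g + 1,
                    "day": days,
                    "mean": mean,
                    "ci_low": mean - 1.96 * se,
                    "ci_high": mean + 1.96 * se,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def relabel_by_baseline(fit: LCGMMFit) -> LCGMMFit:
    """Reorder classes by fitted mean at day 0, descending, for stable reporting."""
    t0 = np.zeros(1)
    B = ncs_basis(t0, fit.spec.basis)
    X0 = np.column_stack([np.ones(1), B])
    day0 = (X0 @ fit.params.beta.T).ravel()
    order = np.argsort(-day0, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    params = LCGMMParams(
        beta=fit.params.beta[order],
        sigma_b=fit.params.sigma_b,
        sigma_eps=fit.params.sigma_eps,
        pi=fit.params.pi[order],
        se_beta=None if fit.params.se_beta is None else fit.params.se_beta[order],
    )
    return replace(
        fit,
        params=params,
        posterior=fit.posterior[:, order],
        assignment=inv[fit.assignment - 1] + 1,
        beta_cov=None if fit.beta_cov is None else fit.beta_cov[order],
    )


def align_to_truth(assignment: np.ndarray, truth: np.ndarray, n_classes: int):
    """Best label permutation (Hungarian) and the resulting accuracy.

    Returns ``(mapping, accuracy)`` where ``mapping[k]`` is the truth label
    matched to fitted label k+1.
    """
    assignment = np.asarray(assignment)
    truth = np.asarray(truth)
    conf = np.zeros((n_classes, n_classes))
    for a, t in zip(assignment - 1, truth - 1):
        conf[a, t] += 1
    row, col = linear_sum_assignment(-conf)
    mapping = np.empty(n_classes, dtype=int)
    mapping[row] = col + 1
    accuracy = conf[row, col].sum() / len(truth)
    return mapping, float(accuracy)
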