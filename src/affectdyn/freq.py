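"""Maximum-likelihood mixed-effects location-scale model.

Level 1: y_ti = pi0_i + pi1_i * x_ti + e_ti with x the person-mean-centered
lagged outcome and Var(e_ti) = sigma2_g, log sigma2_g linear in the group
dummies.  Level 2: (pi0_i, pi1_i) = group means + (r0_i, r1_i) with a free
2x2 between-person covariance.  The marginal likelihood is available in
closed form person by person, so estimation profiles the fixed effects by
generalized least squares and optimizes the variance parameters
(log-variance coefficients + log-Cholesky factor of the random-effects
covariance) by quasi-Newton with multi-start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2 * np.pi))


@dataclass
class GroupDesign:
    """Dummy coding of group labels against a reference group.

    ``dummy_map`` sends each non-reference group label to the name of its
    indicator covariate.  Several labels may share one indicator (the pooled
    "all patients vs healthy controls" contrast).  The reference group is
    encoded as all zeros.
    """

    reference: str
    dummy_map: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.reference in self.dummy_map:
            raise ValueError("reference group must not appear in dummy_map")
        seen: list[str] = []
        for name in self.dummy_map.values():
            if name not in seen:
                seen.append(name)
        self._dummy_names = tuple(seen)

    @classmethod
    def from_labels(cls, labels: Sequence[str], reference: str, pooled: bool = False,
                    pooled_name: str = "patients") -> "GroupDesign":
        uniq = sorted(set(map(str, labels)))
        if reference not in uniq:
            raise ValueError(f"reference group {reference!r} not among labels {uniq}")
        others = [g for g in uniq if g != reference]
        if pooled:
            return cls(reference, {g: pooled_name for g in others})
        return cls(reference, {g: g for g in others})

    @property
    def dummy_names(self) -> tuple[str, ...]:
        return self._dummy_names

    @property
    def n_dummies(self) -> int:
        return len(self._dummy_names)

    def encode(self, labels: Sequence[str]) -> np.ndarray:
        """(n, K) indicator matrix, one column per dummy covariate."""
        out = np.zeros((len(labels), self.n_dummies))
        col = {name: j for j, name in enumerate(self._dummy_names)}
        for i, lab in enumerate(map(str, labels)):
            if lab == self.reference:
                continue
            if lab not in self.dummy_map:
                raise KeyError(f"unknown group label {lab!r}")
            out[i, col[self.dummy_map[lab]]] = 1.0
        return out


@dataclass
class FreqFit:
    """Maximum-likelihood fit of the location-scale model."""

    design: GroupDesign
    beta: np.ndarray
    beta_names: list[str]
    beta_se: np.ndarray
    vcov_beta: np.ndarray
    alpha: np.ndarray
    alpha_names: list[str]
    alpha_se: np.ndarray
    re_cov: np.ndarray
    re_cov_se: np.ndarray
    loglik: float
    converged: bool
    grad_norm: float
    n_persons: int
    n_obs: int
    boundary: bool = False
    trace: list = field(default_factory=list, repr=False)
    n_starts: int = 1

    @property
    def residual_variances(self) -> dict[str, float]:
        """Fitted within-person variance per group (reference + dummies)."""
        out = {self.design.reference: float(np.exp(self.alpha[0]))}
        for j, name in enumerate(self.design.dummy_names):
            out[name] = float(np.exp(self.alpha[0] + self.alpha[1 + j]))
        return out

    def metadata(self) -> dict:
        return {
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
            "grad_norm": self.grad_norm,
            "n_persons": self.n_persons,
            "n_obs": self.n_obs,
            "n_starts": self.n_starts,
        }


# ---------------------------------------------------------------------------
# sufficient statistics


class _Stats:
    """Per-person sufficient statistics of the marginal likelihood."""

    def __init__(self, frame: pd.DataFrame, design: GroupDesign):
        frame = _analysis_frame(frame)
        sort_cols = [c for c in ("day", "prompt_index") if c in frame.columns]
        ids, groups, A, b, c, n = [], [], [], [], [], []
        for pid, sub in frame.groupby("person_id", sort=True):
            if sort_cols:  # row-order invariance: fix the summation order
                sub = sub.sort_values(sort_cols, kind="stable")
            y = sub["y"].to_numpy(dtype=float)
            x = sub["x"].to_numpy(dtype=float)
            if len(y) < 2:
                raise ValueError(f"person {pid!r} has fewer than 2 usable rows")
            g = sub["group"].iloc[0]
            ids.append(pid)
            groups.append(str(g))
            A.append([[len(y), x.sum()], [x.sum(), (x * x).sum()]])
            b.append([y.sum(), (x * y).sum()])
            c.append(float(y @ y))
            n.append(len(y))
        self.person_ids = ids
        self.groups = groups
        self.A = np.asarray(A)          # (J, 2, 2)
        self.b = np.asarray(b)          # (J, 2)
        self.c = np.asarray(c)          # (J,)
        self.n = np.asarray(n, float)   # (J,)
        self.D = design.encode(groups)  # (J, K)
        self.v = np.hstack([np.ones((len(ids), 1)), self.D])  # (J, 1+K)
        self.N = int(self.n.sum())
        self.J = len(ids)


def _analysis_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Normalize the analysis frame to columns person_id/group/y/x, x non-missing."""
    frame = frame.copy()
    if "x" not in frame.columns:
        if "x_lag_centered" not in frame.columns:
            raise ValueError("analysis frame needs an 'x' or 'x_lag_centered' column")
        frame["x"] = frame["x_lag_centered"]
    frame = frame.dropna(subset=["x", "y"])
    return frame


def _inv2(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch inverse and determinant of (J,2,2) matrices."""
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1]
    inv[:, 1, 1] = M[:, 0, 0]
    inv[:, 0, 1] = -M[:, 0, 1]
    inv[:, 1, 0] = -M[:, 1, 0]
    return inv / det[:, None, None], det


def _person_pieces(stats: _Stats, alpha: np.ndarray, T: np.ndarray):
    """Woodbury pieces per person: W'V^-1 W, W'V^-1 y, y'V^-1 y, logdet V."""
    log_s2 = stats.v[:, : len(alpha)] @ alpha
    with np.errstate(over="ignore"):
        s2 = np.exp(log_s2)
    if np.any(~np.isfinite(s2)) or np.any(s2 <= 0):
        raise FloatingPointError("non-finite residual variance")
    S = stats.A / s2[:, None, None]
    M = np.eye(2)[None] + S @ T
    Minv, detM = _inv2(M)
    if np.any(detM <= 0):
        bad = stats.person_ids[int(np.argmax(detM <= 0))]
        raise np.linalg.LinAlgError(f"singular marginal covariance for person {bad!r}")
    u = stats.b / s2[:, None]
    ST = S @ T
    P = S - ST @ Minv @ S                     # W'V^-1 W, (J,2,2)
    r = u - np.einsum("iab,ib->ia", ST @ Minv, u)  # W'V^-1 y
    TMinv = np.einsum("ab,ibc->iac", T, Minv)
    q = stats.c / s2 - np.einsum("ia,iab,ib->i", u, TMinv, u)
    logdet = stats.n * log_s2 + np.log(detM)
    return P, r, q, logdet


def _beta_from_pieces(stats: _Stats, P, r):
    p = 2 * stats.v.shape[1]
    O = np.einsum("ij,ik->ijk", stats.v, stats.v)
    XtVX = np.einsum("iab,ijk->ajbk", P, O).reshape(p, p)
    XtVy = np.einsum("ia,ij->aj", r, stats.v).reshape(p)
    beta = np.linalg.solve(XtVX, XtVy)
    return beta, XtVX, XtVy


def _loglik_from_pieces(stats: _Stats, P, r, q, logdet, beta):
    nv = stats.v.shape[1]
    B = beta.reshape(2, nv)                   # rows: intercept-eq, slope-eq
    bg = stats.v @ B.T                        # (J, 2) person-level coefficient pair
    quad = q - 2 * np.einsum("ia,ia->i", bg, r) + np.einsum("ia,iab,ib->i", bg, P, bg)
    return -0.5 * (stats.N * _LOG2PI + logdet.sum() + quad.sum())


def marginal_loglik(data: pd.DataFrame, design: GroupDesign, beta: np.ndarray,
                    alpha: np.ndarray, re_cov: np.ndarray) -> float:
    """Closed-form marginal log-likelihood at the given parameter values.

    ``beta`` is ordered (homebase intercept, homebase dummies..., slope
    intercept, slope dummies...), ``alpha`` as (intercept, dummies...),
    ``re_cov`` is the 2x2 covariance of the person-level deviations.
    """
    stats_ = data if isinstance(data, _Stats) else _Stats(data, design)
    beta = np.asarray(beta, float)
    alpha = np.asarray(alpha, float)
    T = np.asarray(re_cov, float)
    if T.shape != (2, 2) or not np.allclose(T, T.T):
        raise ValueError("re_cov must be symmetric 2x2")
    if np.any(np.linalg.eigvalsh(T) < -1e-10):
        raise ValueError("re_cov must be positive semi-definite")
    P, r, q, logdet = _person_pieces(stats_, alpha, T)
    return float(_loglik_from_pieces(stats_, P, r, q, logdet, beta))


# ---------------------------------------------------------------------------
# fitting


def _theta_to_T(theta_T: np.ndarray, random_slope: bool) -> np.ndarray:
    if random_slope:
        l0, l1, l2 = theta_T
        L = np.array([[np.exp(l0), 0.0], [l1, np.exp(l2)]])
    else:
        L = np.array([[np.exp(theta_T[0]), 0.0], [0.0, 0.0]])
    return L @ L.T


def _profiled_nll(theta, stats: _Stats, n_alpha: int, random_slope: bool):
    alpha = theta[:n_alpha]
    T = _theta_to_T(theta[n_alpha:], random_slope)
    P, r, q, logdet = _person_pieces(stats, alpha, T)
    beta, XtVX, XtVy = _beta_from_pieces(stats, P, r)
    ll = -0.5 * (stats.N * _LOG2PI + logdet.sum() + q.sum() - beta @ XtVy)
    return -ll, beta, XtVX


def _start_values(stats: _Stats, n_alpha: int, random_slope: bool) -> np.ndarray:
    """Data-driven start from per-person OLS fits."""
    coefs, resvars = [], []
    for i in range(stats.J):
        A, b, c, n = stats.A[i], stats.b[i], stats.c[i], stats.n[i]
        try:
            th = np.linalg.solve(A + 1e-8 * np.eye(2), b)
        except np.linalg.LinAlgError:
            th = np.array([b[0] / n, 0.0])
        rss = max(c - 2 * th @ b + th @ A @ th, 1e-6)
        coefs.append(th)
        resvars.append(rss / max(n - 2, 1))
    coefs = np.asarray(coefs)
    logrv = np.log(np.asarray(resvars))
    # regress log residual variance on the dummies for the alpha start
    va = stats.v[:, :n_alpha]
    alpha0, *_ = np.linalg.lstsq(va, logrv, rcond=None)
    cc = np.cov(coefs.T) if stats.J > 1 else np.eye(2)
    cc = np.atleast_2d(cc)
    if random_slope:
        t00 = max(cc[0, 0] * 0.5, 1e-3)
        t11 = max(cc[1, 1] * 0.5, 1e-3)
        start_T = np.array([0.5 * np.log(t00), 0.0, 0.5 * np.log(t11)])
    else:
        start_T = np.array([0.5 * np.log(max(cc[0, 0] * 0.5, 1e-3))])
    return np.concatenate([alpha0, start_T])


def _numerical_hessian(fun, x0, h=1e-4):
    k = len(x0)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = fun(x0 + ei + ej)
            fpm = fun(x0 + ei - ej)
            fmp = fun(x0 - ei + ej)
            fmm = fun(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit_mels(
    data: pd.DataFrame,
    design: GroupDesign,
    start: Optional[np.ndarray] = None,
    random_slope: bool = True,
    group_scale: bool = True,
    n_starts: int = 3,
    seed: int = 0,
    gtol: float = 1e-8,
) -> FreqFit:
    """Fit the location-scale model by full maximum likelihood.

    Fixed effects are profiled out by GLS; the optimizer runs over the
    log-variance coefficients and the log-Cholesky factor of the
    random-effects covariance, from ``n_starts`` deterministic starting
    points.  ``group_scale=False`` drops the group dummies from the variance
    model; ``random_slope=False`` constrains the slope deviation variance to
    zero (random-intercept model).
    """
    stats_ = _Stats(data, design)
    counts = pd.Series(stats_.groups).value_counts()
    if (counts < 2).any():
        raise ValueError(f"every group needs >= 2 persons; got {counts.to_dict()}")
    n_alpha = 1 + (design.n_dummies if group_scale else 0)
    n_T = 3 if random_slope else 1

    base = start if start is not None else _start_values(stats_, n_alpha, random_slope)
    base = np.asarray(base, float)
    if len(base) != n_alpha + n_T:
        raise ValueError(f"start must have length {n_alpha + n_T}")

    rng = np.random.default_rng(seed)
    starts = [base] + [base + rng.normal(scale=0.3, size=len(base)) for _ in range(max(n_starts - 1, 0))]

    def nll(theta):
        try:
            return _profiled_nll(theta, stats_, n_alpha, random_slope)[0]
        except (FloatingPointError, np.linalg.LinAlgError, OverflowError):
            return 1e12

    best = None
    trace: list[float] = []
    for x0 in starts:
        local_trace = [float(nll(x0))]
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            callback=lambda xk: local_trace.append(float(nll(xk))),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": gtol},
        )
        if best is None or res.fun < best[0].fun - 1e-10:
            best = (res, local_trace)
    res, trace = best
    theta = res.x
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success) or grad_norm < 1e-3
    if not converged:
        logger.warning("fit_mels: optimizer did not converge (%s)", res.message)

    nll_val, beta, XtVX = _profiled_nll(theta, stats_, n_alpha, random_slope)
    alpha = theta[:n_alpha]
    T = _theta_to_T(theta[n_alpha:], random_slope)
    boundary = bool(np.min(np.diag(T)[: (2 if random_slope else 1)]) < 1e-6)
    if boundary:
        logger.warning("fit_mels: random-effect variance near boundary (re_cov diag %s)", np.diag(T))

    vcov_beta = np.linalg.inv(XtVX)
    beta_se = np.sqrt(np.diag(vcov_beta))

    # SEs of the variance parameters from the observed information of the
    # profile likelihood (its Hessian is the Schur complement of the full
    # information, so this is the correct marginal covariance under ML).
    H = _numerical_hessian(nll, theta)
    try:
        theta_cov = np.linalg.inv(H)
        theta_se = np.sqrt(np.clip(np.diag(theta_cov), 0, None))
    except np.linalg.LinAlgError:
        theta_cov = np.full((len(theta), len(theta)), np.nan)
        theta_se = np.full(len(theta), np.nan)
    alpha_se = theta_se[:n_alpha]

    # delta method for the three unique re_cov entries
    def t_entries(th):
        Tm = _theta_to_T(th[n_alpha:], random_slope)
        return np.array([Tm[0, 0], Tm[0, 1], Tm[1, 1]])

    Jac = np.empty((3, len(theta)))
    h = 1e-5
    for j in range(len(theta)):
        e = np.zeros(len(theta)); e[j] = h
        Jac[:, j] = (t_entries(theta + e) - t_entries(theta - e)) / (2 * h)
    if np.all(np.isfinite(theta_cov)):
        tvar = np.clip(np.diag(Jac @ theta_cov @ Jac.T), 0, None)
        tse = np.sqrt(tvar)
    else:
        tse = np.full(3, np.nan)
    re_cov_se = np.array([[tse[0], tse[1]], [tse[1], tse[2]]])

    dummy = list(design.dummy_names)
    beta_names = (["homebase:intercept"] + [f"homebase:{d}" for d in dummy]
                  + ["autoreg:intercept"] + [f"autoreg:{d}" for d in dummy])
    alpha_names = ["logvar:intercept"] + ([f"logvar:{d}" for d in dummy] if group_scale else [])

    return FreqFit(
        design=design,
        beta=beta,
        beta_names=beta_names,
        beta_se=beta_se,
        vcov_beta=vcov_beta,
        alpha=alpha,
        alpha_names=alpha_names,
        alpha_se=alpha_se,
        re_cov=T,
        re_cov_se=re_cov_se,
        loglik=float(-nll_val),
        converged=converged,
        grad_norm=grad_norm,
        n_persons=stats_.J,
        n_obs=stats_.N,
        boundary=boundary,
        trace=trace,
        n_starts=len(starts),
    )


def wald_table(fit: FreqFit, J_per_equation: Optional[int] = None) -> pd.DataFrame:
    """Coefficient table with the publication df convention.

    Fixed-effect rows use t statistics on ``J - Q`` degrees of freedom where
    J is the number of persons in the analytic sample and Q the number of
    coefficients of that level-2 equation (intercept + dummies); variance
    rows use z statistics and print no df.
    """
    J = fit.n_persons if J_per_equation is None else int(J_per_equation)
    Q = 1 + fit.design.n_dummies
    df = J - Q
    rows = []
    half = len(fit.beta) // 2
    for block, names, est, se in (
        ("HOMEBASE", fit.beta_names[:half], fit.beta[:half], fit.beta_se[:half]),
        ("VARIANCE", fit.alpha_names, fit.alpha, fit.alpha_se),
        ("AUTOREGRESSIVE", fit.beta_names[half:], fit.beta[half:], fit.beta_se[half:]),
    ):
        for name, e, s in zip(names, est, se):
            stat = e / s if s > 0 else np.nan
            if block == "VARIANCE":
                p = 2 * stats.norm.sf(abs(stat))
                rows.append((block, name, e, s, stat, np.nan, p))
            else:
                p = 2 * stats.t.sf(abs(stat), df)
                rows.append((block, name, e, s, stat, df, p))
    order = ["HOMEBASE", "VARIANCE", "AUTOREGRESSIVE"]
    out = pd.DataFrame(rows, columns=["block", "name", "coeff", "se", "stat", "df", "p"])
    out["block"] = pd.Categorical(out["block"], categories=order, ordered=True)
    return out


def df_for_sample(group_sizes: Sequence[int], n_coefficients: int) -> int:
    """Degrees of freedom of a fixed-effect t test: persons minus coefficients."""
    return int(sum(group_sizes)) - int(n_coefficients)
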