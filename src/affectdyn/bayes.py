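"""Metropolis-within-Gibbs sampler for the location-scale model with
person-specific within-person variances.

Each person carries a (homebase, autoregressive slope, log within-person
variance) triplet drawn from a trivariate normal population whose mean is
group-specific and whose covariance is shared across groups.  Priors: vague
normals (mean 0, variance 1000) on the group-level means and deviations --
truncated to (-1, 1) for the autoregressive components -- and an
inverse-Wishart with identity scale and 4 degrees of freedom on the
population covariance.  The default chain protocol is four chains, 5000
burn-in iterations and 2500 kept iterations with no thinning.

Updates: (homebase, slope) pairs and all group-level means are conjugate
normal draws; person log-variances use an adaptive random-walk Metropolis
step (adaptation frozen at the end of burn-in); the population covariance is
a conjugate inverse-Wishart draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from affectdyn.freq import GroupDesign, _analysis_frame

logger = logging.getLogger(__name__)

COMPONENTS = ("homebase", "autoreg", "logvar")
_SLOPE = 1  # index of the autoregressive component in the triplet


@dataclass
class PriorSpec:
    """Priors for the hierarchical model."""

    fixed_effect_variance: float = 1000.0
    slope_truncation: tuple[float, float] = (-1.0, 1.0)
    wishart_scale: np.ndarray = field(default_factory=lambda: np.eye(3))
    wishart_df: float = 4.0

    def __post_init__(self) -> None:
        self.wishart_scale = np.asarray(self.wishart_scale, float)
        if self.fixed_effect_variance <= 0:
            raise ValueError("fixed_effect_variance must be > 0")
        lo, hi = self.slope_truncation
        if not lo < hi:
            raise ValueError("slope truncation bounds must be ordered")
        if self.wishart_scale.shape != (3, 3):
            raise ValueError("wishart_scale must be 3x3")
        if self.wishart_df < 3:
            raise ValueError("wishart_df must be >= dimension (3)")


@dataclass
class McmcConfig:
    """Chain protocol and proposal tuning."""

    n_chains: int = 4
    burn_in: int = 5000
    keep: int = 2500
    thin: int = 1
    seed: int = 0
    adapt_target: float = 0.4
    initial_step: float = 0.5
    # test hooks: hold parts of the model fixed to expose conjugate sub-models
    fixed_pop_cov: Optional[np.ndarray] = None
    fixed_person_log_var: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.keep < 1:
            raise ValueError("keep must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


class PosteriorDraws:
    """Kept draws indexed (chain, iteration, parameter).

    Group-level parameters come first (reference means, group deviations,
    population covariance entries), then the per-person triplets.  Use
    :meth:`to_frame` / :meth:`sel` for labeled access.
    """

    def __init__(self, array: np.ndarray, param_names: list[str], person_ids: list[str],
                 person_groups: list[str], design: GroupDesign,
                 acceptance: Optional[np.ndarray] = None):
        self.array = array
        self.param_names = list(param_names)
        self.person_ids = list(person_ids)
        self.person_groups = list(person_groups)
        self.design = design
        self.acceptance = acceptance
        self._index = {p: i for i, p in enumerate(self.param_names)}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_iterations(self) -> int:
        return self.array.shape[1]

    @property
    def group_level_names(self) -> list[str]:
        return [p for p in self.param_names if not p.startswith("person_")]

    def sel(self, parameter: str) -> np.ndarray:
        """(chain, iteration) slice of one parameter."""
        return self.array[:, :, self._index[parameter]]

    def flat(self, parameter: str) -> np.ndarray:
        return self.sel(parameter).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        C, n, P = self.array.shape
        frame = pd.DataFrame(self.array.reshape(C * n, P), columns=self.param_names)
        frame.insert(0, "iteration", np.tile(np.arange(n), C))
        frame.insert(0, "chain", np.repeat(np.arange(C), n))
        return frame

    def permute_chains(self, order: Sequence[int]) -> "PosteriorDraws":
        return PosteriorDraws(self.array[list(order)], self.param_names, self.person_ids,
                              self.person_groups, self.design, self.acceptance)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ConvergenceReport:
    psrf: pd.Series
    worst: float
    worst_parameter: str
    lag1_autocorr: pd.Series
    threshold: float = 1.1

    @property
    def passed(self) -> bool:
        return bool(self.worst < self.threshold)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "worst": self.worst,
            "worst_parameter": self.worst_parameter,
            "passed": self.passed,
            "psrf": self.psrf.to_dict(),
            "lag1_autocorr": self.lag1_autocorr.to_dict(),
        }


# ---------------------------------------------------------------------------
# sufficient statistics and parameter layout


class _BayesData:
    def __init__(self, frame: pd.DataFrame, design: GroupDesign):
        frame = _analysis_frame(frame)
        sort_cols = [col for col in ("day", "prompt_index") if col in frame.columns]
        ids, groups, A, b, c, n = [], [], [], [], [], []
        for pid, sub in frame.groupby("person_id", sort=True):
            if sort_cols:
                sub = sub.sort_values(sort_cols, kind="stable")
            y = sub["y"].to_numpy(float)
            x = sub["x"].to_numpy(float)
            if len(y) < 2:
                raise ValueError(f"person {pid!r} has fewer than 2 usable rows")
            ids.append(str(pid))
            groups.append(str(sub["group"].iloc[0]))
            A.append([[len(y), x.sum()], [x.sum(), x @ x]])
            b.append([y.sum(), x @ y])
            c.append(float(y @ y))
            n.append(float(len(y)))
        self.person_ids = ids
        self.groups = groups
        self.A = np.asarray(A)
        self.b = np.asarray(b)
        self.c = np.asarray(c)
        self.n = np.asarray(n)
        self.J = len(ids)
        # map person -> row of the group-mean lookup
        dummies = design.encode(groups) if self.J else np.zeros((0, design.n_dummies))
        self.dummies = dummies  # (J, K)


def _param_names(design: GroupDesign, person_ids: Sequence[str]) -> list[str]:
    names = [f"mean_{c}" for c in COMPONENTS]
    for d in design.dummy_names:
        names += [f"diff_{c}[{d}]" for c in COMPONENTS]
    names += [f"pop_cov[{i},{j}]" for i in range(3) for j in range(i, 3)]
    for pid in person_ids:
        names += [f"person_{c}[{pid}]" for c in COMPONENTS]
    return names


def _rss(theta12: np.ndarray, A, b, c) -> np.ndarray:
    """Residual sum of squares per person given (mu, phi)."""
    quad = np.einsum("ia,iab,ib->i", theta12, A, theta12)
    return c - 2 * np.einsum("ia,ia->i", theta12, b) + quad


def _sample_trunc_mvn(rng, mean, cov, trunc_idx, lo, hi, max_tries=200):
    """Multivariate normal draw restricted to lo < x[trunc_idx] < hi.

    Rejection from the unrestricted normal; if that fails (mass far outside
    the box) fall back to drawing the truncated coordinate from its marginal
    and the rest from the conditional distribution.
    """
    L = np.linalg.cholesky(cov)
    for _ in range(max_tries):
        x = mean + L @ rng.standard_normal(len(mean))
        if lo < x[trunc_idx] < hi:
            return x
    k = trunc_idx
    sd = np.sqrt(cov[k, k])
    a, bnd = (lo - mean[k]) / sd, (hi - mean[k]) / sd
    xk = sps.truncnorm.rvs(a, bnd, loc=mean[k], scale=sd, random_state=rng)
    idx = [i for i in range(len(mean)) if i != k]
    c12 = cov[np.ix_(idx, [k])].ravel()
    cond_mean = mean[idx] + c12 / cov[k, k] * (xk - mean[k])
    cond_cov = cov[np.ix_(idx, idx)] - np.outer(c12, c12) / cov[k, k]
    Lc = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(len(idx)))
    rest = cond_mean + Lc @ rng.standard_normal(len(idx))
    out = np.empty(len(mean))
    out[k] = xk
    out[idx] = rest
    return out


def _init_state(data: _BayesData, design: GroupDesign, rng, config: McmcConfig):
    """Data-driven initial state, jittered per chain for overdispersion."""
    theta = np.zeros((data.J, 3))
    for i in range(data.J):
        A, b, c, n = data.A[i], data.b[i], data.c[i], data.n[i]
        try:
            th = np.linalg.solve(A + 1e-8 * np.eye(2), b)
        except np.linalg.LinAlgError:
            th = np.array([b[0] / n, 0.0])
        th[1] = np.clip(th[1], -0.9, 0.9)
        rss = max(_rss(th[None], A[None], b[None], c[None])[0], 1e-3)
        theta[i] = [th[0], th[1], np.log(rss / max(n - 2, 1))]
    if config.fixed_person_log_var is not None:
        theta[:, 2] = np.asarray(config.fixed_person_log_var, float)

    K = design.n_dummies
    if data.J:
        ref_mask = data.dummies.sum(axis=1) == 0
        b0 = theta[ref_mask].mean(axis=0) if ref_mask.any() else theta.mean(axis=0)
        deltas = np.zeros((K, 3))
        for k in range(K):
            mask = data.dummies[:, k] == 1
            if mask.any():
                deltas[k] = theta[mask].mean(axis=0) - b0
    else:
        b0 = np.zeros(3)
        deltas = np.zeros((K, 3))
    b0 = b0 + rng.normal(scale=0.3, size=3)
    b0[_SLOPE] = np.clip(b0[_SLOPE], -0.9, 0.9)
    deltas = deltas + rng.normal(scale=0.3, size=deltas.shape)
    deltas[:, _SLOPE] = np.clip(deltas[:, _SLOPE], -0.9, 0.9)
    if data.J:
        theta = theta + rng.normal(scale=0.1, size=theta.shape)
        if config.fixed_person_log_var is not None:
            theta[:, 2] = np.asarray(config.fixed_person_log_var, float)

    if config.fixed_pop_cov is not None:
        Sigma = np.asarray(config.fixed_pop_cov, float)
    elif data.J > 3:
        Sigma = np.cov(theta.T) + 0.1 * np.eye(3)
    else:
        Sigma = np.eye(3)
    return theta, b0, deltas, Sigma


def _run_chain(data: _BayesData, design: GroupDesign, priors: PriorSpec,
               config: McmcConfig, seed) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed)
    J, K = data.J, design.n_dummies
    theta, b0, deltas, Sigma = _init_state(data, design, rng, config)
    step = np.full(J, config.initial_step)
    prior_prec = 1.0 / priors.fixed_effect_variance
    lo, hi = priors.slope_truncation
    n_kept_params = 3 * (1 + K) + 6 + 3 * J
    out = np.empty((config.keep, n_kept_params))
    total = config.burn_in + config.keep * config.thin
    n_acc = 0
    n_prop = 0

    has_pop_cov_update = config.fixed_pop_cov is None
    has_lv_update = config.fixed_person_log_var is None

    for it in range(total):
        Sigma_inv = np.linalg.inv(Sigma)
        m_g = b0[None] + data.dummies @ deltas if J else np.zeros((0, 3))

        if J:
            # --- conjugate (homebase, slope) update given log-variance ---
            s11 = Sigma[:2, :2]
            s12 = Sigma[:2, 2]
            s22 = Sigma[2, 2]
            cond_cov = s11 - np.outer(s12, s12) / s22
            cond_prec = np.linalg.inv(cond_cov)
            cond_mean = m_g[:, :2] + np.outer(theta[:, 2] - m_g[:, 2], s12 / s22)

            inv_s2 = np.exp(-theta[:, 2])
            P = cond_prec[None] + inv_s2[:, None, None] * data.A
            rhs = cond_mean @ cond_prec.T + inv_s2[:, None] * data.b
            detP = P[:, 0, 0] * P[:, 1, 1] - P[:, 0, 1] ** 2
            Pinv = np.empty_like(P)
            Pinv[:, 0, 0] = P[:, 1, 1]
            Pinv[:, 1, 1] = P[:, 0, 0]
            Pinv[:, 0, 1] = Pinv[:, 1, 0] = -P[:, 0, 1]
            Pinv /= detP[:, None, None]
            mean = np.einsum("iab,ib->ia", Pinv, rhs)
            # closed-form 2x2 Cholesky of the posterior covariance
            L11 = np.sqrt(Pinv[:, 0, 0])
            L21 = Pinv[:, 1, 0] / L11
            L22 = np.sqrt(np.clip(Pinv[:, 1, 1] - L21**2, 1e-300, None))
            z = rng.standard_normal((J, 2))
            theta[:, 0] = mean[:, 0] + L11 * z[:, 0]
            theta[:, 1] = mean[:, 1] + L21 * z[:, 0] + L22 * z[:, 1]

            # --- random-walk Metropolis on person log-variances ---
            if has_lv_update:
                diff12 = theta[:, :2] - m_g[:, :2]
                w = np.linalg.solve(s11, s12)
                lv_mean = m_g[:, 2] + diff12 @ w
                lv_var = s22 - s12 @ w
                cur = theta[:, 2]
                prop = cur + step * rng.standard_normal(J)
                rss = _rss(theta[:, :2], data.A, data.b, data.c)
                logp_cur = -0.5 * data.n * cur - 0.5 * np.exp(-cur) * rss \
                    - 0.5 * (cur - lv_mean) ** 2 / lv_var
                logp_prop = -0.5 * data.n * prop - 0.5 * np.exp(-prop) * rss \
                    - 0.5 * (prop - lv_mean) ** 2 / lv_var
                accept = np.log(rng.random(J)) < logp_prop - logp_cur
                theta[accept, 2] = prop[accept]
                n_acc += int(accept.sum())
                n_prop += J
                if it < config.burn_in:
                    gamma = min(0.25, 2.0 / np.sqrt(it + 1))
                    step *= np.exp(gamma * (accept.astype(float) - config.adapt_target))

        # --- conjugate group-level mean updates (slope coords truncated) ---
        if J:
            resid = theta - data.dummies @ deltas
            prec = J * Sigma_inv + prior_prec * np.eye(3)
            rhs = Sigma_inv @ resid.sum(axis=0)
        else:
            prec = prior_prec * np.eye(3)
            rhs = np.zeros(3)
        cov = np.linalg.inv(prec)
        b0 = _sample_trunc_mvn(rng, cov @ rhs, cov, _SLOPE, lo, hi)

        for k in range(K):
            mask = data.dummies[:, k] == 1 if J else np.zeros(0, bool)
            nk = int(mask.sum())
            if nk:
                prec = nk * Sigma_inv + prior_prec * np.eye(3)
                rhs = Sigma_inv @ (theta[mask] - b0[None]).sum(axis=0)
            else:
                prec = prior_prec * np.eye(3)
                rhs = np.zeros(3)
            cov = np.linalg.inv(prec)
            deltas[k] = _sample_trunc_mvn(rng, cov @ rhs, cov, _SLOPE, lo, hi)

        # --- conjugate inverse-Wishart update of the population covariance ---
        if has_pop_cov_update:
            if J:
                m_g = b0[None] + data.dummies @ deltas
                dev = theta - m_g
                S = priors.wishart_scale + dev.T @ dev
            else:
                S = priors.wishart_scale
            Sigma = sps.invwishart.rvs(df=priors.wishart_df + J, scale=S, random_state=rng)

        k_it = it - config.burn_in
        if k_it >= 0 and k_it % config.thin == 0:
            row = [b0]
            for k in range(K):
                row.append(deltas[k])
            tri = [Sigma[i, j] for i in range(3) for j in range(i, 3)]
            out[k_it // config.thin] = np.concatenate(row + [np.asarray(tri), theta.reshape(-1)])

    acc_rate = n_acc / n_prop if n_prop else np.nan
    return out, acc_rate


def run_mcmc(data: pd.DataFrame, design: GroupDesign,
             priors: Optional[PriorSpec] = None,
             config: Optional[McmcConfig] = None) -> PosteriorDraws:
    """Run the Metropolis-within-Gibbs sampler.

    ``data`` is the analysis-ready lagged frame (may be empty for a
    prior-only run).  Per-chain seeds are derived deterministically from
    ``config.seed``; acceptance rates of the log-variance step are logged.
    """
    priors = priors or PriorSpec()
    config = config or McmcConfig()
    bd = _BayesData(data, design) if len(data) else _BayesData(
        pd.DataFrame(columns=["person_id", "group", "y", "x"]), design)
    names = _param_names(design, bd.person_ids)

    draws = np.empty((config.n_chains, config.keep, len(names)))
    acc = np.empty(config.n_chains)
    for c in range(config.n_chains):
        chain_seed = np.random.SeedSequence([int(config.seed), c])
        draws[c], acc[c] = _run_chain(bd, design, priors, config, chain_seed)
        logger.info("chain %d: log-variance acceptance rate %.3f", c, acc[c])
    return PosteriorDraws(draws, names, bd.person_ids, bd.groups, design, acceptance=acc)


# ---------------------------------------------------------------------------
# diagnostics and summaries


def shrink_factor(draws: PosteriorDraws, parameter: str) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B the between-chain variance of the chain means, over kept iterations.
    """
    chains = draws.sel(parameter) if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    C, n = chains.shape
    if C < 2:
        raise ValueError("shrink factor needs >= 2 chains")
    if n < 10:
        raise ValueError("shrink factor needs >= 10 kept iterations")
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chains.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def split_shrink_factor(draws: PosteriorDraws, parameter: str) -> float:
    """Split-chain variant: each chain halved before the classic formula."""
    chains = draws.sel(parameter) if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    return shrink_factor(split, parameter)


def _lag1_autocorr(chains: np.ndarray) -> float:
    vals = []
    for ch in chains:
        ch = ch - ch.mean()
        denom = float(ch @ ch)
        if denom == 0:
            vals.append(0.0)
        else:
            vals.append(float(ch[:-1] @ ch[1:]) / denom)
    return float(np.mean(vals))


def convergence_report(draws: PosteriorDraws, parameters: Optional[Sequence[str]] = None,
                       threshold: float = 1.1) -> ConvergenceReport:
    """PSRF and chain-autocorrelation summary over the given parameters
    (defaults to all group-level parameters)."""
    params = list(parameters) if parameters is not None else draws.group_level_names
    psrf = pd.Series({p: shrink_factor(draws, p) for p in params})
    ac = pd.Series({p: _lag1_autocorr(draws.sel(p)) for p in params})
    worst = psrf.idxmax()
    return ConvergenceReport(psrf=psrf, worst=float(psrf.max()), worst_parameter=str(worst),
                             lag1_autocorr=ac, threshold=threshold)


def posterior_person_means(draws: PosteriorDraws, variance_scale: str = "variance") -> pd.DataFrame:
    """Per-person posterior means of the triplet, grouped by diagnosis.

    The within-person variance is averaged on the variance scale
    (mean of exp(log-variance) draws) by default; ``variance_scale="log"``
    averages the log-variance draws instead.
    """
    if variance_scale not in ("variance", "log"):
        raise ValueError("variance_scale must be 'variance' or 'log'")
    rows = []
    for pid, group in zip(draws.person_ids, draws.person_groups):
        hb = draws.flat(f"person_homebase[{pid}]").mean()
        ar = draws.flat(f"person_autoreg[{pid}]").mean()
        lv = draws.flat(f"person_logvar[{pid}]")
        wv = np.exp(lv).mean() if variance_scale == "variance" else lv.mean()
        rows.append({"person_id": pid, "group": group, "homebase": hb,
                     "within_variance": wv, "autocorrelation": ar})
    return pd.DataFrame(rows)


def group_contrast_summary(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """Posterior mean and central credible interval of each group deviation.

    ``supported`` flags contrasts whose central interval excludes zero (the
    declared decision rule for Bayesian corroboration of a frequentist
    result).
    """
    a = (1 - level) / 2
    rows = []
    for d in draws.design.dummy_names:
        for comp in COMPONENTS:
            vals = draws.flat(f"diff_{comp}[{d}]")
            lo, hi = np.quantile(vals, [a, 1 - a])
            rows.append({
                "contrast": d,
                "component": comp,
                "mean": float(vals.mean()),
                "lo": float(lo),
                "hi": float(hi),
                "supported": bool(lo > 0 or hi < 0),
            })
    return pd.DataFrame(rows)
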