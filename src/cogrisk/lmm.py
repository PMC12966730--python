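"""Linear mixed models for short panels, with participant-level weights.

The study design gives each participant at most two cognitive assessments,
so each participant's marginal covariance block is at most 2x2 and the
marginal (RE-integrated) likelihood has a cheap closed form:

    y_i = X_i beta + Z_i b_i + e_i,   b_i ~ N(0, Psi),  e_i ~ N(0, sigma^2 I)

with Z rows (1, t) for a random intercept + slope, or (1,) for a random
intercept only. Attrition weights enter as participant-level
pseudo-likelihood weights: loglik = sum_i w_i * loglik_i, the standard
survey-weighted ML for cluster-level weights. With all weights equal to one
this is exactly the unweighted ML/REML fit (cross-checked against
statsmodels MixedLM in the test suite).

Psi is parametrized through its Cholesky factor, so it stays positive
semi-definite during optimization; near-zero slope variance or |corr| -> 1
is reported via ``singular`` rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, DataError

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedFitResult:
    """Fixed effects, variance components and fit statistics of one model."""

    param_names: list[str]
    fe_params: np.ndarray
    fe_se: np.ndarray
    cov_fe: np.ndarray
    cov_re: np.ndarray          # 1x1 or 2x2 random-effect covariance
    sigma2: float               # residual variance
    llf: float
    aic: float
    k_params: int
    n_obs: int
    n_groups: int
    method: str                 # "ML" or "REML"
    random_slope: bool
    converged: bool
    singular: bool
    fell_back_to_intercept: bool = False
    optimizer_message: str = ""
    weighted: bool = False

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        zcrit = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.fe_params - zcrit * self.fe_se,
                                self.fe_params + zcrit * self.fe_se])

    def pvalues(self) -> np.ndarray:
        z = self.fe_params / self.fe_se
        return 2 * stats.norm.sf(np.abs(z))

    def summary_frame(self):
        import pandas as pd
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.param_names,
            "estimate": self.fe_params,
            "se": self.fe_se,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": self.pvalues(),
        })

    def __getitem__(self, term: str) -> float:
        return float(self.fe_params[self.param_names.index(term)])

    def se_of(self, term: str) -> float:
        return float(self.fe_se[self.param_names.index(term)])


class _Blocks:
    """Data rearranged into singleton and pair blocks, time-sorted."""

    def __init__(self, y, X, groups, times, weights):
        y = np.asarray(y, float)
        X = np.asarray(X, float)
        times = np.asarray(times, float)
        groups = np.asarray(groups)
        n = y.shape[0]
        if weights is None:
            weights = np.ones(n)
        else:
            weights = np.asarray(weights, float)
            if np.any(weights <= 0):
                raise DataError("weights must be positive")
        order = np.lexsort((times, groups))
        y, X, times, groups, weights = (a[order] for a in
                                        (y, X, times, groups, weights))
        uniq, start, counts = np.unique(groups, return_index=True,
                                        return_counts=True)
        if counts.max(initial=1) > 2:
            raise DataError("more than two observations for a participant")
        w_group = weights[start]
        # weights must be constant within participant
        if counts.max(initial=1) == 2:
            second = start[counts == 2] + 1
            if not np.allclose(weights[second], w_group[counts == 2]):
                raise DataError("weights must be constant within participant")
        s_idx = start[counts == 1]
        p_idx = start[counts == 2]
        self.n_obs = n
        self.n_groups = uniq.size
        self.p = X.shape[1]
        self.ys, self.Xs, self.ts = y[s_idx], X[s_idx], times[s_idx]
        self.ws = w_group[counts == 1]
        self.ya, self.yb = y[p_idx], y[p_idx + 1]
        self.Xa, self.Xb = X[p_idx], X[p_idx + 1]
        self.ta, self.tb = times[p_idx], times[p_idx + 1]
        self.wp = w_group[counts == 2]
        self.sum_w_obs = float(self.ws.sum() + 2 * self.wp.sum())
        self.weighted = not np.allclose(weights, 1.0)


def _variance_elements(blocks: _Blocks, psi, sigma2, random_slope):
    """Marginal covariance entries for all blocks under (Psi, sigma^2)."""
    p00 = psi[0, 0]
    p01 = psi[0, 1] if random_slope else 0.0
    p11 = psi[1, 1] if random_slope else 0.0

    def q(s, t):
        return p00 + (s + t) * p01 + s * t * p11

    vs = q(blocks.ts, blocks.ts) + sigma2
    v11 = q(blocks.ta, blocks.ta) + sigma2
    v12 = q(blocks.ta, blocks.tb)
    v22 = q(blocks.tb, blocks.tb) + sigma2
    return vs, v11, v12, v22


def _profile_beta(blocks: _Blocks, vs, v11, v12, v22):
    """Weighted GLS fixed effects given the variance elements."""
    det = v11 * v22 - v12 ** 2
    ia, ib, ic = v22 / det, -v12 / det, v11 / det
    A = np.zeros((blocks.p, blocks.p))
    rhs = np.zeros(blocks.p)
    if blocks.ys.size:
        ww = blocks.ws / vs
        A += np.einsum("m,mi,mj->ij", ww, blocks.Xs, blocks.Xs)
        rhs += ww @ (blocks.Xs * blocks.ys[:, None])
    if blocks.ya.size:
        w = blocks.wp
        xa, xb = blocks.Xa, blocks.Xb
        A += (np.einsum("m,mi,mj->ij", w * ia, xa, xa)
              + np.einsum("m,mi,mj->ij", w * ib, xa, xb)
              + np.einsum("m,mi,mj->ij", w * ib, xb, xa)
              + np.einsum("m,mi,mj->ij", w * ic, xb, xb))
        ca = w * (ia * blocks.ya + ib * blocks.yb)
        cb = w * (ib * blocks.ya + ic * blocks.yb)
        rhs += ca @ xa + cb @ xb
    beta = np.linalg.solve(A, rhs)
    return beta, A, (det, ia, ib, ic)


def _loglik_at(blocks: _Blocks, psi, sigma2, random_slope, reml):
    vs, v11, v12, v22 = _variance_elements(blocks, psi, sigma2, random_slope)
    if np.any(vs <= 0) or np.any(v11 * v22 - v12 ** 2 <= 0):
        return -np.inf, None, None
    try:
        beta, A, (det, ia, ib, ic) = _profile_beta(blocks, vs, v11, v12, v22)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    ll = 0.0
    if blocks.ys.size:
        rs = blocks.ys - blocks.Xs @ beta
        ll += -0.5 * np.sum(blocks.ws * (np.log(vs) + rs ** 2 / vs + _LOG2PI))
    if blocks.ya.size:
        ra = blocks.ya - blocks.Xa @ beta
        rb = blocks.yb - blocks.Xb @ beta
        quad = ia * ra ** 2 + 2 * ib * ra * rb + ic * rb ** 2
        ll += -0.5 * np.sum(blocks.wp * (np.log(det) + quad + 2 * _LOG2PI))
    if reml:
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf, None, None
        ll += -0.5 * logdet_A + 0.5 * blocks.p * _LOG2PI
    return ll, beta, A


def _unpack(theta, random_slope):
    log_sigma = theta[0]
    sigma2 = np.exp(2 * log_sigma)
    if random_slope:
        l00 = np.exp(theta[1])
        l10 = theta[2]
        l11 = np.exp(theta[3])
        psi = np.array([[l00 ** 2, l00 * l10],
                        [l00 * l10, l10 ** 2 + l11 ** 2]])
    else:
        l00 = np.exp(theta[1])
        psi = np.array([[l00 ** 2, 0.0], [0.0, 0.0]])
    return psi, sigma2


def fit_mixed_model(y, X, groups, times, weights=None, *,
                    random_slope: bool = True, reml: bool = True,
                    param_names: list[str] | None = None,
                    allow_intercept_fallback: bool = True) -> MixedFitResult:
    """Fit the mixed model by ML (``reml=False``) or REML.

    Falls back (flagged, never silent) to a random-intercept-only model when
    the slope variance is estimated at the boundary: two observations per
    participant barely identify it, and average fixed effects are the
    estimand of interest.
    """
    blocks = _Blocks(y, X, groups, times, weights)
    if param_names is None:
        param_names = [f"x{j}" for j in range(blocks.p)]

    # moment-based starting values from pooled OLS
    Xall = np.vstack([blocks.Xs, blocks.Xa, blocks.Xb]) if blocks.ys.size \
        else np.vstack([blocks.Xa, blocks.Xb])
    yall = np.concatenate([blocks.ys, blocks.ya, blocks.yb]) if blocks.ys.size \
        else np.concatenate([blocks.ya, blocks.yb])
    beta0, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    s2 = max(float(np.var(yall - Xall @ beta0)), 1e-8)
    t_scale = max(float(np.max(np.abs(np.concatenate(
        [blocks.ts, blocks.ta, blocks.tb])))), 1.0)

    def negll(theta):
        psi, sigma2 = _unpack(theta, random_slope)
        ll, _, _ = _loglik_at(blocks, psi, sigma2, random_slope, reml)
        return -ll if np.isfinite(ll) else 1e12

    starts = []
    base = [0.5 * np.log(0.5 * s2), 0.5 * np.log(0.45 * s2)]
    if random_slope:
        starts.append(base + [0.0, 0.5 * np.log(0.02 * s2 / t_scale ** 2)])
        starts.append(base + [0.0, 0.5 * np.log(0.2 * s2 / t_scale ** 2)])
    else:
        starts.append(base)
        starts.append([0.5 * np.log(0.9 * s2), 0.5 * np.log(0.05 * s2)])

    sd_log = 0.5 * np.log(s2)
    log_bounds = (sd_log - 12.0, sd_log + 6.0)
    bounds = [log_bounds, log_bounds]
    if random_slope:
        bounds += [(-np.exp(sd_log + 3), np.exp(sd_log + 3)), log_bounds]

    best = None
    for x0 in starts:
        gtol = 1e-8 * max(blocks.sum_w_obs / blocks.n_obs, 1.0)
        res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": gtol})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("mixed-model optimizer failed",
                               details={"message": getattr(best, "message", "")})

    psi, sigma2 = _unpack(best.x, random_slope)
    ll, beta, A = _loglik_at(blocks, psi, sigma2, random_slope, reml)
    if beta is None:
        raise ConvergenceError("variance estimate on an infeasible boundary",
                               details={"theta": best.x.tolist()})

    singular = False
    if random_slope:
        rel = psi[1, 1] * t_scale ** 2 / max(psi[0, 0] + sigma2, 1e-12)
        corr = psi[0, 1] / np.sqrt(max(psi[0, 0] * psi[1, 1], 1e-300))
        singular = rel < 1e-5 or abs(corr) > 0.999

    if singular and allow_intercept_fallback:
        import logging
        logging.getLogger(__name__).info(
            "singular random-slope covariance; refitting with random "
            "intercept only")
        out = fit_mixed_model(y, X, groups, times, weights,
                              random_slope=False, reml=reml,
                              param_names=param_names)
        out.fell_back_to_intercept = True
        out.singular = True
        return out

    cov_fe = np.linalg.inv(A)
    k_var = 4 if random_slope else 2
    k = blocks.p + k_var
    aic = 2 * k - 2 * ll
    cov_re = psi if random_slope else psi[:1, :1]
    return MixedFitResult(
        param_names=list(param_names),
        fe_params=beta, fe_se=np.sqrt(np.diag(cov_fe)), cov_fe=cov_fe,
        cov_re=cov_re, sigma2=float(sigma2),
        llf=float(ll), aic=float(aic), k_params=k,
        n_obs=blocks.n_obs, n_groups=blocks.n_groups,
        method="REML" if reml else "ML",
        random_slope=random_slope,
        converged=bool(best.success or best.fun < 1e11),
        singular=singular,
        optimizer_message=str(best.message),
        weighted=blocks.weighted)


def likelihood_ratio_test(fit_restricted: MixedFitResult,
                          fit_full: MixedFitResult) -> dict:
    """LRT and delta-AIC for nested ML fits on identical rows.

    A caveat applies when the tested parameters are variance components on
    the boundary of their space (the nominal chi-square reference is then
    conservative); callers comparing random-effect structures should read p
    with that in mind.
    """
    if fit_restricted.n_obs != fit_full.n_obs:
        raise DataError("model comparison requires identical rows")
    stat = 2.0 * (fit_full.llf - fit_restricted.llf)
    df = fit_full.k_params - fit_restricted.k_params
    p = float(stats.chi2.sf(max(stat, 0.0), df)) if df > 0 else float("nan")
    return {"lrt_stat": float(stat), "df": int(df), "p": p,
            "delta_aic": float(fit_full.aic - fit_restricted.aic),
            "boundary_caveat": fit_full.random_slope
            and not fit_restricted.random_slope}
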