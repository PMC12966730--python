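"""Inverse probability of attrition weighting.

A logistic model predicts attendance at the second cognitive visit from
baseline covariates (default: age, education, heart disease, depression,
diabetes, hypertension, stroke). Weights are the reciprocal of the
predicted attendance probability, truncated at the empirical 99th
percentile of the weight distribution to limit the influence of extreme
weights. Weights are meant for attendees; participants contributing only a
baseline row keep weight 1 in the longitudinal models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (ConfigError, DegenerateOutcomeError, SeparationError,
                     CogriskError)

DEFAULT_PARTICIPATION_COVARIATES = (
    "age_baseline", "education", "heart_disease", "depression",
    "diabetes", "hypertension", "stroke")


@dataclass
class ParticipationModel:
    covariates: list[str]
    params: pd.Series          # includes "const"
    bse: pd.Series
    llf: float
    aic: float
    n: int
    converged: bool

    def predict(self, cohort: pd.DataFrame) -> pd.Series:
        """Predicted attendance probability; NaN where a covariate is missing."""
        X = sm.add_constant(cohort[self.covariates].astype(float), has_constant="add")
        eta = X.to_numpy() @ self.params.reindex(X.columns).to_numpy()
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=cohort.index,
                         name="p_hat")

    def summary_dict(self) -> dict:
        return {"covariates": list(self.covariates),
                "coefficients": {k: float(v) for k, v in self.params.items()},
                "se": {k: float(v) for k, v in self.bse.items()},
                "aic": float(self.aic), "loglik": float(self.llf),
                "n": int(self.n)}


@dataclass
class IPWeights:
    p_hat: np.ndarray
    weight: np.ndarray
    truncated_weight: np.ndarray
    cap_value: float
    n_truncated: int
    index: np.ndarray | None = None

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"p_hat": self.p_hat, "weight": self.weight,
                            "truncated_weight": self.truncated_weight})
        if self.index is not None:
            out.insert(0, "id", self.index)
        return out


def fit_participation_model(cohort: pd.DataFrame,
                            covariates=DEFAULT_PARTICIPATION_COVARIATES
                            ) -> ParticipationModel:
    """ML logistic fit of attendance on baseline covariates (complete case)."""
    covariates = list(covariates)
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ConfigError(f"covariates not in cohort: {missing}")
    data = cohort[["attended_followup", *covariates]].dropna()
    y = data["attended_followup"].astype(float).to_numpy()
    if y.size == 0:
        raise DegenerateOutcomeError("no complete-case rows")
    if y.min() == y.max():
        raise DegenerateOutcomeError(
            "attendance has no variation (all "
            + ("attended" if y.min() == 1 else "missed") + ")")
    X = sm.add_constant(data[covariates].astype(float), has_constant="add")
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError
        if "separat" in str(exc).lower() or "Singular" in str(exc):
            raise SeparationError(str(exc)) from exc
        raise
    big = fit.params.abs() > 50
    if big.any():
        raise SeparationError(
            "quasi-separation: runaway coefficient(s) for "
            + ", ".join(fit.params.index[big]))
    if not fit.mle_retvals.get("converged", True):
        raise CogriskError("participation model did not converge")
    return ParticipationModel(covariates=covariates, params=fit.params,
                              bse=fit.bse, llf=float(fit.llf),
                              aic=float(fit.aic), n=int(y.size),
                              converged=True)


def compute_ipw(p_hat, truncation_quantile: float = 0.99,
                index=None) -> IPWeights:
    """Weights 1/p, capped at the given quantile of the weight distribution.

    The cap is the empirical quantile with linear interpolation; every weight
    above the cap (ties at the cap are already at it) is set to the cap.
    """
    p = np.asarray(p_hat, dtype=float)
    if p.size == 0:
        raise ConfigError("empty probability vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ConfigError("predicted probabilities must lie in (0, 1]")
    if not 0 < truncation_quantile <= 1:
        raise ConfigError("truncation quantile must be in (0, 1]")
    w = 1.0 / p
    cap = float(np.quantile(w, truncation_quantile))
    truncated = np.minimum(w, cap)
    return IPWeights(p_hat=p, weight=w, truncated_weight=truncated,
                     cap_value=cap, n_truncated=int(np.sum(w > cap)),
                     index=None if index is None else np.asarray(index))


def attrition_weights_for_cohort(cohort: pd.DataFrame,
                                 covariates=DEFAULT_PARTICIPATION_COVARIATES,
                                 truncation_quantile: float = 0.99
                                 ) -> tuple[pd.Series, ParticipationModel, IPWeights]:
    """Participant-level weight vector for the longitudinal models.

    Attendees get the truncated inverse probability of attendance;
    non-attendees (and attendees with unpredictable p, e.g. missing
    covariates) keep weight 1.
    """
    model = fit_participation_model(cohort, covariates)
    p_hat = model.predict(cohort)
    attendees = cohort["attended_followup"].to_numpy(bool) & p_hat.notna().to_numpy()
    ipw = compute_ipw(p_hat[attendees].to_numpy(),
                      truncation_quantile=truncation_quantile,
                      index=cohort.loc[attendees, "id"].to_numpy())
    weights = pd.Series(1.0, index=cohort.index, name="weight")
    weights[attendees] = ipw.truncated_weight
    return weights, model, ipw
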