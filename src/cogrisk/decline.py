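"""Binary cognitive decline: labels, logistic models, AUC and DeLong's test.

Decline is a drop of at least ``threshold`` raw MoCA points between the two
visits (default 3, roughly one SD of the MoCA distribution in older
community cohorts). Discrimination is the area under the ROC curve,
computed as the normalized Mann-Whitney statistic (ties get half credit),
with variance and paired comparisons from DeLong placement values --
implemented here rather than delegated, because AUC comparison is a
load-bearing result and is oracle-tested in-repo against brute-force pair
counting and a bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (CogriskError, ConfigError, DataError,
                     DegenerateOutcomeError, SeparationError)

DEFAULT_THRESHOLDS = (2, 3, 4, 6, 9)
DEFAULT_FLOOR_EXCLUSIONS = (18, 20, 22, 24)


def label_decline(cohort: pd.DataFrame, threshold: int = 3) -> pd.DataFrame:
    """Per-participant decline labels; only rows with both visits are labelled.

    declined <=> moca_visit1 - moca_visit2 >= threshold.
    """
    both = cohort["moca_visit1"].notna() & cohort["moca_visit2"].notna()
    n_excluded = int((~both).sum())
    if n_excluded:
        import logging
        logging.getLogger(__name__).info(
            "decline labels: %d participants without both visits excluded",
            n_excluded)
    sub = cohort.loc[both]
    delta = (sub["moca_visit1"].astype(int)
             - sub["moca_visit2"].astype(int)).to_numpy()
    return pd.DataFrame({"id": sub["id"].to_numpy(), "delta": delta,
                         "declined": delta >= threshold}, index=sub.index)


# -- logistic models ----------------------------------------------------------

@dataclass
class LogisticFit:
    param_names: list[str]
    params: np.ndarray
    se: np.ndarray
    conf_int: np.ndarray
    aic: float
    llf: float
    n: int
    linear_predictor: np.ndarray

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def se_of(self, name: str) -> float:
        return float(self.se[self.param_names.index(name)])


def fit_logistic(markers: pd.DataFrame | pd.Series | np.ndarray,
                 labels, weights=None) -> LogisticFit:
    """Weighted ML logistic regression of decline on marker column(s)."""
    if isinstance(markers, (pd.Series, np.ndarray, list)):
        markers = pd.DataFrame({"marker": np.asarray(markers, float)})
    y = np.asarray(labels, float)
    if y.size != len(markers):
        raise DataError("labels not aligned with markers")
    if y.min() == y.max():
        raise DegenerateOutcomeError("both outcome classes must be present")
    X = sm.add_constant(markers.astype(float), has_constant="add")
    kwargs = {}
    if weights is not None:
        kwargs["freq_weights"] = np.asarray(weights, float)
    model = sm.GLM(y, X, family=sm.families.Binomial(), **kwargs)
    try:
        fit = model.fit(maxiter=200)
    except Exception as exc:
        if "separat" in str(exc).lower():
            raise SeparationError(str(exc)) from exc
        raise
    if np.any(np.abs(fit.params.to_numpy()) > 50):
        raise SeparationError("quasi-separation: runaway logistic coefficient")
    ci = fit.conf_int().to_numpy()
    return LogisticFit(param_names=list(X.columns),
                       params=fit.params.to_numpy(),
                       se=fit.bse.to_numpy(), conf_int=ci,
                       aic=float(fit.aic), llf=float(fit.llf), n=int(y.size),
                       linear_predictor=np.asarray(
                           X.to_numpy() @ fit.params.to_numpy()))


# -- AUC / DeLong -------------------------------------------------------------

@dataclass
class AUCResult:
    auc: float
    variance: float
    ci: tuple[float, float]
    n_pos: int
    n_neg: int


@dataclass
class DeLongComparison:
    auc_a: float
    auc_b: float
    variance: float   # of the AUC difference, covariance-adjusted
    z: float
    p: float


def _placements(marker: np.ndarray, labels: np.ndarray):
    """Placement values: for each positive, the fraction of negatives below
    it (ties half); symmetrically for negatives. mean(V10) == AUC."""
    pos = marker[labels]
    neg = marker[~labels]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise DegenerateOutcomeError("AUC needs both classes")
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks handle ties
    r_pos, r_neg = ranks[:m], ranks[m:]
    v10 = (r_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m
    return v10, v01


def auc_mann_whitney(marker, labels) -> AUCResult:
    """AUC with DeLong variance; ties get half credit."""
    marker = np.asarray(marker, float)
    labels = np.asarray(labels, bool)
    if marker.size != labels.size:
        raise DataError("marker and labels differ in length")
    v10, v01 = _placements(marker, labels)
    m, n = v10.size, v01.size
    auc = float(np.mean(v10))
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return AUCResult(auc=auc, variance=var, ci=ci, n_pos=m, n_neg=n)


def delong_test(marker_a, marker_b, labels) -> DeLongComparison:
    """Paired DeLong comparison of two AUCs on the same labelled set."""
    marker_a = np.asarray(marker_a, float)
    marker_b = np.asarray(marker_b, float)
    labels = np.asarray(labels, bool)
    if marker_a.size != labels.size or marker_b.size != labels.size:
        raise DataError("markers and labels must be aligned (paired design)")
    va10, va01 = _placements(marker_a, labels)
    vb10, vb01 = _placements(marker_b, labels)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(np.mean(va10)), float(np.mean(vb10))

    def cov(u, v):
        return float(np.cov(u, v, ddof=1)[0, 1]) if u.size > 1 else 0.0

    var_diff = (cov(va10, va10) + cov(vb10, vb10) - 2 * cov(va10, vb10)) / m \
        + (cov(va01, va01) + cov(vb01, vb01) - 2 * cov(va01, vb01)) / n
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        if abs(diff) < 1e-12:
            return DeLongComparison(auc_a=auc_a, auc_b=auc_b, variance=0.0,
                                    z=0.0, p=1.0)
        raise CogriskError("degenerate DeLong variance with unequal AUCs")
    z = diff / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, variance=float(var_diff),
                            z=float(z), p=p)


# -- sensitivity grid ---------------------------------------------------------

def run_sensitivity_grid(cohort: pd.DataFrame,
                         markers: dict[str, pd.Series | np.ndarray],
                         thresholds=DEFAULT_THRESHOLDS,
                         floor_exclusions=(None, *DEFAULT_FLOOR_EXCLUSIONS)
                         ) -> pd.DataFrame:
    """AUC per (decline threshold, baseline floor exclusion, marker) cell.

    Floor exclusion ``f`` drops participants with baseline MoCA below ``f``
    (guarding against floor effects); ``None`` keeps everyone. Cells where a
    class is empty are reported not-estimable rather than raised.
    """
    markers = {name: pd.Series(np.asarray(v, float), index=cohort.index)
               for name, v in markers.items()}
    rows = []
    for floor in floor_exclusions:
        if floor is None:
            keep = pd.Series(True, index=cohort.index)
        else:
            keep = cohort["moca_visit1"].notna() & (cohort["moca_visit1"] >= floor)
        sub = cohort.loc[keep]
        for thr in thresholds:
            labels = label_decline(sub, threshold=thr)
            n_inc = len(labels)
            n_dec = int(labels["declined"].sum())
            for name, series in markers.items():
                vals = series.loc[labels.index]
                ok = vals.notna()
                lab = labels.loc[ok, "declined"].to_numpy()
                estimable = lab.size > 0 and 0 < lab.sum() < lab.size
                if estimable:
                    res = auc_mann_whitney(vals[ok].to_numpy(), lab)
                    auc, lo, hi = res.auc, res.ci[0], res.ci[1]
                else:
                    auc = lo = hi = np.nan
                rows.append({"floor_exclusion": np.nan if floor is None else floor,
                             "threshold": thr, "marker": name,
                             "n_included": n_inc, "n_declined": n_dec,
                             "estimable": estimable,
                             "auc": auc, "auc_lo": lo, "auc_hi": hi})
    return pd.DataFrame(rows)
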