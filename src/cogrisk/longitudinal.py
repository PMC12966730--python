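"""Person-period tables and mixed-effects models of MoCA level and change.

One row per available cognitive visit: time is years since the first visit
(0 at visit 1, the follow-up interval at visit 2); participants who missed
the second visit contribute their baseline row only. The models estimate

* the expected baseline MoCA at the reference level of the score,
* the score main effect (per 1 SD, or per tertile vs the low group),
* the common time slope (MoCA points/year), and
* the time x score interaction -- the additional annual change per score
  unit, the quantity of interest for "does the score predict decline".

Moderation models add age-group (under/over 65 at risk assessment) and sex
terms up to the three-way interactions needed for group-specific score
slopes; they are meant for demographics-stripped scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .lmm import MixedFitResult, fit_mixed_model, likelihood_ratio_test

TERTILE_DUMMIES = ("score_medium", "score_high")


def build_long_table(cohort: pd.DataFrame, scores, form: str = "continuous",
                     weights: pd.Series | np.ndarray | None = None,
                     moderators: bool = False,
                     age_cut: float = 65.0) -> pd.DataFrame:
    """Stack the two visits into a person-period table.

    ``scores`` is a per-participant vector aligned with ``cohort`` (z-scores
    for ``form="continuous"``, tertile labels low/medium/high for
    ``form="tertile"``). Participants with a missing score are excluded.
    """
    if form not in ("continuous", "tertile"):
        raise ConfigError(f"unknown form {form!r}")
    scores = np.asarray(scores if not hasattr(scores, "to_numpy")
                        else scores.to_numpy())
    if len(scores) != len(cohort):
        raise DataError("scores not aligned with cohort")
    if weights is None:
        weights = np.ones(len(cohort))
    else:
        weights = np.asarray(weights, float)

    has_v1 = cohort["moca_visit1"].notna().to_numpy()
    has_v2 = cohort["moca_visit2"].notna().to_numpy()
    if np.any(has_v2 & ~has_v1):
        raise DataError("participant with a follow-up visit but no baseline visit")
    if form == "continuous":
        score_ok = np.isfinite(scores.astype(float))
    else:
        score_ok = pd.notna(scores)
    include = has_v1 & score_ok

    def visit_rows(mask, visit):
        sub = cohort.loc[mask]
        rows = pd.DataFrame({
            "id": sub["id"].to_numpy(),
            "time": np.zeros(mask.sum()) if visit == 1
            else sub["followup_years"].to_numpy(float),
            "moca": (sub["moca_visit1"] if visit == 1
                     else sub["moca_visit2"]).to_numpy(float),
            "weight": weights[mask],
        })
        if form == "continuous":
            rows["score_z"] = scores[mask].astype(float)
        else:
            lab = scores[mask]
            rows["score_medium"] = (lab == "medium").astype(float)
            rows["score_high"] = (lab == "high").astype(float)
        if moderators:
            rows["age_ge65"] = (sub["age_baseline"].to_numpy(float)
                                >= age_cut).astype(float)
            rows["male"] = (sub["sex"].to_numpy() == "male").astype(float)
        return rows

    table = pd.concat([visit_rows(include, 1),
                       visit_rows(include & has_v2, 2)], ignore_index=True)
    table = table.sort_values(["id", "time"], kind="mergesort",
                              ignore_index=True)
    if np.any(table.loc[table["time"] > 0, "time"] <= 0):
        raise DataError("non-positive follow-up time")
    return table


def _design(table: pd.DataFrame, score_cols: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for c in score_cols:
        cols.append(table[c].to_numpy(float))
        names.append(c)
    cols.append(table["time"].to_numpy(float))
    names.append("time")
    for c in score_cols:
        cols.append(table[c].to_numpy(float) * table["time"].to_numpy(float))
        names.append(f"time:{c}")
    return np.column_stack(cols), names


def _score_cols(table: pd.DataFrame) -> list[str]:
    if "score_z" in table.columns:
        return ["score_z"]
    return [c for c in TERTILE_DUMMIES if c in table.columns]


def fit_lmm(table: pd.DataFrame, *, reml: bool = True,
            random_slope: bool = True, use_weights: bool = True,
            min_pairs: int = 50) -> MixedFitResult:
    """Fit MoCA ~ score * time with random intercepts (and slopes).

    REML by default; pass ``reml=False`` when the fit will enter a
    likelihood-ratio comparison of fixed effects.
    """
    pairs = int(table["id"].value_counts().eq(2).sum())
    if random_slope and pairs < min_pairs:
        raise DataError(
            f"only {pairs} participants with two visits; slope variance "
            f"needs at least {min_pairs}")
    X, names = _design(table, _score_cols(table))
    w = table["weight"].to_numpy(float) if use_weights else None
    return fit_mixed_model(table["moca"].to_numpy(float), X,
                           table["id"].to_numpy(), table["time"].to_numpy(float),
                           w, random_slope=random_slope, reml=reml,
                           param_names=names)


def fit_lmm_moderation(table: pd.DataFrame, *, reml: bool = True,
                       random_slope: bool = True) -> MixedFitResult:
    """Score x time model with age-group and sex moderation.

    Uses the separate-moderator expansion: every term of
    ``(1 + score) * (1 + time)`` is crossed with each moderator, giving the
    three-way ``time:score:moderator`` terms that express group-specific
    score slopes. Intended for tables built from demographics-stripped
    scores (the score itself then carries no age/sex content).
    """
    for col in ("age_ge65", "male"):
        if col not in table.columns:
            raise ConfigError("table was built without moderators")
    base = table.drop_duplicates("id")
    for a in (0.0, 1.0):
        for m in (0.0, 1.0):
            cell = ((base["age_ge65"] == a) & (base["male"] == m)).sum()
            if cell == 0:
                raise DataError(
                    f"empty moderator cell: age_ge65={int(a)}, male={int(m)}")
    score_cols = _score_cols(table)
    t = table["time"].to_numpy(float)
    cols, names = [np.ones(len(table))], ["intercept"]

    def add(name, values):
        cols.append(values)
        names.append(name)

    for c in score_cols:
        add(c, table[c].to_numpy(float))
    add("time", t)
    for c in score_cols:
        add(f"time:{c}", table[c].to_numpy(float) * t)
    for mod in ("age_ge65", "male"):
        m = table[mod].to_numpy(float)
        add(mod, m)
        for c in score_cols:
            add(f"{c}:{mod}", table[c].to_numpy(float) * m)
        add(f"time:{mod}", t * m)
        for c in score_cols:
            add(f"time:{c}:{mod}", table[c].to_numpy(float) * t * m)
    X = np.column_stack(cols)
    return fit_mixed_model(table["moca"].to_numpy(float), X,
                           table["id"].to_numpy(), t,
                           table["weight"].to_numpy(float),
                           random_slope=random_slope, reml=reml,
                           param_names=names)


def compare_models(fit_restricted: MixedFitResult,
                   fit_full: MixedFitResult) -> dict:
    """Likelihood-ratio test and delta-AIC for nested fits on the same rows."""
    return likelihood_ratio_test(fit_restricted, fit_full)
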