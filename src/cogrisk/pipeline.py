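"""End-to-end seeded runs: simulate -> score -> weight -> mixed models ->
decline classification -> sensitivity grids, with paper-shaped outputs.

Every number in the emitted report comes from a stage output collected here;
the markdown formatter only formats. Runs are deterministic for a fixed
configuration: two runs with the same config produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .cohort import SimConfig, generate_cohort, read_cohort_csv, write_cohort_csv
from .decline import (auc_mann_whitney, delong_test, fit_logistic,
                      label_decline, run_sensitivity_grid)
from .errors import CogriskError, ConfigError
from .ipw import attrition_weights_for_cohort
from .longitudinal import build_long_table, fit_lmm, fit_lmm_moderation
from .scoring import (ScoreDefinition, assign_tertiles, compute_scores_frame,
                      load_bundled_definitions, strip_demographics, zscore)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimConfig | None = None
    cohort_csv: str | None = None
    score_definitions: dict[str, ScoreDefinition] | None = None  # None = bundled
    use_ipw: bool = True
    complete_case: bool = False
    strip_demographics_variant: bool = True
    decline_threshold: int = 3
    sensitivity: bool = True
    moderation: bool = True
    longitudinal: bool = True
    out_dir: str | None = None

    def __post_init__(self):
        if self.sim is None and self.cohort_csv is None:
            self.sim = SimConfig()
        if self.sim is not None and self.cohort_csv is not None:
            raise ConfigError("give either a SimConfig or a cohort CSV, not both")

    def config_hash(self) -> str:
        payload = {
            "sim": self.sim.to_yaml() if self.sim else None,
            "cohort_csv": self.cohort_csv,
            "scores": sorted(self.score_definitions) if self.score_definitions
            else "bundled",
            "use_ipw": self.use_ipw,
            "complete_case": self.complete_case,
            "strip": self.strip_demographics_variant,
            "threshold": self.decline_threshold,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _analysis_scores(cohort: pd.DataFrame,
                     definitions: dict[str, ScoreDefinition]) -> pd.DataFrame:
    """Per-participant prorated scores, z and tertiles for every index.

    Standardization and tertile cutpoints use the full baseline analysis
    sample (everyone with a first cognitive assessment and a scorable
    profile) and are reused for subsamples.
    """
    baseline = cohort["moca_visit1"].notna()
    pieces = {}
    for key, defn in definitions.items():
        frame = compute_scores_frame(cohort, defn)
        scored = frame["prorated"].notna() & baseline
        z = pd.Series(np.nan, index=cohort.index)
        tert = pd.Series(pd.NA, index=cohort.index, dtype=object)
        if scored.sum() >= 3:
            std = assign_tertiles(frame.loc[scored, "prorated"].to_numpy())
            zs = zscore(frame.loc[scored, "prorated"].to_numpy())
            z[scored] = zs.z
            tert[scored] = std.tertile
        pieces[key] = pd.DataFrame({
            f"{key}_raw": frame["raw"], f"{key}_prorated": frame["prorated"],
            f"{key}_complete": frame["complete"], f"{key}_z": z,
            f"{key}_tertile": tert})
    out = pd.concat(pieces.values(), axis=1)
    out.insert(0, "id", cohort["id"].to_numpy())
    return out


def summarize_cohort(cohort: pd.DataFrame, scores: pd.DataFrame | None = None
                     ) -> pd.DataFrame:
    """Descriptives by follow-up status with returner/non-returner tests.

    Continuous rows get mean (SD) [min-max] and a Welch t-test; binary rows
    get n (%) and a chi-squared test. Degenerate groups yield NaN statistics
    rather than errors.
    """
    att = cohort["attended_followup"].to_numpy(bool)
    rows = []

    def cont_row(name, values):
        values = pd.to_numeric(pd.Series(np.asarray(values, dtype=float)),
                               errors="coerce")
        a, b = values[att].dropna(), values[~att].dropna()
        if len(a) > 1 and len(b) > 1:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        else:
            t, p = np.nan, np.nan
        rows.append({"variable": name, "kind": "continuous",
                     "total_mean": values.mean(), "total_sd": values.std(ddof=1),
                     "total_min": values.min(), "total_max": values.max(),
                     "returners_mean": a.mean() if len(a) else np.nan,
                     "nonreturners_mean": b.mean() if len(b) else np.nan,
                     "stat": t, "p": p})

    def binary_row(name, values):
        values = np.asarray(values, dtype=float)
        ok = np.isfinite(values)
        a, b = values[att & ok], values[~att & ok]
        if len(a) and len(b) and 0 < values[ok].mean() < 1:
            tab = np.array([[a.sum(), len(a) - a.sum()],
                            [b.sum(), len(b) - b.sum()]])
            if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
                chi2, p = sps.chi2_contingency(tab)[:2]
            else:
                chi2, p = np.nan, np.nan
        else:
            chi2, p = np.nan, np.nan
        rows.append({"variable": name, "kind": "binary",
                     "total_mean": values[ok].mean() if ok.any() else np.nan,
                     "total_sd": np.nan, "total_min": np.nan, "total_max": np.nan,
                     "returners_mean": a.mean() if len(a) else np.nan,
                     "nonreturners_mean": b.mean() if len(b) else np.nan,
                     "stat": chi2, "p": p})

    cont_row("age_baseline", cohort["age_baseline"])
    cont_row("education", cohort["education"])
    binary_row("female", (cohort["sex"] == "female").astype(float))
    cont_row("moca_visit1", cohort["moca_visit1"].astype("Float64"))
    if cohort["moca_visit2"].notna().any():
        cont_row("moca_visit2", cohort["moca_visit2"].astype("Float64"))
    if scores is not None:
        for col in scores.columns:
            if col.endswith("_prorated"):
                cont_row(col.replace("_prorated", ""), scores[col])
    return pd.DataFrame(rows)


def _lmm_rows(fitres, score_key, form, model):
    rows = []
    ci = fitres.conf_int()
    p = fitres.pvalues()
    for i, term in enumerate(fitres.param_names):
        rows.append({"score": score_key, "form": form, "model": model,
                     "term": term, "estimate": fitres.fe_params[i],
                     "se": fitres.fe_se[i], "ci_low": ci[i, 0],
                     "ci_high": ci[i, 1], "p": p[i],
                     "aic": fitres.aic, "loglik": fitres.llf,
                     "n_participants": fitres.n_groups,
                     "n_rows": fitres.n_obs,
                     "random_slope": fitres.random_slope,
                     "singular": fitres.singular})
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the result bundle and optionally writes it."""
    stage = "setup"
    try:
        definitions = config.score_definitions or load_bundled_definitions()

        stage = "simulate"
        if config.sim is not None:
            cohort = generate_cohort(config.sim)
        else:
            cohort = read_cohort_csv(config.cohort_csv)

        stage = "score"
        scores = _analysis_scores(cohort, definitions)
        stripped_defs = {k: strip_demographics(d) for k, d in definitions.items()}
        stripped_defs = {k: d for k, d in stripped_defs.items() if d.items}
        scores_stripped = _analysis_scores(cohort, stripped_defs)

        if config.complete_case:
            complete_cols = [c for c in scores.columns if c.endswith("_complete")]
            keep = scores[complete_cols].all(axis=1).to_numpy()
            log.info("complete-case analysis: keeping %d of %d participants",
                     int(keep.sum()), len(cohort))
            cohort = cohort.loc[keep].reset_index(drop=True)
            scores = _analysis_scores(cohort, definitions)
            scores_stripped = _analysis_scores(cohort, stripped_defs)

        stage = "weights"
        if config.use_ipw:
            weights, part_model, ipw = attrition_weights_for_cohort(cohort)
            weight_summary = {"participation_model": part_model.summary_dict(),
                              "cap_value": ipw.cap_value,
                              "n_truncated": ipw.n_truncated,
                              "mean_weight_attendees":
                                  float(np.mean(ipw.truncated_weight))}
            ipw_frame = ipw.frame()
        else:
            weights = pd.Series(1.0, index=cohort.index)
            weight_summary = {"participation_model": None, "cap_value": None,
                              "n_truncated": 0, "mean_weight_attendees": 1.0}
            ipw_frame = pd.DataFrame(columns=["id", "p_hat", "weight",
                                              "truncated_weight"])

        stage = "lmm"
        lmm_rows = []
        for key in (definitions if config.longitudinal else ()):
            z = scores[f"{key}_z"]
            table = build_long_table(cohort, z, form="continuous",
                                     weights=weights)
            lmm_rows += _lmm_rows(fit_lmm(table), key, "continuous", "with_demographics")
            tert = scores[f"{key}_tertile"]
            table_t = build_long_table(cohort, tert, form="tertile",
                                       weights=weights)
            lmm_rows += _lmm_rows(fit_lmm(table_t), key, "tertile", "with_demographics")
        if config.strip_demographics_variant and config.longitudinal:
            for key in stripped_defs:
                z = scores_stripped[f"{key}_z"]
                table = build_long_table(cohort, z, form="continuous",
                                         weights=weights)
                lmm_rows += _lmm_rows(fit_lmm(table), key, "continuous",
                                      "without_demographics")
        lmm_frame = pd.DataFrame(lmm_rows)

        stage = "moderation"
        moderation_rows = []
        if config.moderation and config.longitudinal:
            for key in stripped_defs:
                z = scores_stripped[f"{key}_z"]
                table = build_long_table(cohort, z, form="continuous",
                                         weights=weights, moderators=True)
                fit = fit_lmm_moderation(table)
                moderation_rows += _lmm_rows(fit, key, "continuous", "moderation")
        moderation_frame = pd.DataFrame(moderation_rows)

        stage = "classify"
        labels = label_decline(cohort, threshold=config.decline_threshold)
        lab_idx = labels.index
        y = labels["declined"].to_numpy()
        w_lab = weights.loc[lab_idx].to_numpy()
        demo = cohort.loc[lab_idx, ["age_baseline", "education"]].astype(float)
        demo.columns = ["age", "education"]
        class_rows = []
        demo_fit = fit_logistic(demo, y, w_lab)
        demo_auc = auc_mann_whitney(demo_fit.linear_predictor, y)
        class_rows.append({
            "marker": "demographics_only", "model": "with_demographics",
            "coefficient": demo_fit.coef("age"), "ci_low": demo_fit.conf_int[1, 0],
            "ci_high": demo_fit.conf_int[1, 1], "aic": demo_fit.aic,
            "auc": demo_auc.auc, "auc_lo": demo_auc.ci[0],
            "auc_hi": demo_auc.ci[1], "delong_p_vs_demographics": np.nan,
            "n": demo_fit.n})
        for variant, score_frame, defs in (
                ("with_demographics", scores, definitions),
                ("without_demographics", scores_stripped, stripped_defs)):
            if variant == "without_demographics" and not config.strip_demographics_variant:
                continue
            for key in defs:
                z = score_frame.loc[lab_idx, f"{key}_z"]
                ok = z.notna().to_numpy()
                fitl = fit_logistic(z[ok].to_numpy(), y[ok], w_lab[ok])
                auc = auc_mann_whitney(z[ok].to_numpy(), y[ok])
                demo_lp = pd.Series(demo_fit.linear_predictor, index=lab_idx)
                dl = delong_test(z[ok].to_numpy(), demo_lp[ok].to_numpy(), y[ok])
                class_rows.append({
                    "marker": key, "model": variant,
                    "coefficient": fitl.coef("marker"),
                    "ci_low": fitl.conf_int[1, 0], "ci_high": fitl.conf_int[1, 1],
                    "aic": fitl.aic, "auc": auc.auc, "auc_lo": auc.ci[0],
                    "auc_hi": auc.ci[1], "delong_p_vs_demographics": dl.p,
                    "n": fitl.n})
        class_frame = pd.DataFrame(class_rows)

        stage = "sensitivity"
        if config.sensitivity:
            markers = {k: scores[f"{k}_z"] for k in definitions}
            grid = run_sensitivity_grid(cohort, markers)
        else:
            grid = pd.DataFrame()

        stage = "report"
        descriptives = summarize_cohort(cohort, scores)
        bundle = {
            "config_hash": config.config_hash(),
            "seed": config.sim.seed if config.sim else None,
            "version": __version__,
            "cohort": cohort, "scores": scores,
            "scores_stripped": scores_stripped,
            "weights": weights, "ipw": ipw_frame,
            "weight_summary": weight_summary,
            "descriptives": descriptives,
            "lmm": lmm_frame, "moderation": moderation_frame,
            "classification": class_frame, "sensitivity_grid": grid,
        }
        if config.out_dir is not None:
            write_outputs(bundle, Path(config.out_dir))
        return bundle
    except CogriskError as exc:
        raise CogriskError(f"[stage={stage}] {exc}") from exc


FLOAT_FMT = "%.10g"


def write_outputs(bundle: dict, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(bundle["cohort"], out_dir / "cohort.csv")
    for name in ("scores", "scores_stripped", "ipw", "descriptives", "lmm",
                 "moderation", "classification", "sensitivity_grid"):
        bundle[name].to_csv(out_dir / f"{name}.csv", index=False,
                            float_format=FLOAT_FMT)
    run_info = {"config_hash": bundle["config_hash"], "seed": bundle["seed"],
                "version": bundle["version"],
                "weight_summary": bundle["weight_summary"]}
    (out_dir / "run.json").write_text(
        json.dumps(run_info, indent=2, sort_keys=True, default=float) + "\n")
    (out_dir / "report.md").write_text(render_report(bundle))


def _fmt(x, nd=2):
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) \
        else f"{x:.{nd}f}"


def _stars(p):
    if not np.isfinite(p):
        return ""
    return "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else ""


def render_report(bundle: dict) -> str:
    """Markdown run report shaped like the study's result tables."""
    lines = ["# Risk-score comparison run report", "",
             f"- config hash: `{bundle['config_hash']}`",
             f"- seed: {bundle['seed']}",
             f"- package version: {bundle['version']}", ""]
    coh = bundle["cohort"]
    att = coh["attended_followup"].mean()
    lines += ["## Cohort", "",
              f"- participants: {len(coh)}",
              f"- follow-up attendance: {att:.1%}", ""]
    lmm = bundle["lmm"]
    if len(lmm):
        lines += ["## Mixed models (continuous z-scores, with demographics)", "",
                  "| score | baseline MoCA | score (z) | time x score (z) |",
                  "|---|---|---|---|"]
        sub = lmm[(lmm["form"] == "continuous")
                  & (lmm["model"] == "with_demographics")]
        for key in sub["score"].unique():
            s = sub[sub["score"] == key].set_index("term")
            def cell(term):
                if term not in s.index:
                    return "NA"
                r = s.loc[term]
                return (f"{_fmt(r['estimate'])}{_stars(r['p'])} "
                        f"[{_fmt(r['ci_low'])}, {_fmt(r['ci_high'])}]")
            lines.append(f"| {key} | {cell('intercept')} | {cell('score_z')} "
                         f"| {cell('time:score_z')} |")
        lines.append("")
    cls = bundle["classification"]
    if len(cls):
        lines += ["## Binary decline classification", "",
                  "| marker | model | coef | AIC | AUC [95% CI] | DeLong p vs demographics |",
                  "|---|---|---|---|---|---|"]
        for _, r in cls.iterrows():
            lines.append(
                f"| {r['marker']} | {r['model']} | {_fmt(r['coefficient'])} "
                f"| {_fmt(r['aic'], 1)} | {_fmt(r['auc'], 3)} "
                f"[{_fmt(r['auc_lo'], 3)}, {_fmt(r['auc_hi'], 3)}] "
                f"| {_fmt(r['delong_p_vs_demographics'], 4)} |")
        lines.append("")
    ws = bundle["weight_summary"]
    lines += ["## Attrition weights", "",
              f"- mean truncated weight (attendees): "
              f"{_fmt(ws['mean_weight_attendees'], 3)}",
              f"- weights truncated at cap: {ws['n_truncated']}", ""]
    return "\n".join(lines)
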