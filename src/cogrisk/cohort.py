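"""Seeded synthetic two-visit cohorts with the structure the analyses assume.

The generator emulates a population-based ageing cohort: risk factors are
measured once at baseline, global cognition (MoCA, integer 0-30) is measured
at two later visits roughly four years apart, attendance at the second visit
depends on age and health, and risk-factor items have item-level missingness.

A latent "true risk" burden -- a fixed linear combination of the generated
risk items -- drives both the level of cognition and its annual rate of
change, so parameter-recovery tests downstream know the generative truth
exactly.

All randomness flows from a single integer seed expanded into independent
per-stage substreams (demographics, items, trajectories, follow-up timing,
attrition, missingness), so each stage is individually reproducible.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigError

log = logging.getLogger(__name__)

#: binary risk-factor prevalences at baseline (probability of "present").
DEFAULT_PREVALENCES: dict[str, float] = {
    "diabetes": 0.09,
    "hypertension": 0.45,
    "smoking": 0.15,
    "depression": 0.10,
    "heart_disease": 0.12,
    "stroke": 0.05,
    "hearing_loss": 0.20,
    "social_isolation": 0.15,
    "physical_inactivity": 0.30,
    "high_alcohol": 0.05,
    "head_injury": 0.08,
    "kidney_disease": 0.04,
    "vision_loss": 0.10,
    "apoe4": 0.27,
    "family_history": 0.25,
    "living_alone": 0.25,
    "deprivation": 0.15,
    "low_cognitive_activity": 0.30,
    "poor_diet": 0.35,
    "poor_sleep": 0.20,
    "low_fish_intake": 0.30,
    "air_pollution": 0.30,
}

#: continuous risk measures: name -> (mean, sd, lower clip, upper clip)
DEFAULT_CONTINUOUS: dict[str, tuple[float, float, float, float]] = {
    "bmi": (27.0, 4.0, 16.0, 45.0),
    "systolic_bp": (135.0, 17.0, 90.0, 220.0),
    "cholesterol": (5.8, 1.1, 2.5, 10.0),
    "alcohol_units": (4.0, 4.0, 0.0, 40.0),
}

# Weights of the latent burden. Continuous demographics/biomarkers enter as
# z-deviations from the centring constants below; binary items enter as 0/1.
DEFAULT_RISK_WEIGHTS: dict[str, float] = {
    "age_z": 0.35,
    "education_z": -0.25,
    "male": 0.10,
    "bmi_z": 0.15,
    "systolic_bp_z": 0.15,
    "cholesterol_z": 0.10,
    "diabetes": 0.25,
    "hypertension": 0.20,
    "smoking": 0.25,
    "depression": 0.30,
    "heart_disease": 0.25,
    "stroke": 0.30,
    "hearing_loss": 0.20,
    "social_isolation": 0.20,
    "physical_inactivity": 0.20,
    "high_alcohol": 0.15,
    "head_injury": 0.15,
    "kidney_disease": 0.15,
    "vision_loss": 0.15,
    "apoe4": 0.30,
    "family_history": 0.20,
    "living_alone": 0.10,
    "deprivation": 0.15,
    "low_cognitive_activity": 0.25,
    "poor_diet": 0.15,
    "poor_sleep": 0.15,
    "low_fish_intake": 0.10,
    "air_pollution": 0.10,
}

# Centring/scaling constants for the *_z terms of the latent burden (fixed,
# not sample-dependent, so true_risk is a deterministic function of the items).
RISK_Z_ANCHORS: dict[str, tuple[float, float]] = {
    "age_z": (66.3, 5.6),
    "education_z": (12.7, 2.3),
    "bmi_z": (27.0, 4.0),
    "systolic_bp_z": (135.0, 17.0),
    "cholesterol_z": (5.8, 1.1),
}

#: attendance model on the raw covariate scale (log-odds); calibrated to an
#: attendance fraction near 0.65 with older, frailer, lower-MoCA dropout.
DEFAULT_ATTRITION: dict[str, float] = {
    "intercept": 2.41,
    "age_baseline": -0.06,
    "moca_visit1": 0.10,
    "heart_disease": -0.30,
    "depression": -0.30,
    "diabetes": -0.20,
    "stroke": -0.40,
    "hypertension": -0.10,
}

#: item-level missingness rates (self-report items miss more than registry
#: ones); calibrated so a 14-18 item score is incomplete for roughly a
#: quarter of participants.
DEFAULT_MISSINGNESS: dict[str, float] = {
    "bmi": 0.010,
    "systolic_bp": 0.010,
    "cholesterol": 0.030,
    "alcohol_units": 0.020,
    "diabetes": 0.005,
    "hypertension": 0.005,
    "smoking": 0.015,
    "depression": 0.020,
    "heart_disease": 0.005,
    "stroke": 0.005,
    "hearing_loss": 0.025,
    "social_isolation": 0.025,
    "physical_inactivity": 0.020,
    "high_alcohol": 0.020,
    "head_injury": 0.020,
    "kidney_disease": 0.010,
    "vision_loss": 0.020,
    "apoe4": 0.060,
    "family_history": 0.030,
    "living_alone": 0.005,
    "deprivation": 0.005,
    "low_cognitive_activity": 0.030,
    "poor_diet": 0.030,
    "poor_sleep": 0.025,
    "low_fish_intake": 0.030,
    "air_pollution": 0.015,
}


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Units: ages and education in years, MoCA in points, slopes in MoCA
    points per year, ``*_per_risk_unit`` per unit of latent burden.
    """

    n_participants: int = 7221
    seed: int = 0
    age_range_baseline: tuple[float, float] = (57.8, 89.9)
    age_mean_sd: tuple[float, float] = (66.3, 5.6)
    education_mean_sd: tuple[float, float] = (12.7, 2.3)
    sex_female_prob: float = 0.54
    factor_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    continuous_items: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTINUOUS))
    risk_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_WEIGHTS))
    level_per_risk_unit: float = -2.5
    slope_per_risk_unit: float = -0.33
    base_slope_per_year: float = -0.30
    baseline_moca_mean_sd: tuple[float, float] = (23.8, 2.4)
    person_slope_sd: float = 0.15
    #: coupling of the annual slope to the person's baseline level (MoCA
    #: points/year per baseline point above the mean): cognitive-reserve-style
    #: dependence that makes attrition on baseline cognition informative for
    #: change, not just level. 0 = independent.
    slope_per_baseline_point: float = 0.0
    residual_sd: float = 1.3
    followup_interval_mean_sd_range: tuple[float, float, tuple[float, float]] = (
        4.2, 0.3, (2.9, 5.2))
    attrition_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTRITION))
    item_missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        for name, p in {**self.factor_prevalences,
                        **self.item_missingness_rates,
                        "sex_female_prob": self.sex_female_prob}.items():
            if not (isinstance(p, (int, float)) and math.isfinite(p)):
                raise ConfigError(f"non-finite probability for {name!r}: {p!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability for {name!r} outside [0, 1]: {p}")
        scalars = {
            "level_per_risk_unit": self.level_per_risk_unit,
            "slope_per_risk_unit": self.slope_per_risk_unit,
            "base_slope_per_year": self.base_slope_per_year,
            "person_slope_sd": self.person_slope_sd,
            "residual_sd": self.residual_sd,
        }
        for name, v in scalars.items():
            if not math.isfinite(v):
                raise ConfigError(f"non-finite value for {name!r}: {v!r}")
        for name, w in self.risk_weights.items():
            if not math.isfinite(w):
                raise ConfigError(f"non-finite risk weight for {name!r}")
        for name, c in self.attrition_coefficients.items():
            if not math.isfinite(c):
                raise ConfigError(f"non-finite attrition coefficient for {name!r}")
        mean, sd, (lo, hi) = self.followup_interval_mean_sd_range
        if not (math.isfinite(mean) and math.isfinite(sd) and lo < hi and sd >= 0):
            raise ConfigError("invalid follow-up interval specification")
        if self.residual_sd < 0 or self.person_slope_sd < 0:
            raise ConfigError("standard deviations must be >= 0")

    # -- YAML round trip -----------------------------------------------------
    def to_yaml(self) -> str:
        d = asdict(self)
        d["age_range_baseline"] = list(self.age_range_baseline)
        d["age_mean_sd"] = list(self.age_mean_sd)
        d["education_mean_sd"] = list(self.education_mean_sd)
        d["baseline_moca_mean_sd"] = list(self.baseline_moca_mean_sd)
        m, s, rng = self.followup_interval_mean_sd_range
        d["followup_interval_mean_sd_range"] = [m, s, list(rng)]
        d["continuous_items"] = {k: list(v) for k, v in self.continuous_items.items()}
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text)
        d["age_range_baseline"] = tuple(d["age_range_baseline"])
        d["age_mean_sd"] = tuple(d["age_mean_sd"])
        d["education_mean_sd"] = tuple(d["education_mean_sd"])
        d["baseline_moca_mean_sd"] = tuple(d["baseline_moca_mean_sd"])
        m, s, rng = d["followup_interval_mean_sd_range"]
        d["followup_interval_mean_sd_range"] = (m, s, tuple(rng))
        d["continuous_items"] = {k: tuple(v) for k, v in d["continuous_items"].items()}
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (numpy rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _observe_moca(latent: np.ndarray) -> np.ndarray:
    """Integer MoCA observation: round half away from zero, clamp to [0, 30]."""
    rounded = _round_half_away(latent)
    clamped = np.clip(rounded, 0.0, 30.0)
    n_clamped = int(np.sum(rounded != clamped))
    if n_clamped:
        log.info("MoCA clamping applied to %d observations", n_clamped)
    return clamped


def true_risk_from_items(frame: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    """Deterministic latent burden: weighted sum of item values.

    ``*_z`` weight names refer to the fixed anchors in :data:`RISK_Z_ANCHORS`;
    ``male`` refers to the sex column. The result is centred at its analytic
    population expectation under the default prevalences so that a burden of
    zero means "average risk" (centring uses the observed item means, which
    converge to the analytic ones; it does not affect any downstream analysis,
    all of which standardize scores before use).
    """
    total = np.zeros(len(frame))
    for name, w in weights.items():
        if name in RISK_Z_ANCHORS:
            col = name[:-2]  # strip _z
            if col == "age":
                col = "age_baseline"
            centre, scale = RISK_Z_ANCHORS[name]
            total += w * (frame[col].to_numpy(float) - centre) / scale
        elif name == "male":
            total += w * (frame["sex"].to_numpy() == "male").astype(float)
        elif name in frame.columns:
            total += w * frame[name].to_numpy(float)
        else:
            raise ConfigError(f"risk weight refers to unknown item {name!r}")
    return total - float(np.mean(total)) if len(total) else total


MOCA_COLUMNS = ("moca_visit1", "moca_visit2")


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate one cohort table; deterministic for a fixed ``config.seed``.

    The latent trajectory of participant *i* at time *t* (years since the
    first cognitive visit) is

        b0_i + level_per_risk_unit * risk_i
             + (base_slope + slope_per_risk_unit * risk_i + u_i) * t + e_it

    with b0_i ~ N(baseline mean, baseline sd), u_i ~ N(0, person_slope_sd)
    and e_it ~ N(0, residual_sd); observations are rounded and clamped to the
    0-30 MoCA scale. Visit 1 is at t = 0, visit 2 at t = followup_years.

    Attrition and item missingness are applied only when their configuration
    maps are non-empty (the pipeline may also apply them as separate stages).
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_demo, rng_items, rng_traj, rng_fu, rng_att, rng_miss = (
        np.random.default_rng(s) for s in streams)
    n = config.n_participants

    lo, hi = config.age_range_baseline
    mu, sd = config.age_mean_sd
    age = stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd).rvs(
        size=n, random_state=rng_demo)
    emu, esd = config.education_mean_sd
    education = np.clip(rng_demo.normal(emu, esd, size=n), 0.0, 25.0)
    sex = np.where(rng_demo.random(n) < config.sex_female_prob, "female", "male")

    frame = pd.DataFrame({
        "id": np.arange(1, n + 1, dtype=np.int64),
        "age_baseline": age,
        "sex": sex,
        "education": education,
    })
    for name, prev in sorted(config.factor_prevalences.items()):
        frame[name] = (rng_items.random(n) < prev).astype(float)
    for name, (cmu, csd, clo, chi) in sorted(config.continuous_items.items()):
        frame[name] = np.clip(rng_items.normal(cmu, csd, size=n), clo, chi)

    frame["true_risk"] = true_risk_from_items(frame, config.risk_weights)

    fmu, fsd, (flo, fhi) = config.followup_interval_mean_sd_range
    if fsd > 0:
        fu = stats.truncnorm((flo - fmu) / fsd, (fhi - fmu) / fsd,
                             loc=fmu, scale=fsd).rvs(size=n, random_state=rng_fu)
    else:
        fu = np.full(n, fmu)
    frame["followup_years"] = fu

    bmu, bsd = config.baseline_moca_mean_sd
    b0 = rng_traj.normal(bmu, bsd, size=n)
    slope = (config.base_slope_per_year
             + config.slope_per_risk_unit * frame["true_risk"].to_numpy()
             + config.slope_per_baseline_point * (b0 - bmu)
             + rng_traj.normal(0.0, config.person_slope_sd, size=n))
    level = b0 + config.level_per_risk_unit * frame["true_risk"].to_numpy()
    e1 = rng_traj.normal(0.0, config.residual_sd, size=n)
    e2 = rng_traj.normal(0.0, config.residual_sd, size=n)
    frame["moca_visit1"] = pd.array(
        _observe_moca(level + e1).astype(np.int64) if n else [], dtype="Int64")
    frame["moca_visit2"] = pd.array(
        _observe_moca(level + slope * fu + e2).astype(np.int64) if n else [],
        dtype="Int64")
    frame["attended_followup"] = np.ones(n, dtype=bool)

    if config.attrition_coefficients:
        frame = apply_attrition(frame, config.attrition_coefficients, rng=rng_att)
    if config.item_missingness_rates:
        frame = apply_item_missingness(frame, config.item_missingness_rates,
                                       rng=rng_miss)
    return frame


_COVARIATE_ALIASES = {"age": "age_baseline", "moca": "moca_visit1"}


def _resolve_covariate(name: str, frame: pd.DataFrame) -> str:
    col = _COVARIATE_ALIASES.get(name, name)
    if col not in frame.columns:
        raise ConfigError(f"unknown attrition covariate {name!r}")
    return col


def apply_attrition(cohort: pd.DataFrame, coefficients: dict[str, float],
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw second-visit attendance from a logistic model on cohort covariates.

    ``coefficients`` maps covariate names (plus an optional ``"intercept"``)
    to log-odds per raw covariate unit. ``sex`` may be used and is coded
    male = 1. Non-attendees have ``moca_visit2`` removed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = cohort.copy()
    eta = np.full(len(out), float(coefficients.get("intercept", 0.0)))
    for name, coef in coefficients.items():
        if name == "intercept":
            continue
        if not math.isfinite(coef):
            raise ConfigError(f"non-finite attrition coefficient for {name!r}")
        col = _resolve_covariate(name, out)
        if col == "sex":
            vals = (out["sex"].to_numpy() == "male").astype(float)
        else:
            vals = out[col].to_numpy(float)
        eta += coef * vals
    p = 1.0 / (1.0 + np.exp(-eta))
    attended = rng.random(len(out)) < p
    out["attended_followup"] = attended
    out.loc[~attended, "moca_visit2"] = pd.NA
    return out


def apply_item_missingness(cohort: pd.DataFrame, rates: dict[str, float],
                           seed: int | None = None,
                           rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Blank each listed item independently with its rate.

    Demographics (``age_baseline``, ``sex``) are never blanked; listing them
    is a configuration error.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = cohort.copy()
    for name in sorted(rates):
        rate = rates[name]
        if not (isinstance(rate, (int, float)) and 0.0 <= rate <= 1.0):
            raise ConfigError(f"missingness rate for {name!r} outside [0, 1]")
        if name in ("age", "age_baseline", "sex", "id"):
            raise ConfigError(f"demographic item {name!r} cannot be blanked")
        if name not in out.columns:
            raise ConfigError(f"unknown item {name!r} in missingness rates")
        mask = rng.random(len(out)) < rate
        col = out[name].astype(float)
        col[mask] = np.nan
        out[name] = col
    return out


# -- CSV round trip ----------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path_or_buf) -> None:
    """Write the cohort with a stable header and full float precision."""
    cohort.to_csv(path_or_buf, index=False, float_format="%.12g")


def cohort_to_csv_bytes(cohort: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_cohort_csv(cohort, buf)
    return buf.getvalue().encode()


def read_cohort_csv(path_or_buf) -> pd.DataFrame:
    frame = pd.read_csv(path_or_buf)
    for col in MOCA_COLUMNS:
        if col in frame.columns:
            frame[col] = frame[col].astype("Int64")
    if "attended_followup" in frame.columns:
        frame["attended_followup"] = frame["attended_followup"].astype(bool)
    return frame
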