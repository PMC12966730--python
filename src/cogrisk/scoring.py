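"""Declarative, config-driven computation of composite dementia risk scores.

A risk index is a :class:`ScoreDefinition`: a list of items, each mapping a
harmonized profile value to points. Four item kinds cover the published
indices:

``binary``
    present (1) earns ``points``, absent (0) earns 0.
``categorical``
    an explicit label -> points mapping.
``banded``
    a continuous measure cut into half-open bands ``[min, max)`` with points
    per band (e.g. CAIDE age groups, BMI categories).
``linear``
    points = slope * value, with an ``anchor`` value at which the item's
    theoretical maximum is evaluated (the UK Biobank-style convention:
    age anchored at 100 years, education at 20 years).

Incomplete profiles are prorated to the full theoretical scale:

    prorated = observed points / max attainable over observed items
               * theoretical maximum

Protective items (only non-positive points) contribute 0 to the prorating
denominator and to the theoretical maximum, keeping both positive for
LIBRA-style indices; linear items instead contribute their anchor value
(possibly negative for protective linear weights, matching the published
convention for linearly weighted demographics).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DegenerateDistributionError, UnscorableError

TERTILE_LABELS = ("low", "medium", "high")


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return value is pd.NA


@dataclass(frozen=True)
class Band:
    """Half-open interval [min, max) worth ``points``; open ends = unbounded."""
    points: float
    min: float | None = None
    max: float | None = None

    def contains(self, value: float) -> bool:
        if self.min is not None and value < self.min:
            return False
        if self.max is not None and value >= self.max:
            return False
        return True


@dataclass(frozen=True)
class ScoreItem:
    name: str
    kind: str
    demographic: bool = False
    points: float | None = None                    # binary
    mapping: Mapping[str, float] | None = None     # categorical
    bands: tuple[Band, ...] | None = None          # banded
    slope: float | None = None                     # linear
    anchor: float | None = None                    # linear

    def __post_init__(self):
        if self.kind not in ("binary", "categorical", "banded", "linear"):
            raise ConfigError(f"unknown item kind {self.kind!r} for {self.name!r}")
        if self.kind == "binary" and self.points is None:
            raise ConfigError(f"binary item {self.name!r} needs points")
        if self.kind == "categorical" and not self.mapping:
            raise ConfigError(f"categorical item {self.name!r} needs a mapping")
        if self.kind == "banded" and not self.bands:
            raise ConfigError(f"banded item {self.name!r} needs bands")
        if self.kind == "linear" and self.slope is None:
            raise ConfigError(f"linear item {self.name!r} needs a slope")

    def evaluate(self, value: Any) -> float:
        """Points earned by ``value``; raises ConfigError outside the domain."""
        if self.kind == "binary":
            v = float(value)
            if v not in (0.0, 1.0):
                raise ConfigError(
                    f"binary item {self.name!r} got non-binary value {value!r}")
            return v * float(self.points)
        if self.kind == "categorical":
            key = str(value)
            if key not in self.mapping:
                raise ConfigError(
                    f"value {value!r} outside declared levels of {self.name!r}")
            return float(self.mapping[key])
        if self.kind == "banded":
            v = float(value)
            for band in self.bands:
                if band.contains(v):
                    return float(band.points)
            raise ConfigError(
                f"value {value!r} not covered by bands of {self.name!r}")
        return float(self.slope) * float(value)  # linear

    def max_points(self) -> float:
        """Contribution to theoretical max / prorating denominator.

        Non-linear items contribute their largest non-negative mapping value
        (protective-only items contribute 0); linear items are evaluated at
        their anchor.
        """
        if self.kind == "linear":
            if self.anchor is None:
                raise ConfigError(
                    f"linear item {self.name!r} is unbounded: no anchor configured")
            return float(self.slope) * float(self.anchor)
        if self.kind == "binary":
            return max(0.0, float(self.points))
        if self.kind == "categorical":
            return max(0.0, max(float(v) for v in self.mapping.values()))
        return max(0.0, max(float(b.points) for b in self.bands))

    def min_points(self) -> float:
        if self.kind == "linear":
            return 0.0
        if self.kind == "binary":
            return min(0.0, float(self.points))
        if self.kind == "categorical":
            return min(0.0, min(float(v) for v in self.mapping.values()))
        return min(0.0, min(float(b.points) for b in self.bands))


@dataclass
class ScoreDefinition:
    name: str
    items: tuple[ScoreItem, ...]
    theoretical_max: float | None = None  # computed from items when None
    provenance: str = ""

    def __post_init__(self):
        names = [it.name for it in self.items]
        if len(names) != len(set(names)):
            raise ConfigError(f"duplicate item names in score {self.name!r}")
        self.items = tuple(self.items)

    def item(self, name: str) -> ScoreItem:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)


@dataclass
class ScoreResult:
    raw_points: float
    observed_items: int
    max_available: float
    prorated: float
    complete: bool


def theoretical_max_for(definition: ScoreDefinition) -> float:
    """Theoretical maximum: sum of per-item maxima (linear items at anchors)."""
    if definition.theoretical_max is not None:
        return float(definition.theoretical_max)
    return sum(it.max_points() for it in definition.items)


def prorate(observed_points: float, max_available: float,
            theoretical_max: float) -> float:
    """Rescale observed points to the full theoretical range of the score."""
    if max_available <= 0:
        raise UnscorableError(
            f"prorating denominator not positive: {max_available}")
    if theoretical_max <= 0:
        raise UnscorableError(
            f"theoretical maximum not positive: {theoretical_max}")
    return observed_points / max_available * theoretical_max


def compute_score(profile: Mapping[str, Any],
                  definition: ScoreDefinition) -> ScoreResult:
    """Score one harmonized profile; missing items are prorated, never zeroed."""
    raw = 0.0
    observed = 0
    max_avail = 0.0
    for item in definition.items:
        value = profile.get(item.name)
        if _is_missing(value):
            continue
        raw += item.evaluate(value)
        max_avail += item.max_points()
        observed += 1
    if observed == 0:
        raise UnscorableError(
            f"no observed items for score {definition.name!r}")
    complete = observed == len(definition.items)
    if complete:
        prorated = raw
    else:
        prorated = prorate(raw, max_avail, theoretical_max_for(definition))
    return ScoreResult(raw_points=raw, observed_items=observed,
                       max_available=max_avail, prorated=prorated,
                       complete=complete)


def compute_scores_frame(cohort: pd.DataFrame, definition: ScoreDefinition,
                         column_map: Mapping[str, str] | None = None
                         ) -> pd.DataFrame:
    """Score every cohort row; unscorable rows get NA and are counted.

    ``column_map`` maps item names to cohort column names where they differ
    (by default items named ``age``/``education`` fall back to the cohort's
    ``age_baseline``/``education`` columns).
    """
    column_map = dict(column_map or {})
    column_map.setdefault("age", "age_baseline")
    rows = []
    n_unscorable = 0
    records = cohort.to_dict("records")
    for rec in records:
        profile = {}
        for item in definition.items:
            col = column_map.get(item.name, item.name)
            if col in rec:
                profile[item.name] = rec[col]
        try:
            res = compute_score(profile, definition)
            rows.append((res.raw_points, res.prorated, res.observed_items,
                         res.complete))
        except UnscorableError:
            n_unscorable += 1
            rows.append((np.nan, np.nan, 0, False))
    if n_unscorable:
        import logging
        logging.getLogger(__name__).info(
            "score %s: %d unscorable participants excluded",
            definition.name, n_unscorable)
    out = pd.DataFrame(rows, columns=["raw", "prorated", "observed_items",
                                      "complete"], index=cohort.index)
    out.insert(0, "id", cohort["id"].to_numpy())
    out.insert(1, "score", definition.name)
    return out


# -- demographic augmentation / stripping ------------------------------------

def demographic_items(definition: ScoreDefinition) -> tuple[ScoreItem, ...]:
    return tuple(it for it in definition.items if it.demographic)


def augment_with_demographics(definition: ScoreDefinition,
                              demo_items: Iterable[ScoreItem]
                              ) -> ScoreDefinition:
    """Append demographic items (e.g. another index's age/sex weights)."""
    demo_items = tuple(demo_items)
    for it in demo_items:
        if not it.demographic:
            raise ConfigError(f"item {it.name!r} is not flagged demographic")
        if any(existing.name == it.name for existing in definition.items):
            raise ConfigError(
                f"item name collision on {it.name!r} in {definition.name!r}")
    return ScoreDefinition(name=definition.name,
                           items=definition.items + demo_items,
                           theoretical_max=None,
                           provenance=definition.provenance)


def strip_demographics(definition: ScoreDefinition) -> ScoreDefinition:
    """Remove age/sex/education-style items, isolating modifiable content."""
    return ScoreDefinition(
        name=definition.name,
        items=tuple(it for it in definition.items if not it.demographic),
        theoretical_max=None,
        provenance=definition.provenance)


# -- standardization ----------------------------------------------------------

@dataclass
class StandardizedScores:
    z: np.ndarray
    mean_used: float
    sd_used: float
    tertile: np.ndarray | None = None
    cutpoints: tuple[float, float] | None = None


def zscore(values: Sequence[float]) -> StandardizedScores:
    """Standardize to mean 0, SD 1 (sample SD, denominator n-1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateDistributionError("need at least 2 values to standardize")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateDistributionError("constant input: zero variance")
    return StandardizedScores(z=(x - mean) / sd, mean_used=mean, sd_used=sd)


def assign_tertiles(values: Sequence[float]) -> StandardizedScores:
    """Cut at the 1/3 and 2/3 empirical quantiles; ties go to the lower group."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateDistributionError("need at least 3 values for tertiles")
    if np.unique(x).size < 3:
        warnings.warn("fewer than 3 distinct values: degenerate tertile grouping",
                      stacklevel=2)
    c1, c2 = np.quantile(x, [1 / 3, 2 / 3])
    labels = np.where(x <= c1, "low", np.where(x <= c2, "medium", "high"))
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return StandardizedScores(
        z=(x - mean) / sd if sd > 0 else np.zeros_like(x),
        mean_used=mean, sd_used=sd,
        tertile=labels, cutpoints=(float(c1), float(c2)))


# -- YAML configuration -------------------------------------------------------

def _item_from_dict(d: Mapping[str, Any]) -> ScoreItem:
    kind = d.get("kind")
    kwargs = dict(name=d["name"], kind=kind,
                  demographic=bool(d.get("demographic", False)))
    if kind == "binary":
        kwargs["points"] = float(d["points"])
    elif kind == "categorical":
        kwargs["mapping"] = {str(k): float(v) for k, v in d["mapping"].items()}
    elif kind == "banded":
        kwargs["bands"] = tuple(
            Band(points=float(b["points"]),
                 min=None if b.get("min") is None else float(b["min"]),
                 max=None if b.get("max") is None else float(b["max"]))
            for b in d["bands"])
    elif kind == "linear":
        kwargs["slope"] = float(d["slope"])
        kwargs["anchor"] = None if d.get("anchor") is None else float(d["anchor"])
    else:
        raise ConfigError(f"unknown item kind {kind!r}")
    return ScoreItem(**kwargs)


def _item_to_dict(it: ScoreItem) -> dict:
    d: dict[str, Any] = {"name": it.name, "kind": it.kind}
    if it.demographic:
        d["demographic"] = True
    if it.kind == "binary":
        d["points"] = it.points
    elif it.kind == "categorical":
        d["mapping"] = dict(it.mapping)
    elif it.kind == "banded":
        d["bands"] = [{k: v for k, v in
                       (("min", b.min), ("max", b.max), ("points", b.points))
                       if v is not None} for b in it.bands]
    elif it.kind == "linear":
        d["slope"] = it.slope
        if it.anchor is not None:
            d["anchor"] = it.anchor
    return d


def definition_from_dict(d: Mapping[str, Any]) -> ScoreDefinition:
    return ScoreDefinition(
        name=d["name"],
        items=tuple(_item_from_dict(i) for i in d["items"]),
        theoretical_max=d.get("theoretical_max"),
        provenance=d.get("provenance", ""))


def definition_to_dict(defn: ScoreDefinition) -> dict:
    d: dict[str, Any] = {"name": defn.name,
                         "items": [_item_to_dict(i) for i in defn.items]}
    if defn.theoretical_max is not None:
        d["theoretical_max"] = defn.theoretical_max
    if defn.provenance:
        d["provenance"] = defn.provenance
    return d


def load_score_config(path_or_text) -> ScoreDefinition:
    """Load one ScoreDefinition from a YAML file path or YAML text."""
    text = path_or_text
    try:
        import os
        if os.path.exists(str(path_or_text)):
            with open(path_or_text) as fh:
                text = fh.read()
    except (OSError, ValueError):
        pass
    return definition_from_dict(yaml.safe_load(text))


BUNDLED_SCORES = ("anu_adri", "caide", "cogdrisk", "libra", "libra2",
                  "ukbdrs", "ukbdrs_apoe", "lancet")


def load_bundled_definition(key: str) -> ScoreDefinition:
    text = resources.files("cogrisk.score_configs").joinpath(
        f"{key}.yaml").read_text()
    return definition_from_dict(yaml.safe_load(text))


def load_bundled_definitions(augment_demographics: bool = True
                             ) -> dict[str, ScoreDefinition]:
    """The eight bundled indices, keyed by config name.

    When ``augment_demographics`` is set, the indices that carry no native
    demographic weights (LIBRA, LIBRA2, Lancet) are augmented with the
    ANU-ADRI age and sex items so all eight are comparable head-to-head.
    """
    defs = {k: load_bundled_definition(k) for k in BUNDLED_SCORES}
    if augment_demographics:
        donor = tuple(it for it in demographic_items(defs["anu_adri"])
                      if it.name in ("age", "sex"))
        for key in ("libra", "libra2", "lancet"):
            has_age = any(it.name in ("age", "sex") for it in defs[key].items)
            if not has_age:
                defs[key] = augment_with_demographics(defs[key], donor)
    return defs
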