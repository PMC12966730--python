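"""Score engine: prorating, theoretical maxima, augmentation, standardization."""

import numpy as np
import pytest
import yaml
from hypothesis import given, settings, strategies as st

from cogrisk.errors import (ConfigError, DegenerateDistributionError,
                            UnscorableError)
from cogrisk.scoring import (Band, ScoreDefinition, ScoreItem, assign_tertiles,
                             augment_with_demographics, compute_score,
                             compute_scores_frame, definition_from_dict,
                             definition_to_dict, demographic_items,
                             load_bundled_definition,
                             load_bundled_definitions, prorate,
                             strip_demographics, theoretical_max_for, zscore)

from conftest import random_profiles


def brute_force_score(profile, definition):
    """Independent oracle: explicit loop-free re-derivation of the item sum."""
    pts = [definition.item(n).evaluate(profile[n]) for n in profile
           if profile[n] is not None]
    observed = [n for n in profile if profile[n] is not None]
    raw = sum(pts)
    avail = sum(definition.item(n).max_points() for n in observed)
    if not observed:
        return None
    if len(observed) == len(definition.items):
        return raw, raw
    return raw, raw / avail * theoretical_max_for(definition)


class TestProrate:
    @pytest.mark.parametrize("obs,avail,tmax,expected", [
        (5.0, 10.0, 20.0, 10.0),
        (0.0, 10.0, 20.0, 0.0),
        (3.5, 3.5, 3.5, 3.5),
        (2.0, 2.0, 3.5, 3.5),
    ])
    def test_formula(self, obs, avail, tmax, expected):
        assert prorate(obs, avail, tmax) == pytest.approx(expected)

    @given(x=st.floats(-50, 50), m=st.floats(0.1, 100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_full_availability_is_identity(self, x, m):
        assert prorate(x, m, m) == pytest.approx(x, abs=1e-12)

    def test_nonpositive_denominator_is_unscorable(self):
        with pytest.raises(UnscorableError):
            prorate(1.0, 0.0, 10.0)
        with pytest.raises(UnscorableError):
            prorate(1.0, -2.0, 10.0)


class TestComputeScore:
    def test_complete_profile(self, toy_definition):
        res = compute_score({"smoking": 1.0, "diabetes": 1.0}, toy_definition)
        assert res.raw_points == pytest.approx(3.5)
        assert res.complete and res.prorated == pytest.approx(3.5)

    def test_absent_of_risk_scores_zero(self, toy_definition):
        res = compute_score({"smoking": 0.0, "diabetes": 0.0}, toy_definition)
        assert res.raw_points == 0.0 and res.complete

    def test_missing_item_is_prorated(self, toy_definition):
        res = compute_score({"smoking": 1.0, "diabetes": None}, toy_definition)
        assert res.raw_points == pytest.approx(2.0)
        assert res.max_available == pytest.approx(2.0)
        assert not res.complete
        # (2.0 / 2.0) * 3.5
        assert res.prorated == pytest.approx(3.5)

    def test_zero_observed_items_raises(self, toy_definition):
        with pytest.raises(UnscorableError):
            compute_score({"smoking": None, "diabetes": None}, toy_definition)

    def test_matches_bruteforce_oracle(self, toy_definition, toy_definition_b):
        rng = np.random.default_rng(11)
        for defn in (toy_definition, toy_definition_b):
            names = [it.name for it in defn.items]
            for prof in random_profiles(rng, 300, names):
                oracle = brute_force_score(prof, defn)
                if oracle is None:
                    with pytest.raises(UnscorableError):
                        compute_score(prof, defn)
                    continue
                res = compute_score(prof, defn)
                assert res.raw_points == pytest.approx(oracle[0], abs=1e-12)
                assert res.prorated == pytest.approx(oracle[1], abs=1e-12)

    def test_monotone_in_added_risk_item(self, toy_definition_b):
        # flipping any absent-of-risk item to present never lowers raw points
        rng = np.random.default_rng(5)
        names = [it.name for it in toy_definition_b.items]
        for prof in random_profiles(rng, 200, names, missing_rate=0.1):
            base = compute_score(prof, toy_definition_b).raw_points \
                if any(v is not None for v in prof.values()) else None
            for name in names:
                if prof[name] == 0.0:
                    bumped = dict(prof)
                    bumped[name] = 1.0
                    assert (compute_score(bumped, toy_definition_b).raw_points
                            >= (base if base is not None else -np.inf))


class TestTheoreticalMax:
    def test_simple_sum(self, toy_definition):
        assert theoretical_max_for(toy_definition) == pytest.approx(3.5)

    def test_protective_item_contributes_zero(self):
        defn = ScoreDefinition(name="p", items=(
            ScoreItem(name="protect", kind="banded",
                      bands=(Band(points=-1.0, max=0.5),
                             Band(points=0.0, min=0.5))),
            ScoreItem(name="risk", kind="binary", points=2.0)))
        assert theoretical_max_for(defn) == pytest.approx(2.0)

    def test_linear_item_evaluated_at_anchor(self):
        defn = ScoreDefinition(name="l", items=(
            ScoreItem(name="age", kind="linear", slope=0.05, anchor=100.0),))
        assert theoretical_max_for(defn) == pytest.approx(5.0)

    def test_linear_item_without_anchor_raises(self):
        defn = ScoreDefinition(name="l", items=(
            ScoreItem(name="age", kind="linear", slope=0.05),))
        with pytest.raises(ConfigError):
            theoretical_max_for(defn)


class TestAugmentStrip:
    def demo_items(self):
        return (ScoreItem(name="age", kind="linear", slope=0.1, anchor=100,
                          demographic=True),
                ScoreItem(name="sex", kind="categorical",
                          mapping={"female": 0.0, "male": 1.0},
                          demographic=True))

    def test_round_trip(self, toy_definition):
        aug = augment_with_demographics(toy_definition, self.demo_items())
        assert {it.name for it in aug.items} == {"smoking", "diabetes",
                                                 "age", "sex"}
        back = strip_demographics(aug)
        assert [it.name for it in back.items] == [it.name for it
                                                  in toy_definition.items]

    def test_theoretical_max_additivity(self, toy_definition):
        demo = self.demo_items()
        aug = augment_with_demographics(toy_definition, demo)
        demo_only = ScoreDefinition(name="demo", items=demo)
        assert theoretical_max_for(aug) == pytest.approx(
            theoretical_max_for(toy_definition) + theoretical_max_for(demo_only))

    def test_empty_augmentation_is_identity(self, toy_definition):
        aug = augment_with_demographics(toy_definition, ())
        assert aug.items == toy_definition.items

    def test_collision_raises(self, toy_definition):
        clash = (ScoreItem(name="smoking", kind="binary", points=1.0,
                           demographic=True),)
        with pytest.raises(ConfigError):
            augment_with_demographics(toy_definition, clash)

    def test_unflagged_item_raises(self, toy_definition):
        bad = (ScoreItem(name="age", kind="linear", slope=0.1, anchor=100),)
        with pytest.raises(ConfigError):
            augment_with_demographics(toy_definition, bad)

    def test_strip_without_demographics_is_identity(self, toy_definition):
        assert strip_demographics(toy_definition).items == toy_definition.items


class TestStandardization:
    def test_zscore_hand_example(self):
        out = zscore([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out.z, [-1.0, 0.0, 1.0])
        assert out.sd_used == pytest.approx(1.0)  # n-1 denominator

    def test_zscore_centering(self):
        rng = np.random.default_rng(3)
        out = zscore(rng.normal(10, 4, size=500))
        assert abs(out.z.mean()) < 1e-9
        assert np.std(out.z, ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateDistributionError):
            zscore([5.0, 5.0, 5.0])

    @given(a=st.floats(0.1, 10), b=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_equivariance(self, a, b):
        x = np.array([0.3, 1.7, -2.2, 5.5, 0.0])
        np.testing.assert_allclose(zscore(a * x + b).z, zscore(x).z,
                                   atol=1e-9)


class TestTertiles:
    def test_one_to_nine(self):
        out = assign_tertiles(np.arange(1.0, 10.0))
        assert list(out.tertile) == (["low"] * 3 + ["medium"] * 3
                                     + ["high"] * 3)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        a = assign_tertiles(x).tertile
        b = assign_tertiles(np.exp(x)).tertile
        assert (a == b).all()

    def test_all_equal_single_group_with_warning(self):
        with pytest.warns(UserWarning):
            out = assign_tertiles([2.0] * 10)
        assert set(out.tertile) == {"low"}

    def test_too_few_values_raises(self):
        with pytest.raises(DegenerateDistributionError):
            assign_tertiles([1.0, 2.0])


class TestConfigDriven:
    def test_weight_table_swap_changes_output(self, toy_definition):
        text_a = yaml.safe_dump(definition_to_dict(toy_definition))
        loaded = definition_from_dict(yaml.safe_load(text_a))
        prof = {"smoking": 1.0, "diabetes": 1.0}
        assert compute_score(prof, loaded).raw_points == pytest.approx(3.5)
        swapped = yaml.safe_load(text_a)
        swapped["items"][0]["points"] = 10.0
        assert compute_score(prof, definition_from_dict(swapped)
                             ).raw_points == pytest.approx(11.5)

    def test_definition_yaml_round_trip(self, toy_definition_b):
        d = definition_to_dict(toy_definition_b)
        back = definition_from_dict(yaml.safe_load(yaml.safe_dump(d)))
        assert back.items == toy_definition_b.items


class TestBundledConfigs:
    def test_all_eight_load(self):
        defs = load_bundled_definitions()
        assert len(defs) == 8
        for defn in defs.values():
            assert theoretical_max_for(defn) > 0

    def test_augmented_indices_gain_age_and_sex(self):
        defs = load_bundled_definitions()
        for key in ("libra", "libra2", "lancet"):
            names = {it.name for it in defs[key].items}
            assert {"age", "sex"} <= names
        raw_libra = load_bundled_definition("libra")
        assert not any(it.name in ("age", "sex") for it in raw_libra.items)

    def test_strip_ukbdrs_removes_all_demographics(self):
        ukbdrs = load_bundled_definition("ukbdrs")
        stripped = strip_demographics(ukbdrs)
        names = {it.name for it in stripped.items}
        assert names.isdisjoint({"age", "sex", "education"})
        assert not demographic_items(stripped)
        assert len(stripped.items) < len(ukbdrs.items)

    def test_ukbdrs_linear_anchors(self):
        ukbdrs = load_bundled_definition("ukbdrs")
        age = ukbdrs.item("age")
        edu = ukbdrs.item("education")
        assert age.kind == "linear" and age.anchor == 100.0
        assert edu.kind == "linear" and edu.anchor == 20.0

    def test_frame_scoring_on_cohort(self, default_cohort):
        defs = load_bundled_definitions()
        frame = compute_scores_frame(default_cohort, defs["lancet"])
        assert len(frame) == len(default_cohort)
        scored = frame["prorated"].dropna()
        assert len(scored) > 0.95 * len(frame)
        assert (frame.loc[frame["complete"], "raw"]
                == frame.loc[frame["complete"], "prorated"]).all()
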