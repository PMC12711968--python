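"""Baseline / new / follow-up classification against the published table."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungscreen import (
    InvalidInputError,
    MorphologyProfile,
    NoduleHistory,
    NoduleObservation,
    SizeMeasurement,
    classify,
    classify_baseline,
    classify_followup,
    classify_new,
    effective_density,
    participant_decision,
)
from lungscreen.classifier import ACTION_INTENSITY

from _oracles import table_action
from conftest import D0, non_solid_obs, part_solid_obs, solid_obs

MORPH = {
    "neutral": {},
    "suspicious": {"spiculation": True},
    "benign": {"calcification_pattern": "popcorn"},
}


class TestEffectiveDensity:
    def test_large_solid_component_reclassified(self):
        obs = part_solid_obs(solid_diameter=17.0, whole_diameter=19.0)
        assert effective_density(obs) == "solid"

    def test_half_solid_stays_part_solid(self):
        obs = part_solid_obs(solid_diameter=10.0, whole_diameter=20.0)
        assert effective_density(obs) == "part_solid"

    def test_solid_identity(self):
        assert effective_density(solid_obs(volume=200)) == "solid"

    def test_effective_diameters_used_when_volumes_given(self):
        # solid component 523.6 mm3 -> 10 mm of an 11 mm whole: 91% -> solid
        obs = NoduleObservation(
            "n1", D0, "part_solid",
            whole=SizeMeasurement(volume_mm3=696.9),  # 11 mm sphere
            solid_component=SizeMeasurement(volume_mm3=523.6),
        )
        assert effective_density(obs) == "solid"


class TestBaseline:
    @pytest.mark.parametrize(
        "volume, morph, action",
        [
            (80, "neutral", "repeat_12m"),
            (80, "suspicious", "repeat_6m"),
            (80, "benign", "repeat_12m"),
            (150, "neutral", "repeat_6m"),
            (150, "suspicious", "repeat_3m"),
            (300, "neutral", "repeat_3m"),
            (300, "suspicious", "workup"),
            (600, "neutral", "workup"),
            (600, "suspicious", "workup"),
            (600, "benign", "repeat_12m"),
        ],
    )
    def test_solid_rows(self, volume, morph, action):
        dec = classify_baseline(solid_obs(volume=volume, **MORPH[morph]))
        assert dec.action == action

    def test_part_solid_large_component_one_month(self):
        dec = classify_baseline(part_solid_obs(solid_volume=600, whole_diameter=18))
        assert (dec.category, dec.action) == ("positive", "repeat_1m")

    def test_part_solid_suspicious_large_component_workup(self):
        dec = classify_baseline(
            part_solid_obs(solid_volume=300, whole_diameter=20, spiculation=True)
        )
        assert dec.action == "workup"

    @pytest.mark.parametrize(
        "diameter, morph, action",
        [
            (20, "neutral", "repeat_12m"),
            (20, "suspicious", "repeat_6m"),
            (35, "neutral", "repeat_6m"),
            (35, "suspicious", "repeat_3m"),
        ],
    )
    def test_non_solid_rows(self, diameter, morph, action):
        dec = classify_baseline(non_solid_obs(diameter, **MORPH[morph]))
        assert dec.action == action

    def test_diameter_bins_when_volumetry_failed(self):
        assert classify_baseline(solid_obs(diameter=5.5)).action == "repeat_12m"
        assert classify_baseline(solid_obs(diameter=7.0)).action == "repeat_6m"
        assert classify_baseline(solid_obs(diameter=9.0)).action == "repeat_3m"
        assert classify_baseline(solid_obs(diameter=12.0)).action == "workup"

    def test_volume_governs_over_diameter(self):
        # 90 mm3 is bin 0 even though 6.2 mm would be bin 1
        obs = NoduleObservation(
            "n1", D0, "solid",
            whole=SizeMeasurement(volume_mm3=90.0, mean_diameter_mm=6.2),
        )
        assert classify_baseline(obs).action == "repeat_12m"

    def test_ipln_morphology_negative_despite_growthlike_size(self):
        obs = solid_obs(
            volume=200,
            margin="smooth", shape="lentiform",
            distance_to_pleura_mm=3.0, below_carina=True,
        )
        dec = classify_baseline(obs)
        assert dec.action == "repeat_12m"
        assert "typical_ipln" in dec.rationale


class TestOracleGrid:
    def test_exhaustive_boundary_grid_matches_lookup_table(self):
        """Rule engine vs a literal transcription of the management table on
        an exhaustive grid across every size-bin boundary, in volume units,
        in diameter-fallback units, and with conflicting volume+diameter
        pairs (volume must govern)."""
        from lungscreen import effective_diameter

        volumes = [29, 30, 31, 99, 100, 101, 249, 250, 251, 499, 500, 501]
        fallback_diams = [3.9, 4.0, 4.1, 5.9, 6.0, 6.1, 7.9, 8.0, 8.1, 9.9, 10.0, 10.1]
        ggn_diams = [25.0, 29.9, 30.0, 30.1, 35.0, 50.0]
        n = 0

        def check(obs, density, size, morph_name, registration, diameter_units=False):
            nonlocal n
            reg = "prevalent" if registration == "missed_on_prior" else registration
            expected = table_action(
                density, size, morph_name, reg, diameter_units=diameter_units
            )
            got = classify(obs).action
            assert got == expected, (density, size, morph_name, registration, got)
            n += 1

        for morph_name, morph_kwargs in MORPH.items():
            for registration in ("prevalent", "new", "missed_on_prior"):
                for v in volumes:
                    check(
                        solid_obs(volume=v, registration=registration, **morph_kwargs),
                        "solid", v, morph_name, registration,
                    )
                    # conflicting manual diameter one bin up: volume governs
                    d_conflict = effective_diameter(v) + 1.7
                    check(
                        NoduleObservation(
                            "n1", D0, "solid",
                            whole=SizeMeasurement(
                                volume_mm3=float(v), mean_diameter_mm=d_conflict
                            ),
                            morphology=MorphologyProfile(**morph_kwargs),
                            registration=registration,
                        ),
                        "solid", v, morph_name, registration,
                    )
                    # a 25 mm ground-glass extent never trips the 30 mm rule,
                    # and component diameters stay below 80% of 25 mm
                    check(
                        part_solid_obs(
                            solid_volume=v, whole_diameter=25.0,
                            registration=registration, **morph_kwargs,
                        ),
                        "part_solid", v, morph_name, registration,
                    )
                for d in fallback_diams:
                    check(
                        solid_obs(diameter=d, registration=registration, **morph_kwargs),
                        "solid", d, morph_name, registration, diameter_units=True,
                    )
                    check(
                        part_solid_obs(
                            solid_diameter=d, whole_diameter=25.0,
                            registration=registration, **morph_kwargs,
                        ),
                        "part_solid", d, morph_name, registration, diameter_units=True,
                    )
                for d in ggn_diams:
                    check(
                        non_solid_obs(d, registration=registration, **morph_kwargs),
                        "non_solid", d, morph_name, registration,
                    )
        assert n == 9 * (3 * 12 + 2 * 12 + 6)  # 594 boundary cases, all ran


class TestNewNodules:
    def test_small_new_solid_negative(self):
        dec = classify_new(solid_obs(volume=20, registration="new"))
        assert dec.category == "negative"

    def test_new_solid_three_months(self):
        dec = classify_new(solid_obs(volume=50, registration="new"))
        assert (dec.category, dec.action) == ("indeterminate", "repeat_3m")

    def test_new_non_solid_negative(self):
        dec = classify_new(non_solid_obs(40.0, registration="new"))
        assert dec.category == "negative"

    def test_missed_nodule_follows_baseline_rules(self):
        dec = classify_new(solid_obs(volume=150, registration="missed_on_prior"))
        assert dec.action == "repeat_6m"
        assert "missed_nodule_managed_as_baseline" in dec.rationale

    def test_recheck_growth_beyond_15_percent_goes_to_workup(self):
        hist = NoduleHistory((
            solid_obs(volume=40, registration="new"),
            solid_obs(volume=50, date=D0 + dt.timedelta(days=91)),
        ))
        dec = classify(hist)
        assert dec.action == "workup"
        assert "volume_growth_gt_15pct" in dec.rationale

    def test_recheck_stable_deescalates_to_prevalent_pathway(self):
        hist = NoduleHistory((
            solid_obs(volume=40, registration="new"),
            solid_obs(volume=42, date=D0 + dt.timedelta(days=91)),
        ))
        dec = classify(hist)
        assert dec.action == "repeat_12m"
        assert "new_nodule_recheck_stable_deescalated" in dec.rationale

    def test_recheck_diameter_fallback(self):
        hist = NoduleHistory((
            solid_obs(diameter=4.5, registration="new"),
            solid_obs(diameter=6.5, date=D0 + dt.timedelta(days=91)),
        ))
        assert classify(hist).action == "workup"


def _pair(v1, v2, days, **kwargs):
    return NoduleHistory((
        solid_obs(volume=v1),
        solid_obs(volume=v2, date=D0 + dt.timedelta(days=days), **kwargs),
    ))


class TestFollowup:
    def test_fast_growth_at_3_months_workup(self):
        assert classify_followup(_pair(100, 180, 90)).action == "workup"

    def test_slow_growth_at_annual_round_negative(self):
        dec = classify_followup(_pair(200, 240, 365))
        assert (dec.category, dec.action) == ("negative", "repeat_12m")

    def test_intermediate_vdt_at_3_months_continues_6m(self):
        # VDT ~ 313 d: not < 250 at 3 months, so indeterminate continuation
        dec = classify_followup(_pair(100, 122, 90))
        assert dec.action == "repeat_6m"

    def test_vdt_between_400_and_500_at_6_months_negative(self):
        # VDT ~ 450 d: cutoff at 6 months is 400 -> negative
        hist = _pair(100, 132.3, 182)
        dec = classify_followup(hist)
        assert dec.action == "repeat_12m"

    def test_vdt_450_at_12_months_is_workup(self):
        # same VDT at an annual interval falls below the 500-day cutoff
        hist = _pair(100, 175.4, 365)
        assert classify_followup(hist).action == "workup"

    def test_regression_negative(self):
        dec = classify_followup(_pair(200, 120, 180))
        assert dec.action == "repeat_12m"
        assert "followup_regression" in dec.rationale

    def test_new_suspicious_flag_triggers_workup(self):
        hist = NoduleHistory((
            solid_obs(volume=150),
            solid_obs(
                volume=152, date=D0 + dt.timedelta(days=365), spiculation=True
            ),
        ))
        dec = classify_followup(hist)
        assert dec.action == "workup"
        assert "new_suspicious_flag_spiculation" in dec.rationale

    def test_solid_core_development_goes_to_mdt(self):
        hist = NoduleHistory((
            non_solid_obs(20.0),
            part_solid_obs(
                solid_diameter=5.0, whole_diameter=20.0,
                date=D0 + dt.timedelta(days=365),
            ),
        ))
        dec = classify_followup(hist)
        assert (dec.category, dec.action) == ("positive", "mdt")
        assert "non_solid_developed_solid_core" in dec.rationale

    def test_persistent_large_solid_component_goes_to_mdt(self):
        hist = NoduleHistory((
            part_solid_obs(solid_volume=600, whole_diameter=25.0),
            part_solid_obs(
                solid_volume=620, whole_diameter=25.0,
                date=D0 + dt.timedelta(days=30),
            ),
        ))
        dec = classify_followup(hist)
        assert dec.action == "mdt"

    def test_resolved_solid_component_rebaselined(self):
        hist = NoduleHistory((
            part_solid_obs(solid_volume=600, whole_diameter=25.0),
            part_solid_obs(
                solid_volume=200, whole_diameter=25.0,
                date=D0 + dt.timedelta(days=30),
            ),
        ))
        dec = classify_followup(hist)
        assert dec.action == "repeat_6m"
        assert "part_solid_component_below_500mm3_rebaselined" in dec.rationale

    def test_slow_grower_past_5mm_from_baseline_goes_to_mdt(self):
        # three annual scans, VDT ~ 700 d, diameter drifts +5.2 mm overall
        obs = [
            solid_obs(volume=500.0),
            solid_obs(volume=710.0, date=D0 + dt.timedelta(days=365)),
            solid_obs(volume=2000.0, date=D0 + dt.timedelta(days=1460)),
        ]
        hist = NoduleHistory(tuple(obs))
        dec = classify_followup(hist)
        assert dec.action == "mdt"
        assert "slow_growing_total_diameter_gt_5mm_from_baseline" in dec.rationale

    def test_benign_features_at_followup_dominate(self):
        hist = NoduleHistory((
            solid_obs(volume=100),
            solid_obs(
                volume=180, date=D0 + dt.timedelta(days=90),
                calcification_pattern="diffuse",
            ),
        ))
        assert classify_followup(hist).action == "repeat_12m"

    def test_non_solid_crossing_30mm_indeterminate(self):
        hist = NoduleHistory((
            non_solid_obs(28.0),
            non_solid_obs(31.0, date=D0 + dt.timedelta(days=365)),
        ))
        assert classify_followup(hist).action == "repeat_6m"

    def test_non_solid_stable_negative(self):
        hist = NoduleHistory((
            non_solid_obs(20.0),
            non_solid_obs(20.4, date=D0 + dt.timedelta(days=365)),
        ))
        dec = classify_followup(hist)
        assert (dec.category, dec.action) == ("negative", "repeat_12m")


class TestDispatchAndInvariants:
    def test_dispatch_routes(self):
        single = solid_obs(volume=150)
        assert classify(single).action == classify_baseline(single).action
        new = solid_obs(volume=50, registration="new")
        assert classify(new).action == classify_new(new).action
        hist = _pair(100, 180, 90)
        assert classify(hist).action == classify_followup(hist).action

    def test_history_invariants(self):
        with pytest.raises(InvalidInputError):
            NoduleHistory(())
        with pytest.raises(InvalidInputError):
            NoduleHistory((solid_obs(volume=100), solid_obs(volume=110)))
        with pytest.raises(InvalidInputError):
            NoduleHistory((
                solid_obs(volume=100),
                solid_obs(volume=110, nodule_id="other", date=D0 + dt.timedelta(90)),
            ))

    def test_category_action_consistency_enforced(self):
        from lungscreen import ManagementDecision

        with pytest.raises(InvalidInputError):
            ManagementDecision("n", "negative", "workup", (), "solid")

    @given(
        st.floats(min_value=1, max_value=2000),
        st.floats(min_value=1, max_value=2000),
        st.sampled_from(["neutral", "suspicious"]),
        st.sampled_from(["solid", "part_solid"]),
    )
    @settings(max_examples=300, derandomize=True)
    def test_baseline_size_monotonicity(self, v1, v2, morph, density):
        """For fixed density and morphology, action intensity is
        non-decreasing in solid(-component) volume."""
        lo, hi = sorted((v1, v2))
        def dec(v):
            if density == "solid":
                obs = solid_obs(volume=v, **MORPH[morph])
            else:
                obs = part_solid_obs(
                    solid_volume=v, whole_diameter=25.0, **MORPH[morph]
                )
            return classify_baseline(obs)
        assert ACTION_INTENSITY[dec(hi).action] >= ACTION_INTENSITY[dec(lo).action]

    @given(st.floats(min_value=1, max_value=2000))
    @settings(max_examples=300, derandomize=True)
    def test_suspicious_upgrade_is_one_ladder_step(self, v):
        """A suspicious verdict moves the neutral baseline decision up
        exactly one rung on the 12m -> 6m -> 3m -> workup ladder (the
        1-month slot is the dedicated neutral part-solid pathway), never
        down and never beyond workup."""
        ladder = ["repeat_12m", "repeat_6m", "repeat_3m", "workup"]
        neutral = classify_baseline(solid_obs(volume=v)).action
        upgraded = classify_baseline(solid_obs(volume=v, spiculation=True)).action
        assert upgraded == ladder[min(ladder.index(neutral) + 1, 3)]

    @given(
        st.floats(min_value=1, max_value=2000),
        st.sampled_from(["solid", "part_solid", "non_solid"]),
        st.booleans(),
    )
    @settings(max_examples=300, derandomize=True)
    def test_benign_dominance(self, v, density, spiculated):
        """Benign morphology yields negative at any size, even with
        coexisting suspicious flags (warning recorded)."""
        kwargs = {"calcification_pattern": "popcorn"}
        if spiculated:
            kwargs["spiculation"] = True
        if density == "solid":
            obs = solid_obs(volume=v, **kwargs)
        elif density == "part_solid":
            obs = part_solid_obs(solid_volume=v, whole_diameter=25.0, **kwargs)
        else:
            obs = non_solid_obs(min(v / 20, 60.0), **kwargs)
        dec = classify_baseline(obs)
        assert dec.category == "negative"
        if spiculated:
            assert dec.warnings

    def test_participant_level_maximum(self):
        d1 = classify_baseline(solid_obs(volume=80, nodule_id="a"))
        d2 = classify_baseline(solid_obs(volume=300, nodule_id="b"))
        top = participant_decision([d1, d2])
        assert top.nodule_id == "b" and top.action == "repeat_3m"
        assert participant_decision([]) is None

    def test_decision_serialization_round_trip(self):
        dec = classify_baseline(solid_obs(volume=300, spiculation=True))
        d = dec.to_dict()
        assert d["action"] == "workup" and d["interval_months"] is None
        assert "spiculation" in d["rationale"][-1] or "spiculation" in d["rationale"]
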