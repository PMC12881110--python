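"""Model family, effect coding and trial-level parameter assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from driftprime import (ModelSpec, PersonParams, get_model, model_family,
                        trial_params, validate_trials)

# person at the study's group-level posterior means (winning model)
STUDY_PERSON = PersonParams(a=1.398, w=0.514, v_living=3.030, v_nonliving=-2.909,
                            t0=0.296, v_a=0.049, v_c=0.264, v_int=-0.018,
                            t0_a=-0.003, t0_c=0.000, t0_int=-0.003)


def _trial(target="living", A=1, C=1):
    return {"target_type": target, "association": A, "congruence": C}


class TestModelFamily:
    def test_family_is_the_canonical_ten(self):
        fam = model_family()
        assert [s.name for s in fam] == [f"Model {i}" for i in range(10)]
        assert not any(fam[0].flags.values())                      # baseline
        m8 = fam[8]
        assert all([m8.drift_assoc, m8.drift_cong, m8.drift_interaction,
                    m8.t0_assoc, m8.t0_cong, m8.t0_interaction])
        assert not m8.start_cong
        assert fam[9].flags == {**m8.flags, "start_cong": True}
        assert fam[6].flags["drift_cong"] and fam[6].flags["t0_assoc"]
        assert sum(fam[5].flags.values()) == 1 and fam[5].start_cong

    def test_lookup_accepts_aliases(self):
        assert get_model("m8") == get_model("Model 8")
        assert get_model("model 3").name == "Model 3"
        with pytest.raises(KeyError):
            get_model("Model 10")


class TestTrialParams:
    def test_living_congruent_associated_at_study_means(self):
        """Hand arithmetic at the reported group means, full model:
        v = 3.030 + 0.049 + 0.264 - 0.018; t0 = 0.296 - 0.003 + 0 - 0.003."""
        wp = trial_params(_trial("living", 1, 1), STUDY_PERSON, get_model("m8"))
        assert wp.v == pytest.approx(3.325, abs=1e-9)
        assert wp.t0 == pytest.approx(0.290, abs=1e-9)
        assert wp.a == pytest.approx(1.398)
        assert wp.w == pytest.approx(0.514)

    def test_nonliving_nonassoc_incongruent_at_study_means(self):
        """Non-living drift negates the effect sum: with A = C = -1 the
        association and congruence effects add and the interaction (A*C = +1,
        effect -0.018) subtracts: -2.909 + 0.049 + 0.264 + 0.018 = -2.578."""
        wp = trial_params(_trial("nonliving", -1, -1), STUDY_PERSON, get_model("m8"))
        assert wp.v == pytest.approx(-2.578, abs=1e-9)

    def test_baseline_model_ignores_all_effects(self):
        spec = get_model("m0")
        for A in (-1, 1):
            for C in (-1, 1):
                wp = trial_params(_trial("living", A, C), STUDY_PERSON, spec)
                assert wp.v == STUDY_PERSON.v_living
                assert wp.t0 == STUDY_PERSON.t0
                assert wp.w == STUDY_PERSON.w

    def test_baseline_model_has_two_distinct_cells(self):
        spec = get_model("m0")
        seen = {trial_params(_trial(t, A, C), STUDY_PERSON, spec)
                for t in ("living", "nonliving") for A in (-1, 1) for C in (-1, 1)}
        assert len(seen) == 2

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.01, 0.5), st.sampled_from(["living", "nonliving"]),
           st.sampled_from([-1, 1]))
    def test_positive_congruence_effect_helps_both_target_types(self, vc, target, A):
        """With v_c > 0, going incongruent -> congruent moves the drift toward
        the correct boundary: up for living, down for non-living targets."""
        person = PersonParams(a=1.4, w=0.5, v_living=2.0, v_nonliving=-2.0,
                              t0=0.3, v_c=vc)
        spec = get_model("m3")
        v_inc = trial_params(_trial(target, A, -1), person, spec).v
        v_con = trial_params(_trial(target, A, 1), person, spec).v
        if target == "living":
            assert v_con > v_inc
        else:
            assert v_con < v_inc

    def test_starting_point_shift_follows_prime_category(self):
        person = PersonParams(a=1.4, w=0.5, v_living=2.0, v_nonliving=-2.0,
                              t0=0.3, w_c=0.4)
        spec = get_model("m5")
        # congruent living target -> living prime -> bias toward upper
        w_living_prime = trial_params(_trial("living", 1, 1), person, spec).w
        # incongruent living target -> non-living prime -> bias toward lower
        w_nonliving_prime = trial_params(_trial("living", 1, -1), person, spec).w
        assert w_living_prime > 0.5 > w_nonliving_prime
        assert w_living_prime == pytest.approx(1 - w_nonliving_prime)

    def test_t0_floor_clamps_with_warning(self):
        person = PersonParams(a=1.4, w=0.5, v_living=2.0, v_nonliving=-2.0,
                              t0=0.004, t0_a=0.05)
        with pytest.warns(UserWarning, match="clamped"):
            wp = trial_params(_trial("living", -1, 1), person, get_model("m8"))
        assert wp.t0 == pytest.approx(1e-3)

    def test_bad_effect_codes_rejected(self):
        with pytest.raises(ValueError):
            trial_params(_trial("living", 0, 1), STUDY_PERSON, get_model("m8"))

    def test_is_pure_function(self):
        t = _trial("nonliving", 1, -1)
        a = trial_params(t, STUDY_PERSON, get_model("m8"))
        b = trial_params(t, STUDY_PERSON, get_model("m8"))
        assert a == b


class TestValidateTrials:
    def _table(self, **overrides):
        base = {"participant_id": ["p1"] * 4, "item_id": ["i1", "i2", "i3", "i4"],
                "target_type": ["living"] * 2 + ["nonliving"] * 2,
                "association": [1, -1, 1, -1], "congruence": [1, -1, -1, 1],
                "response": ["living"] * 4, "rt_s": [0.5, 0.6, 0.7, 0.8]}
        base.update(overrides)
        return pd.DataFrame(base)

    def test_prime_category_derived_from_congruence(self):
        df = validate_trials(self._table())
        assert list(df["prime_category"]) == ["living", "nonliving", "living", "nonliving"]

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            validate_trials(self._table().drop(columns=["rt_s"]))

    def test_bad_codes_rejected(self):
        with pytest.raises(ValueError, match="codes"):
            validate_trials(self._table(association=[0, 1, -1, 1]))

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError, match="rt_s"):
            validate_trials(self._table(rt_s=[0.5, -0.1, 0.7, 0.8]))

    def test_degenerate_design_warns_not_fails(self):
        df = self._table(congruence=[1, 1, 1, 1], association=[1, 1, 1, 1])
        with pytest.warns(UserWarning, match="missing design cells"):
            validate_trials(df)
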