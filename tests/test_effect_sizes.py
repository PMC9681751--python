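import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaepi.effect_sizes import (
    ArmSummary,
    EffectSize,
    align_direction,
    compute_smd,
    smd_from_ci,
    split_shared_control,
)
from metaepi.exceptions import (
    DegenerateInputError,
    UnclearDirectionError,
    ValidationError,
)

arms_st = st.builds(
    ArmSummary,
    mean_treated=st.floats(-50, 50),
    sd_treated=st.floats(0.1, 20),
    n_treated=st.integers(2, 200),
    mean_control=st.floats(-50, 50),
    sd_control=st.floats(0.1, 20),
    n_control=st.integers(2, 200),
)


class TestComputeSMD:
    def test_equal_means_give_zero_smd_and_baseline_variance(self):
        eff = compute_smd(
            ArmSummary(10, 3, 10, 10, 3, 10), bias_corrected=False
        )
        assert eff.smd == 0.0
        assert eff.variance == pytest.approx(0.2)

    def test_hedges_g_hand_computed_example(self):
        # d = 2/2 = 1, J = 1 - 3/71, var = 20/100 + g^2/40
        eff = compute_smd(ArmSummary(10, 2, 10, 8, 2, 10))
        assert eff.smd == pytest.approx(1.0 * (1 - 3 / 71), abs=1e-10)
        assert eff.smd == pytest.approx(0.9577, abs=5e-5)
        assert eff.variance == pytest.approx(0.2 + eff.smd**2 / 40, abs=1e-12)
        assert eff.variance == pytest.approx(0.2229, abs=5e-5)
        assert not eff.direction_aligned

    @settings(max_examples=100, derandomize=True)
    @given(arms=arms_st)
    def test_antisymmetric_in_arm_order(self, arms):
        swapped = ArmSummary(
            arms.mean_control, arms.sd_control, arms.n_control,
            arms.mean_treated, arms.sd_treated, arms.n_treated,
        )
        a = compute_smd(arms)
        b = compute_smd(swapped)
        assert a.smd == pytest.approx(-b.smd, abs=1e-9)
        assert a.variance == pytest.approx(b.variance, rel=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(arms=arms_st)
    def test_hedges_correction_shrinks_magnitude(self, arms):
        d = compute_smd(arms, bias_corrected=False)
        g = compute_smd(arms, bias_corrected=True)
        assert abs(g.smd) <= abs(d.smd) + 1e-12

    def test_zero_pooled_sd_is_degenerate(self):
        with pytest.raises(ValidationError):
            compute_smd(ArmSummary(10, 0.0, 10, 8, 2, 10))

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            ArmSummary(10, 2, 1, 8, 2, 10)


class TestSMDFromCI:
    def test_unit_variance_when_halfwidth_equals_z(self):
        eff = smd_from_ci(0.0, -1.959963984540054, 1.959963984540054)
        assert eff.variance == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_variance(self):
        # (0.8 / (2 * 1.95996...))^2
        eff = smd_from_ci(0.3, -0.1, 0.7)
        assert eff.variance == pytest.approx(0.0416508, abs=1e-6)

    def test_zero_width_ci_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            smd_from_ci(0.5, 0.5, 0.5)

    def test_inverted_ci_rejected(self):
        with pytest.raises(ValidationError):
            smd_from_ci(0.5, 0.7, 0.3)

    @settings(max_examples=100, derandomize=True)
    @given(
        smd=st.floats(-3, 3),
        var=st.floats(1e-4, 4),
    )
    def test_round_trip_through_wald_interval(self, smd, var):
        half = 1.959963984540054 * math.sqrt(var)
        eff = smd_from_ci(smd, smd - half, smd + half)
        assert eff.variance == pytest.approx(var, abs=1e-9)


class TestAlignDirection:
    def test_benefit_negative_flips_signs(self):
        effects = [EffectSize(-0.4, 0.1), EffectSize(-1.2, 0.2)]
        out = align_direction(effects, "benefit_negative")
        assert [e.smd for e in out] == [0.4, 1.2]
        assert all(e.direction_aligned for e in out)

    def test_benefit_positive_is_identity_on_values(self):
        effects = [EffectSize(0.4, 0.1), EffectSize(1.2, 0.2)]
        out = align_direction(effects, "benefit_positive")
        assert [e.smd for e in out] == [0.4, 1.2]

    def test_idempotent_on_aligned_input(self):
        effects = [EffectSize(-0.4, 0.1), EffectSize(1.2, 0.2)]
        once = align_direction(effects, "benefit_negative")
        twice = align_direction(once, "benefit_positive")
        assert [e.smd for e in twice] == [e.smd for e in once]

    def test_preserves_magnitude_and_variance(self):
        effects = [EffectSize(-0.7, 0.3)]
        out = align_direction(effects, "benefit_negative")
        assert abs(out[0].smd) == abs(effects[0].smd)
        assert out[0].variance == effects[0].variance

    def test_unclear_without_fallback_raises(self):
        with pytest.raises(UnclearDirectionError):
            align_direction([EffectSize(0.4, 0.1)], "unclear")

    def test_unclear_with_pooled_sign_fallback(self):
        out = align_direction(
            [EffectSize(-0.4, 0.1)], "unclear", fallback_sign=-1.0
        )
        assert out[0].smd == 0.4


class TestSplitSharedControl:
    def test_control_of_12_split_three_ways(self):
        arms = [ArmSummary(10 + i, 2, 8, 9, 2, 12) for i in range(3)]
        out = split_shared_control(arms, k=3)
        assert all(a.n_control == 4 for a in out)
        assert [a.mean_treated for a in out] == [10, 11, 12]

    def test_k_one_is_identity(self):
        arms = [ArmSummary(10, 2, 8, 9, 2, 12)]
        assert split_shared_control(arms, k=1) == arms

    def test_too_small_control_is_degenerate(self):
        arms = [ArmSummary(10 + i, 2, 8, 9, 2, 5) for i in range(3)]
        with pytest.raises(DegenerateInputError):
            split_shared_control(arms, k=3)
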