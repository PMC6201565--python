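"""Unit tests of the individual reaction rate laws.

Expected values are hand substitutions into the printed kinetic forms
(e.g. PEMT at SAM = Km with saturating PE gives half-maximal SAM term
times the PE prefactor).
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from onecarbon import (
    RegulationSwitches,
    male_parameters,
    v_bah,
    v_bhmt,
    v_cbs,
    v_chox,
    v_gnmt,
    v_pemt,
    v_phld,
    v_sms,
)
from onecarbon.model import (
    bhmt_betaine_factor,
    bhmt_sam_sah_factor,
    cbs_betaine_factor,
    cbs_sam_sah_factor,
    gnmt_5mthf_factor,
)

SW = RegulationSwitches()
SW_OFF = RegulationSwitches(**{f: False for f in RegulationSwitches().__dict__})


@pytest.fixture(scope="module")
def p():
    return male_parameters()


class TestPEMT:
    def test_zero_substrate(self, p):
        assert v_pemt(0.0, 5.0, 5000.0, p) == 0.0
        assert v_pemt(10.0, 5.0, 0.0, p) == 0.0

    def test_half_saturation_no_inhibitor(self, p):
        # (98*18.2/36.4) * (25*5000/10000) = 49 * 12.5
        assert v_pemt(18.2, 0.0, 5000.0, p) == pytest.approx(612.5)

    def test_sah_at_ki_halves_rate(self, p):
        assert v_pemt(18.2, 3.8, 5000.0, p) == pytest.approx(306.25)

    def test_negative_input_rejected(self, p):
        with pytest.raises(ValueError):
            v_pemt(-1.0, 0.0, 5000.0, p)


@pytest.mark.parametrize(
    "fn,km,vmax",
    [
        (v_sms, 20.0, 30.0),
        (v_phld, 400.0, 525.0),
        (v_chox, 200.0, 125.0),
        (v_bah, 250.0, 45.0),
    ],
    ids=["SMS", "PhL-D", "ChOx", "BAH"],
)
class TestSimpleMM:
    def test_zero_substrate(self, fn, km, vmax, p):
        assert fn(0.0, p) == 0.0

    def test_half_saturation_at_km(self, fn, km, vmax, p):
        assert fn(km, p) == pytest.approx(vmax / 2.0)

    def test_saturation_asymptote(self, fn, km, vmax, p):
        assert fn(1e9, p) == pytest.approx(vmax, rel=1e-5)

    def test_negative_input_rejected(self, fn, km, vmax, p):
        with pytest.raises(ValueError):
            fn(-0.1, p)


class TestSimpleMMValues:
    """Hand-substituted intermediate points of the MM laws."""

    def test_phld_at_1200(self, p):
        assert v_phld(1200.0, p) == pytest.approx(525 * 1200 / 1600)

    def test_chox_at_60(self, p):
        assert v_chox(60.0, p) == pytest.approx(125 * 60 / 260)

    def test_bah_at_750(self, p):
        assert v_bah(750.0, p) == pytest.approx(45 * 750 / 1000)


class TestBHMT:
    def test_zero_substrate(self, p):
        assert v_bhmt(0.0, 315.0, 29.03, 3.27, p, SW) == 0.0

    def test_normal_state_regulation_factors_are_one(self, p):
        # hcy at its Km, betaine/(Km+betaine) = 315/2315, both
        # regulation factors exactly 1 at SAM+SAH = 32.3, Bet = 315
        v = v_bhmt(12.0, 315.0, 29.0, 3.3, p, SW)
        assert v == pytest.approx(p.bhmt_vmax * 0.5 * 315 / 2315)

    def test_all_switches_off_double_half_saturation(self, p):
        v = v_bhmt(12.0, 2000.0, 100.0, 50.0, p, SW_OFF)
        assert v == pytest.approx(p.bhmt_vmax * 0.25)

    def test_factor_normalization(self, p):
        assert bhmt_sam_sah_factor(29.0, 3.3, p) == pytest.approx(1.0)
        assert bhmt_betaine_factor(315.0, p) == pytest.approx(1.0)

    def test_betaine_factor_unclamped_below_reference(self, p):
        # slope 16% per reference betaine: value 0.84 at Bet = 0
        assert bhmt_betaine_factor(0.0, p) == pytest.approx(0.84)

    def test_negative_input_rejected(self, p):
        with pytest.raises(ValueError):
            v_bhmt(1.0, -5.0, 29.0, 3.3, p, SW)


class TestCBS:
    def test_half_saturation_at_normal_regulators(self, p):
        v = v_cbs(1000.0, 29.0, 3.3, 315.0, p, SW)
        assert v == pytest.approx(p.cbs_vmax / 2.0)

    def test_betaine_term_is_one_below_reference(self, p):
        assert cbs_betaine_factor(200.0, p) == 1.0
        assert cbs_betaine_factor(315.0, p) == 1.0  # H(0) = 0

    def test_betaine_term_continuous_at_reference(self, p):
        eps = 1e-9
        assert cbs_betaine_factor(315.0 + eps, p) == pytest.approx(1.0, abs=1e-9)

    def test_betaine_term_supremum(self, p):
        assert cbs_betaine_factor(1e12, p) == pytest.approx(1.2, rel=1e-9)

    def test_betaine_term_monotone(self, p):
        grid = [0, 100, 315, 320, 400, 600, 1000, 5000]
        vals = [cbs_betaine_factor(b, p) for b in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v <= 1.2 for v in vals)

    def test_sam_sah_factor_normalization(self, p):
        assert cbs_sam_sah_factor(29.03, 3.27, p) == pytest.approx(1.0)

    def test_negative_input_rejected(self, p):
        with pytest.raises(ValueError):
            v_cbs(-1.0, 29.0, 3.3, 315.0, p, SW)


class TestGNMT:
    def test_no_inhibitor_multiplier_is_one(self, p):
        assert gnmt_5mthf_factor(0.0, p) == 1.0

    def test_multiplier_vanishes_at_saturating_inhibitor(self, p):
        assert gnmt_5mthf_factor(1e12, p) == pytest.approx(0.0, abs=1e-9)

    def test_multiplier_non_increasing(self, p):
        grid = [0.0, 0.1, 0.5, 1.0, 5.0, 20.0, 100.0]
        vals = [gnmt_5mthf_factor(f, p) for f in grid]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_switch_off_equals_uninhibited(self, p):
        sw_off = SW.with_flag("gnmt_inhibition_by_5mthf", False)
        for f5 in (0.0, 3.0, 50.0):
            assert v_gnmt(29.0, 3.3, f5, p, sw_off) == pytest.approx(
                v_gnmt(29.0, 3.3, 0.0, p, SW)
            )

    def test_negative_input_rejected(self, p):
        with pytest.raises(ValueError):
            v_gnmt(29.0, 3.3, -2.0, p, SW)


class TestSwitchAblation:
    """Disabling a flag replaces exactly one multiplicative factor by 1."""

    def test_bhmt_factors_ablate_independently(self, p):
        hcy, bet, sam, sah = 5.0, 500.0, 40.0, 6.0
        base_mm = (p.bhmt_vmax * hcy * bet
                   / ((p.bhmt_km_hcy + hcy) * (p.bhmt_km_bet + bet)))
        f_inh = bhmt_sam_sah_factor(sam, sah, p)
        f_act = bhmt_betaine_factor(bet, p)
        assert v_bhmt(hcy, bet, sam, sah, p, SW) == pytest.approx(base_mm * f_inh * f_act)
        sw = SW.with_flag("bhmt_inhibition_by_sam_sah", False)
        assert v_bhmt(hcy, bet, sam, sah, p, sw) == pytest.approx(base_mm * f_act)
        sw = SW.with_flag("bhmt_activation_by_betaine", False)
        assert v_bhmt(hcy, bet, sam, sah, p, sw) == pytest.approx(base_mm * f_inh)

    def test_cbs_factors_ablate_independently(self, p):
        hcy, sam, sah, bet = 5.0, 40.0, 6.0, 500.0
        mm = p.cbs_vmax * hcy / (p.cbs_km_hcy + hcy)
        f_ss = cbs_sam_sah_factor(sam, sah, p)
        f_b = cbs_betaine_factor(bet, p)
        assert v_cbs(hcy, sam, sah, bet, p, SW) == pytest.approx(mm * f_ss * f_b)
        sw = SW.with_flag("cbs_activation_by_sam_sah", False)
        assert v_cbs(hcy, sam, sah, bet, p, sw) == pytest.approx(mm * f_b)
        sw = SW.with_flag("cbs_activation_by_betaine", False)
        assert v_cbs(hcy, sam, sah, bet, p, sw) == pytest.approx(mm * f_ss)


@settings(derandomize=True, max_examples=40)
@given(x=st.floats(min_value=0.0, max_value=1e5),
       dx=st.floats(min_value=1e-3, max_value=1e3))
def test_mm_rates_monotone_in_substrate(x, dx):
    """Every single-substrate MM law is nondecreasing on [0, inf)."""
    p = male_parameters()
    for fn in (v_sms, v_phld, v_chox, v_bah):
        assert fn(x + dx, p) >= fn(x, p) - 1e-9


@settings(derandomize=True, max_examples=40)
@given(hcy=st.floats(min_value=0.0, max_value=1e4),
       dh=st.floats(min_value=1e-3, max_value=1e3))
def test_bhmt_cbs_monotone_in_homocysteine(hcy, dh):
    p = male_parameters()
    assert v_bhmt(hcy + dh, 315.0, 29.0, 3.3, p, SW) >= \
        v_bhmt(hcy, 315.0, 29.0, 3.3, p, SW) - 1e-9
    assert v_cbs(hcy + dh, 29.0, 3.3, 315.0, p, SW) >= \
        v_cbs(hcy, 29.0, 3.3, 315.0, p, SW) - 1e-9


@settings(derandomize=True, max_examples=30)
@given(sam=st.floats(min_value=1e-3, max_value=500.0),
       sah=st.floats(min_value=0.0, max_value=50.0),
       f5=st.floats(min_value=0.0, max_value=50.0))
def test_rates_finite_and_nonnegative(sam, sah, f5):
    p = male_parameters()
    for v in (v_pemt(sam, sah, p.pe, p),
              v_gnmt(sam, sah, f5, p, SW),
              v_bhmt(1.0, 300.0, sam, sah, p, SW),
              v_cbs(1.0, sam, sah, 300.0, p, SW)):
        assert math.isfinite(v) and v >= 0.0
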