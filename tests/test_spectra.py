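"""Energy spectra, windows, decay arithmetic."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import bremspect as bs
from bremspect.errors import (
    AlignmentError,
    DegenerateInputError,
    DomainError,
)
from bremspect.spectra import (
    ENERGY_CENTERS_KEV,
    N_BINS,
    SubtractionResult,
    load_spectrum,
    save_spectrum,
)

W_LOW, W_MID, W_HIGH = bs.STUDY_WINDOWS


class TestBroadening:
    def test_zero_width_response_is_identity(self):
        tc = bs.technetium99m()
        out = bs.detected_spectrum(tc, bs.DetectorEnergyResponse(0.0))
        np.testing.assert_array_equal(out, tc.emission_spectrum)

    def test_broadened_line_fwhm(self):
        """A pure 140.5 keV line broadened at 9.9% FWHM measures ~13.9 keV."""
        line = np.zeros(N_BINS)
        line[np.argmin(np.abs(ENERGY_CENTERS_KEV - 140.5))] = 1.0
        iso = bs.IsotopeModel("line", 6.0, line, 1.0)
        out = bs.detected_spectrum(iso, bs.DetectorEnergyResponse(9.9))
        half = out.max() / 2.0
        above = np.where(out >= half)[0]
        # interpolate the half-maximum crossings
        lo, hi = above[0], above[-1]
        e = ENERGY_CENTERS_KEV

        def cross(i, j):
            return e[i] + (half - out[i]) * (e[j] - e[i]) / (out[j] - out[i])

        fwhm = cross(hi, hi + 1) - cross(lo, lo - 1)
        assert fwhm == pytest.approx(13.9, abs=0.2)

    def test_normalization_preserved(self):
        for iso in (bs.yttrium90(), bs.technetium99m()):
            out = bs.detected_spectrum(iso, bs.DetectorEnergyResponse(9.9))
            assert out.sum() == pytest.approx(1.0, abs=1e-9)
            assert iso.emission_spectrum.sum() == pytest.approx(1.0, abs=1e-9)


class TestWindowFraction:
    def test_full_range_window_is_one(self):
        y90 = bs.yttrium90()
        full = bs.EnergyWindow(20.0, 400.0)
        assert bs.window_fraction(y90.emission_spectrum, full) == pytest.approx(1.0)

    def test_disjoint_windows_sum_below_one(self):
        spec = bs.detected_spectrum(bs.technetium99m(), bs.DetectorEnergyResponse())
        total = sum(bs.window_fraction(spec, w) for w in bs.STUDY_WINDOWS)
        assert total <= 1.0

    def test_window_outside_range_raises(self):
        with pytest.raises(DomainError):
            bs.window_fraction(bs.yttrium90().emission_spectrum, bs.EnergyWindow(10.0, 50.0))

    @given(st.floats(min_value=5.0, max_value=15.0))
    def test_tc_window_ordering_for_any_resolution(self, fwhm_pct):
        """99mTc counts: 90-120 > 160-200 > 200-250 keV for FWHM in [5%, 15%]."""
        spec = bs.detected_spectrum(bs.technetium99m(), bs.DetectorEnergyResponse(fwhm_pct))
        f_low = bs.window_fraction(spec, W_LOW)
        f_mid = bs.window_fraction(spec, W_MID)
        f_high = bs.window_fraction(spec, W_HIGH)
        assert f_low > f_mid > f_high


class TestComposeSubtract:
    def test_single_component_identity(self):
        y90 = bs.yttrium90()
        out = bs.compose_dual_spectrum([(y90, 1.0)])
        np.testing.assert_allclose(out, y90.emission_spectrum, atol=1e-15)

    def test_dual_is_binwise_weighted_sum(self):
        y90, tc = bs.yttrium90(), bs.technetium99m()
        dual = bs.compose_dual_spectrum([(y90, 1.0), (tc, 0.13)])
        np.testing.assert_allclose(
            dual, y90.emission_spectrum + 0.13 * tc.emission_spectrum, atol=1e-15
        )

    def test_subtraction_recovers_component_exactly(self):
        y90, tc = bs.yttrium90(), bs.technetium99m()
        dual = bs.compose_dual_spectrum([(y90, 1.0), (tc, 0.13)])
        res = bs.subtract_component(dual, y90.emission_spectrum, 1.0)
        assert res.clipped_mass == 0.0
        assert np.max(np.abs(res.spectrum - 0.13 * tc.emission_spectrum)) < 1e-12

    def test_overestimated_weight_reports_clipped_mass(self):
        y90, tc = bs.yttrium90(), bs.technetium99m()
        dual = bs.compose_dual_spectrum([(y90, 1.0), (tc, 0.13)])
        res = bs.subtract_component(dual, y90.emission_spectrum, 1.5)
        assert res.clipped_mass > 0
        assert res.spectrum.min() == 0.0

    def test_grid_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            bs.subtract_component(np.ones(N_BINS), np.ones(N_BINS - 1), 1.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(DegenerateInputError):
            bs.compose_dual_spectrum([(bs.yttrium90(), 0.0)])


class TestDecay:
    def test_zero_dt_unchanged(self):
        s = bs.ActivityState("Tc99m", 100.0)
        assert bs.decay_correct(s, 0.0).activity_mbq == 100.0

    def test_half_life_halves(self):
        s = bs.ActivityState("Tc99m", 100.0)
        out = bs.decay_correct(s, 6.007)
        assert out.activity_mbq == pytest.approx(50.0, rel=1e-12)

    def test_same_day_scenario_value(self):
        """180 MBq 99mTc decayed 3 h -> 127.33 MBq (closed form)."""
        out = bs.decay_correct(bs.ActivityState("Tc99m", 180.0), 3.0)
        assert out.activity_mbq == pytest.approx(127.33, abs=0.05)

    @given(
        st.floats(min_value=0.0, max_value=50.0),
        st.floats(min_value=0.0, max_value=50.0),
    )
    def test_decay_is_multiplicative(self, t1, t2):
        s = bs.ActivityState("Y90", 1000.0)
        a = bs.decay_correct(bs.decay_correct(s, t1), t2).activity_mbq
        b = bs.decay_correct(s, t1 + t2).activity_mbq
        assert a == pytest.approx(b, rel=1e-12)

    def test_negative_dt_rejected(self):
        with pytest.raises(DomainError):
            bs.decay_correct(bs.ActivityState("Y90", 1.0), -1.0)


class TestPercentContamination:
    @pytest.mark.parametrize(
        "tc_mbq, y90_gbq, expected",
        [(189.0, 3.1, 6), (376.0, 3.0, 13), (450.0, 3.1, 15), (165.0, 3.1, 5), (0.0, 3.2, 0)],
    )
    def test_schedule_percentages(self, tc_mbq, y90_gbq, expected):
        res = bs.percent_contamination(
            bs.ActivityState("Tc99m", tc_mbq),
            bs.ActivityState("Y90", y90_gbq * 1000.0),
        )
        assert res.rounded == expected

    def test_zero_y90_rejected(self):
        with pytest.raises(DomainError):
            bs.percent_contamination(
                bs.ActivityState("Tc99m", 1.0), bs.ActivityState("Y90", 0.0)
            )


def test_spectrum_text_roundtrip(tmp_path):
    spec = bs.detected_spectrum(bs.yttrium90(), bs.DetectorEnergyResponse())
    path = tmp_path / "y90.txt"
    save_spectrum(path, spec)
    np.testing.assert_allclose(load_spectrum(path), spec, rtol=1e-6)
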