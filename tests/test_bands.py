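"""Trapezoidal-baseline band integration and the parameter registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from hippospec import bands, io


def gaussian(wn, center, sigma, amp=1.0):
    return amp * np.exp(-0.5 * ((wn - center) / sigma) ** 2)


def corrected_area_oracle(center, sigma, lo, hi, wn, hw):
    """Adaptive quadrature of the same baseline-corrected Gaussian.

    Re-derives the anchor points (mean wavenumber / mean absorbance over
    the anchor channels) with independent arithmetic, then integrates the
    continuous corrected function between the first and last channel
    inside the window with scipy.integrate.quad.
    """
    f = lambda w: math.exp(-0.5 * ((w - center) / sigma) ** 2)
    inside = wn[(wn >= lo) & (wn <= hi)]
    a, b = inside[0], inside[-1]
    anchors = []
    for edge in (lo, hi):
        ch = wn[(wn >= edge - hw) & (wn <= edge + hw)]
        anchors.append((ch.mean(), sum(f(w) for w in ch) / ch.size))
    (x0, y0), (x1, y1) = anchors
    slope = (y1 - y0) / (x1 - x0)
    g = lambda w: f(w) - (y0 + slope * (w - x0))
    val, err = quad(g, a, b, epsabs=1e-12, limit=400)
    return val


class TestIntegrateBand:
    def test_linear_spectrum_integrates_to_zero(self):
        wn = np.arange(1000.0, 1500.0, 2.0)
        band = bands.BandDefinition("b", (1100.0, 1300.0))
        area = bands.integrate_band(0.01 * wn - 3.0, wn, band)
        assert abs(area) < 1e-9

    @settings(deadline=None, max_examples=25)
    @given(
        slope=st.floats(-0.05, 0.05),
        intercept=st.floats(-2.0, 2.0),
        amp=st.floats(0.1, 3.0),
    )
    def test_affine_offset_invariance(self, slope, intercept, amp):
        """Adding any affine function of wavenumber leaves the area unchanged."""
        wn = np.arange(1000.0, 1500.0, 2.0)
        spec = gaussian(wn, 1200.0, 12.0, amp)
        band = bands.BandDefinition("b", (1150.0, 1250.0))
        base = bands.integrate_band(spec, wn, band)
        shifted = bands.integrate_band(spec + slope * wn + intercept, wn, band)
        assert shifted == pytest.approx(base, abs=1e-8 * max(1.0, abs(base)))

    def test_wide_window_recovers_closed_form(self):
        """Unit Gaussian, sigma 10, +-60 window: area = sigma*sqrt(2*pi)."""
        wn = np.arange(1000.0, 1500.0, 1.0)
        spec = gaussian(wn, 1250.0, 10.0)
        band = bands.BandDefinition("b", (1190.0, 1310.0))
        area = bands.integrate_band(spec, wn, band)
        assert area == pytest.approx(10.0 * math.sqrt(2 * math.pi), rel=1e-6)

    def test_height_mode(self):
        wn = np.arange(1000.0, 1500.0, 1.0)
        spec = gaussian(wn, 1250.0, 10.0)
        band = bands.BandDefinition("b", (1190.0, 1310.0), mode="height")
        assert bands.integrate_band(spec, wn, band) == pytest.approx(1.0, rel=1e-6)

    def test_matches_quadrature_oracle_on_random_draws(self, rng):
        """>=100 random (center, width, window) draws agree to 1e-6 relative."""
        wn = np.arange(800.0, 2000.0, 0.02)
        worst = 0.0
        for _ in range(100):
            sigma = rng.uniform(8.0, 30.0)
            center = rng.uniform(1100.0, 1700.0)
            half = rng.uniform(2.0, 5.0) * sigma
            lo = wn[np.searchsorted(wn, center - half)]
            hi = wn[np.searchsorted(wn, center + half)]
            band = bands.BandDefinition("b", (lo, hi))
            got = bands.integrate_band(gaussian(wn, center, sigma), wn, band)
            want = corrected_area_oracle(center, sigma, lo, hi, wn, band.anchor_halfwidth)
            worst = max(worst, abs(got - want) / abs(want))
        assert worst < 1e-6

    def test_linearity_in_spectrum(self, rng):
        wn = np.arange(1000.0, 1500.0, 2.0)
        band = bands.BandDefinition("b", (1100.0, 1400.0))
        s1 = gaussian(wn, 1200.0, 15.0)
        s2 = gaussian(wn, 1320.0, 9.0, 0.5) + 0.002 * wn
        a, b = 2.5, -0.7
        lhs = bands.integrate_band(a * s1 + b * s2, wn, band)
        rhs = a * bands.integrate_band(s1, wn, band) + b * bands.integrate_band(s2, wn, band)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_trapezoid_error_shrinks_quadratically(self):
        """Against the quadrature oracle the error falls ~4x per step halving."""
        center, sigma = 1250.0, 20.0
        errs = []
        for step in (4.0, 2.0, 1.0):
            wn = np.arange(1000.0, 1500.0 + step, step)
            lo = wn[np.searchsorted(wn, center - 1.5 * sigma)]
            hi = wn[np.searchsorted(wn, center + 1.5 * sigma)]
            band = bands.BandDefinition("b", (lo, hi), anchor_halfwidth=0.0)
            got = bands.integrate_band(gaussian(wn, center, sigma), wn, band)
            want = corrected_area_oracle(center, sigma, lo, hi, wn, 1e-9)
            errs.append(abs(got - want))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.25)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.25)

    def test_window_outside_axis_rejected(self):
        wn = np.arange(1000.0, 1500.0, 2.0)
        with pytest.raises(bands.DomainError):
            bands.integrate_band(np.zeros_like(wn), wn, bands.BandDefinition("b", (900.0, 1100.0)))

    def test_too_few_channels_rejected(self):
        wn = np.arange(1000.0, 1500.0, 100.0)
        with pytest.raises(bands.ResolutionError):
            bands.integrate_band(np.zeros_like(wn), wn, bands.BandDefinition("b", (1010.0, 1090.0)))


class TestRegistry:
    def test_default_parameter_set_matches_band_table(self):
        """6 absolute bands/massifs + 11 ratios, nominal centers in-window."""
        reg = bands.default_registry()
        assert len(reg) == 17
        absolute = {n for n, s in reg.items() if not s.is_ratio}
        assert absolute == {"1658", "2800-3000", "1080", "1240", "1360-1480", "1740"}
        ratios = {n for n, s in reg.items() if s.is_ratio}
        assert ratios == {
            "1635/1658", "2924/2955",
            "2800-3000/1658", "1080/1658", "1240/1658", "1740/1658",
            "1360-1480/1658", "1080/2800-3000", "1240/2800-3000",
            "1740/2800-3000", "1360-1480/2800-3000",
        }
        nominal = {
            "amide_I": 1658, "beta_1635": 1635, "ch2_2924": 2924,
            "ch3_2955": 2955, "phosphate_1080": 1080, "phosphate_1240": 1240,
            "ester_1740": 1740, "lipid_massif": 2900, "chol_massif": 1420,
        }
        for name, b in bands.default_bands().items():
            lo, hi = b.window
            assert lo < nominal[name] < hi

    def test_amide_subband_windows_disjoint(self):
        b = bands.default_bands()
        assert b["beta_1635"].window[1] < b["amide_I"].window[0]

    def test_unknown_parameter_lookup(self):
        with pytest.raises(KeyError, match="unknown parameter"):
            bands.get_parameter("9999")

    def test_yaml_registry_override(self, tmp_path):
        cfg = tmp_path / "reg.yaml"
        cfg.write_text(
            "bands:\n"
            "  amide_I: {window: [1640, 1676], anchor_halfwidth: 4}\n"
        )
        reg = bands.registry_from_yaml(cfg)
        assert len(reg) == 17
        assert reg["1658"].numerator.window == (1640.0, 1676.0)
        assert reg["1635/1658"].denominator.anchor_halfwidth == 4.0


def _toy_map(rng, spectrum=None):
    wn = np.arange(900.0, 2000.0, 4.0)
    if spectrum is None:
        spectrum = gaussian(wn, 1658.0, 2.5) + gaussian(wn, 1635.0, 2.5, 0.4)
    cube = np.tile(spectrum, (3, 4, 1))
    return io.SpectralMap(cube, wn)


class TestComputeParameter:
    def test_self_ratio_is_one(self, rng):
        smap = _toy_map(rng)
        amide = bands.default_bands()["amide_I"]
        spec = bands.ParameterSpec("self", amide, amide)
        cm = bands.compute_parameter(smap, spec)
        assert cm.valid.all()
        np.testing.assert_allclose(cm.values, 1.0)

    def test_zero_denominator_all_invalid_no_nan(self, rng):
        wn = np.arange(900.0, 2000.0, 4.0)
        smap = _toy_map(rng, spectrum=np.zeros_like(wn))
        reg = bands.default_registry()
        cm = bands.compute_parameter(smap, reg["1635/1658"])
        assert not cm.valid.any()
        assert np.isfinite(cm.values).all()
        assert (cm.values == 0).all()

    def test_shape_matches_source(self, rng):
        cm = bands.compute_parameter(_toy_map(rng), bands.default_registry()["1658"])
        assert cm.values.shape == (3, 4)


class TestTissueMask:
    def test_threshold_zero_all_tissue(self, rng):
        assert bands.tissue_mask(_toy_map(rng), 0.0).all()

    def test_above_maximum_empty_with_warning(self, rng):
        with pytest.warns(UserWarning, match="empty"):
            mask = bands.tissue_mask(_toy_map(rng), 1e9)
        assert not mask.any()

    def test_phantom_background_excluded(self, clean_config):
        from hippospec import synthetic

        smap, lmask, _ = synthetic.make_phantom(clean_config, group="N")
        tissue = bands.tissue_mask(smap, 0.5)
        np.testing.assert_array_equal(tissue, lmask.labels > 0)

    def test_negative_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            bands.tissue_mask(_toy_map(rng), -1.0)
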