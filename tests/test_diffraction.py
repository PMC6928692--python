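"""Meridional diffraction: lattice-sum oracle, shift/dilation laws, beam
convolution, order-dependent broadening."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myoxray as mx


def dirichlet_intensity(Z, N, h):
    """Closed-form |sin(N pi Z h)/sin(pi Z h)|^2 for a uniform lattice of N
    point scatterers at spacing h (finite-lattice oracle)."""
    num = np.sin(N * np.pi * Z * h)
    den = np.sin(np.pi * Z * h)
    out = np.empty_like(Z)
    small = np.abs(den) < 1e-12
    out[~small] = (num[~small] / den[~small]) ** 2
    out[small] = N**2
    return out


class TestLatticeSum:
    def test_uniform_filament_matches_closed_form(self):
        z = mx.uniform_filament(364, 2.73)
        grid = np.linspace(0.30, 0.78, 20001)
        prof = mx.meridional_intensity([z], grid)
        ref = dirichlet_intensity(grid, 364, 2.73)
        np.testing.assert_allclose(prof.intensity, ref, rtol=1e-8, atol=1e-4)

    def test_on_peak_intensity_is_n_squared(self):
        z = mx.uniform_filament(364, 2.73)
        for order in (1, 2, 3):
            grid = np.array([order / 2.73 - 1e-5, order / 2.73, order / 2.73 + 1e-5])
            prof = mx.meridional_intensity([z], grid)
            assert prof.intensity[1] == pytest.approx(364**2, rel=1e-9)

    def test_fast_uniform_grid_path_matches_direct_sum(self):
        rng = np.random.default_rng(2)
        sets = rng.normal(0, 1, size=(12, 50)).cumsum(axis=1) * 0.1 + \
            np.arange(50) * 2.73
        grid = mx.order_window_grid(1, 2.73, points_per_percent=400)
        fast = mx.meridional_intensity(list(sets), grid)     # kernel path
        slow = np.zeros_like(grid)
        for z in sets:
            A = np.exp(2j * np.pi * grid[:, None] * z[None, :]).sum(axis=1)
            slow += np.abs(A) ** 2
        np.testing.assert_allclose(fast.intensity, slow, rtol=1e-9)

    def test_rigid_translation_invariance(self):
        z = mx.uniform_filament(100, 2.73)
        grid = mx.order_window_grid(1, 2.73, points_per_percent=200)
        a = mx.meridional_intensity([z], grid)
        b = mx.meridional_intensity([z + 5.0], grid)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-9,
                                   atol=1e-8 * a.intensity.max())

    def test_incoherent_additivity_exact(self):
        rng = np.random.default_rng(0)
        z1 = mx.uniform_filament(80, 2.73)
        z2 = z1 + rng.normal(0, 0.1, 80)
        grid = mx.order_window_grid(1, 2.73, points_per_percent=100)
        both = mx.meridional_intensity([z1, z2], grid)
        one = mx.meridional_intensity([z1], grid)
        two = mx.meridional_intensity([z2], grid)
        np.testing.assert_allclose(both.intensity, one.intensity + two.intensity,
                                   rtol=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            mx.meridional_intensity([], np.linspace(0.3, 0.4, 10))
        with pytest.raises(ValueError):
            mx.meridional_intensity([np.arange(5.0)], np.array([0.4, 0.3]))


class TestOrderWindows:
    @pytest.mark.parametrize("order,center,spacing", [
        (1, 0.36630, 2.73),
        (2, 0.73260, 1.365),
        (3, 1.09890, 0.91),
    ])
    def test_reflection_positions(self, order, center, spacing):
        z_lo, z_hi = mx.peak_order_window(order, 2.73)
        c = 0.5 * (z_lo + z_hi)
        assert c == pytest.approx(center, abs=1e-4)
        assert 1.0 / c == pytest.approx(spacing, abs=1e-3)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            mx.peak_order_window(0, 2.73)


class TestDilationLaw:
    @given(st.floats(5e-4, 5e-3))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_strain_recovered_from_peak_shift(self, eps):
        """Uniform dilation h -> h(1+eps) moves the order-n peak to
        n/(h(1+eps)); recovered strain matches to 1e-4."""
        h = 2.73
        for order in (1, 2):
            grid = mx.order_window_grid(order, h, points_per_percent=3000)
            base = mx.meridional_intensity([mx.uniform_filament(364, h)], grid)
            dil = mx.meridional_intensity(
                [mx.uniform_filament(364, h * (1 + eps))], grid)
            m0 = mx.peak_top_half_centroid(base, order=order)
            m1 = mx.peak_top_half_centroid(dil, order=order)
            rec = m1.spacing / m0.spacing - 1.0
            assert rec == pytest.approx(eps, abs=1e-4)


class TestBeamConvolution:
    def _gauss_profile(self, fwhm, center=0.3663, span=0.03, n=3001):
        Z = np.linspace(center - span, center + span, n)
        sig = fwhm / (2 * np.sqrt(2 * np.log(2)))
        return mx.MeridionalProfile(Z, np.exp(-0.5 * ((Z - center) / sig) ** 2))

    def test_integral_conserved(self):
        prof = self._gauss_profile(0.002)
        out = mx.convolve_beam(prof, mx.BeamModel(0.003))
        dz = prof.Z[1] - prof.Z[0]
        assert np.trapezoid(out.intensity, dx=dz) == pytest.approx(
            np.trapezoid(prof.intensity, dx=dz), rel=1e-6)
        assert out.intensity.max() < prof.intensity.max()

    def test_delta_peak_acquires_beam_width(self):
        Z = np.linspace(0.35, 0.39, 8001)
        I = np.zeros_like(Z)
        I[4000] = 1.0
        out = mx.convolve_beam(mx.MeridionalProfile(Z, I), mx.BeamModel(0.004))
        m = mx.peak_top_half_centroid(out, order=1)
        assert m.fwhm_Z == pytest.approx(0.004, rel=0.01)

    def test_gaussian_widths_add_in_quadrature(self):
        a, b = 0.0025, 0.0035
        prof = self._gauss_profile(a, n=6001)
        out = mx.convolve_beam(prof, mx.BeamModel(b))
        m = mx.peak_top_half_centroid(out, order=1)
        assert m.fwhm_Z == pytest.approx(np.sqrt(a**2 + b**2), rel=0.01)

    def test_coarse_grid_rejected(self):
        Z = np.linspace(0.3, 0.4, 51)
        prof = mx.MeridionalProfile(Z, np.ones_like(Z))
        with pytest.raises(ValueError, match="coarse"):
            mx.convolve_beam(prof, mx.BeamModel(0.004))


class TestOrderSensitivity:
    def test_cumulative_spacing_disorder_broadens_higher_orders_more(self):
        """Random segment-wise spacing jitter (disorder of the second kind)
        broadens order 2 more than order 1, relative to the peak position."""
        rng = np.random.default_rng(4)
        sets = []
        # 3% segment jitter: cumulative disorder beats the 1/n finite-size
        # width from order 2 on
        for _ in range(40):
            spacing = 2.73 * (1 + rng.normal(0, 0.03, 363))
            sets.append(np.concatenate([[0.0], np.cumsum(spacing)]))
        rel = {}
        for order in (1, 2):
            grid = mx.order_window_grid(order, 2.73, halfwidth=0.06,
                                        points_per_percent=400)
            prof = mx.meridional_intensity(sets, grid)
            m = mx.peak_top_half_centroid(prof, order=order)
            rel[order] = m.fwhm_Z / m.Z_center
        assert rel[2] > rel[1]
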