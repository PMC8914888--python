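"""Reconstruction chain: denoising, unwrapping, SHARP, inversion, R2*."""

import numpy as np
import pytest

from dnqsm.containers import EchoSeries, FrequencyMap, TissueFieldMap
from dnqsm.phantom import forward_field, make_dentate_phantom, make_sphere_chi
from dnqsm.recon import (
    InversionConfig,
    SharpConfig,
    denoise_complex,
    echoes_to_frequency,
    fit_r2star,
    invert_dipole,
    reconstruct_chi,
    reference_chi,
    sharp_remove_background,
    unwrap_phase_3d,
)
from tests.conftest import small_phantom_spec


def _echoes_from(mag, phase, tes=(0.006, 0.017, 0.028, 0.039)):
    n = len(tes)
    return EchoSeries(np.repeat(mag[None], n, 0), np.repeat(phase[None], n, 0),
                      np.asarray(tes), 1.0)


class TestDenoise:
    def test_zero_strength_is_identity(self, rng):
        mag = rng.uniform(0.5, 1.5, (12, 12, 12))
        phase = rng.uniform(-3.0, 3.0, (12, 12, 12))
        ech = _echoes_from(mag, phase)
        out = denoise_complex(ech, 0.0)
        np.testing.assert_array_equal(out.magnitude, ech.magnitude)
        np.testing.assert_array_equal(out.phase, ech.phase)

    def test_reduces_noise_variance(self, rng):
        mag = 1.0 + 0.1 * rng.standard_normal((16, 16, 16))
        phase = 0.1 * rng.standard_normal((16, 16, 16))
        ech = _echoes_from(mag, phase)
        out = denoise_complex(ech, 0.05)
        assert out.magnitude[0].var() < ech.magnitude[0].var()

    def test_preserves_piecewise_constant_interior(self):
        """Edge-preserving: away from the step edge, a noiseless two-level
        volume passes through nearly unchanged."""
        mag = np.ones((16, 16, 16))
        mag[8:] = 2.0
        ech = _echoes_from(mag, np.zeros_like(mag))
        out = denoise_complex(ech, 0.02)
        interior = np.abs(out.magnitude[0][:5] - 1.0)
        assert interior.max() < 0.01
        interior_hi = np.abs(out.magnitude[0][11:] - 2.0)
        assert interior_hi.max() < 0.01 * 2.0


class TestUnwrap:
    def test_identity_when_no_wraps(self, rng):
        smooth = 0.5 * np.sin(np.linspace(0, 2, 16))[:, None, None] * np.ones((16, 16, 16))
        out = unwrap_phase_3d(smooth)
        np.testing.assert_allclose(out, smooth, atol=1e-9)

    def test_recovers_wrapped_ramp_modulo_2pi(self):
        """A 6-pi linear ramp, stored wrapped, is recovered exactly up to a
        single global 2*pi*k offset."""
        ramp = np.linspace(0, 6 * np.pi, 32)[:, None, None] * np.ones((32, 16, 16))
        wrapped = np.angle(np.exp(1j * ramp))
        out = unwrap_phase_3d(wrapped)
        offset = out - ramp
        k = offset.flat[0] / (2 * np.pi)
        assert k == pytest.approx(round(k), abs=1e-9)
        assert np.abs(offset - offset.flat[0]).max() < 1e-6

    def test_disjoint_components_independently_consistent(self):
        ramp = np.linspace(0, 4 * np.pi, 32)[:, None, None] * np.ones((32, 8, 8))
        wrapped = np.angle(np.exp(1j * ramp))
        mask = np.zeros((32, 8, 8), bool)
        mask[:12] = True
        mask[20:] = True
        out = unwrap_phase_3d(wrapped, mask)
        for sl in (slice(0, 12), slice(20, 32)):
            offset = out[sl] - ramp[sl]
            assert np.abs(offset - offset.flat[0]).max() < 1e-6

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            unwrap_phase_3d(np.zeros((8, 8, 8)), np.zeros((8, 8, 8), bool))


class TestEchoCombination:
    def test_single_echo_analytic_value(self):
        phase = np.full((1, 4, 4, 4), np.pi)
        mag = np.ones_like(phase)
        with pytest.warns(UserWarning, match="single echo"):
            fm = echoes_to_frequency(phase, [0.00647], mag)
        assert fm.single_echo
        np.testing.assert_allclose(fm.data_hz, 1.0 / (2 * 0.00647), rtol=1e-12)

    def test_consistent_echoes_recover_frequency(self, rng):
        tes = np.array([0.00647, 0.01723, 0.02799, 0.03875])
        f = rng.uniform(-40, 40, (6, 6, 6))
        phases = 2 * np.pi * f[None] * tes[:, None, None, None]
        mags = rng.uniform(0.2, 1.0, phases.shape)
        fm = echoes_to_frequency(phases, tes, mags)
        np.testing.assert_allclose(fm.data_hz, f, rtol=1e-9, atol=1e-9)

    def test_zero_phase_gives_zero_frequency(self):
        phases = np.zeros((4, 5, 5, 5))
        fm = echoes_to_frequency(phases, [0.006, 0.017, 0.028, 0.039], np.ones_like(phases))
        assert np.all(fm.data_hz == 0)

    def test_temporal_consistency_fixes_echo_offsets(self):
        """Later echoes missing whole 2-pi turns are realigned before
        combination."""
        tes = np.array([0.00647, 0.01723, 0.02799, 0.03875])
        f = np.full((5, 5, 5), 60.0)
        phases = 2 * np.pi * f[None] * tes[:, None, None, None]
        broken = phases.copy()
        broken[2] -= 2 * np.pi  # a spurious global wrap on echo 3
        fm = echoes_to_frequency(broken, tes, np.ones_like(phases))
        np.testing.assert_allclose(fm.data_hz, 60.0, rtol=1e-9)


def _ellipsoid_mask(shape, radii_vox):
    ax = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    return (gx / radii_vox[0]) ** 2 + (gy / radii_vox[1]) ** 2 + (gz / radii_vox[2]) ** 2 <= 1


class TestSharp:
    def test_constant_field_removed(self):
        mask = _ellipsoid_mask((48, 48, 48), (18, 18, 16))
        field = np.where(mask, 7.5, 0.0)
        fm = FrequencyMap(field, mask, 1.0)
        tis = sharp_remove_background(fm, mask, SharpConfig(radii_voxels=(1, 2, 3, 4, 5)))
        rel = tis.reliability_mask
        assert np.sqrt(np.mean(tis.data_hz[rel] ** 2)) < 1e-6 * 7.5

    def test_harmonic_polynomial_suppressed(self):
        mask = _ellipsoid_mask((48, 48, 48), (18, 18, 16))
        ax = [np.arange(48) - 23.5 for _ in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        field = (gx**2 - gy**2) / 100.0 + 0.3 * gx + 0.2 * gy * gz / 10.0
        fm = FrequencyMap(field, mask, 1.0)
        tis = sharp_remove_background(fm, mask, SharpConfig(radii_voxels=(1, 2, 3, 4, 5)))
        rel = tis.reliability_mask
        rms_in = np.sqrt(np.mean(field[rel] ** 2))
        rms_out = np.sqrt(np.mean(tis.data_hz[rel] ** 2))
        assert rms_out < 0.01 * rms_in

    def test_internal_source_preserved(self):
        """A compact internal dipole source survives SHARP nearly intact."""
        mask = _ellipsoid_mask((64, 64, 64), (26, 26, 24))
        chi = make_sphere_chi((64, 64, 64), 1.0, (0, 0, 0), 4.0, 100.0)
        field = forward_field(chi, 1.0)
        fm = FrequencyMap(field, mask, 1.0)
        tis = sharp_remove_background(fm, mask, SharpConfig())
        rel = tis.reliability_mask
        corr = np.corrcoef(tis.data_hz[rel], field[rel])[0, 1]
        assert corr > 0.95

    def test_idempotence_on_tissue_field(self):
        """Re-running SHARP on its own output changes the RMS by < 1%."""
        mask = _ellipsoid_mask((48, 48, 48), (18, 18, 16))
        chi = make_sphere_chi((48, 48, 48), 1.0, (0, 0, 0), 3.0, 100.0)
        field = forward_field(chi, 1.0)
        cfg = SharpConfig(radii_voxels=(1, 2, 3, 4, 5))
        t1 = sharp_remove_background(FrequencyMap(field, mask, 1.0), mask, cfg)
        t2 = sharp_remove_background(FrequencyMap(t1.data_hz, mask, 1.0), mask, cfg)
        rel = t2.reliability_mask
        rms1 = np.sqrt(np.mean(t1.data_hz[rel] ** 2))
        rms2 = np.sqrt(np.mean(t2.data_hz[rel] ** 2))
        assert abs(rms2 - rms1) / rms1 < 0.01

    def test_oversized_kernel_rejected(self):
        mask = _ellipsoid_mask((24, 24, 24), (4, 4, 4))
        fm = FrequencyMap(np.zeros((24, 24, 24)), mask, 1.0)
        with pytest.raises(ValueError, match="smaller radii"):
            sharp_remove_background(fm, mask, SharpConfig(radii_voxels=(1, 2, 8)))


class TestInversion:
    def test_zero_field_zero_chi(self):
        mask = np.ones((16, 16, 16), bool)
        tis = TissueFieldMap(np.zeros((16, 16, 16)), mask, mask, 1.0)
        chi = invert_dipole(tis)
        assert np.all(chi.data_ppb == 0)

    def test_linearity(self, rng):
        mask = np.ones((16, 16, 16), bool)
        f = rng.standard_normal((16, 16, 16))
        c1 = invert_dipole(TissueFieldMap(f, mask, mask, 1.0))
        c2 = invert_dipole(TissueFieldMap(2 * f, mask, mask, 1.0))
        np.testing.assert_allclose(c2.data_ppb, 2 * c1.data_ppb, rtol=1e-9, atol=1e-9)

    def test_round_trip_recovers_interior_voi_mean(self, default_truth):
        cfg = InversionConfig()
        """forward field -> inversion recovers the mean susceptibility of the
        dentate bulk within 5% (noiseless, no background field)."""
        gt = default_truth
        field = forward_field(gt.chi.data_ppb, 0.5)
        tis = TissueFieldMap(field, gt.brain_mask, gt.brain_mask, 0.5)
        chi = reference_chi(invert_dipole(tis, cfg), gt.brain_mask)
        truth = gt.chi.data_ppb - gt.chi.data_ppb[gt.brain_mask].mean()
        bulk = gt.dn_bulk_true.mask
        assert chi.data_ppb[bulk].mean() == pytest.approx(truth[bulk].mean(), rel=0.05)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="tkd_threshold"):
            InversionConfig(method="tkd", tkd_threshold=0.9).validate()


class TestReference:
    def test_constant_map_becomes_zero(self):
        from dnqsm.containers import ChiMap
        mask = np.ones((8, 8, 8), bool)
        chi = reference_chi(ChiMap(np.full((8, 8, 8), 42.0), 1.0), mask)
        assert np.all(np.abs(chi.data_ppb) < 1e-9)

    def test_idempotent_and_zero_mean(self, rng):
        from dnqsm.containers import ChiMap
        mask = rng.random((12, 12, 12)) > 0.4
        chi1 = reference_chi(ChiMap(rng.standard_normal((12, 12, 12)), 1.0), mask)
        assert abs(chi1.data_ppb[mask].mean()) < 1e-9
        chi2 = reference_chi(chi1, mask)
        np.testing.assert_allclose(chi2.data_ppb, chi1.data_ppb, atol=1e-12)

    def test_empty_mask_rejected(self):
        from dnqsm.containers import ChiMap
        with pytest.raises(ValueError, match="empty"):
            reference_chi(ChiMap(np.zeros((4, 4, 4)), 1.0), np.zeros((4, 4, 4), bool))


class TestR2Star:
    def test_noiseless_exact(self):
        shape = (6, 6, 6)
        tes = np.array([0.006, 0.017, 0.028, 0.039])
        mags = np.exp(-20.0 * tes)[:, None, None, None] * np.ones((4,) + shape)
        ech = EchoSeries(mags, np.zeros_like(mags), tes, 1.0)
        r2s = fit_r2star(ech)
        np.testing.assert_allclose(r2s.data, 20.0, atol=1e-8)
        np.testing.assert_allclose(r2s.r_squared, 1.0, atol=1e-12)

    def test_constant_magnitude_gives_zero(self):
        shape = (5, 5, 5)
        mags = np.ones((4,) + shape)
        ech = EchoSeries(mags, np.zeros_like(mags), [0.006, 0.017, 0.028, 0.039], 1.0)
        assert np.all(fit_r2star(ech).data == 0.0)

    def test_zero_magnitude_voxels_marked_nan(self):
        shape = (4, 4, 4)
        mags = np.ones((4,) + shape)
        mags[2, 0, 0, 0] = 0.0
        ech = EchoSeries(mags, np.zeros_like(mags), [0.006, 0.017, 0.028, 0.039], 1.0)
        out = fit_r2star(ech)
        assert np.isnan(out.data[0, 0, 0])
        assert np.isfinite(out.data[1:]).all()

    def test_bias_small_at_snr_50(self, rng):
        """Monte-Carlo: magnitude noise at SNR 50 biases the R2* estimate of
        a 15 1/s decay by less than 5%."""
        tes = np.array([0.00647, 0.01723, 0.02799, 0.03875])
        n = 1000
        sig = np.exp(-15.0 * tes)[:, None]
        noisy = np.abs(sig + (rng.standard_normal((4, n)) + 1j * rng.standard_normal((4, n))) / 50.0)
        ech = EchoSeries(noisy.reshape(4, n, 1, 1), np.zeros((4, n, 1, 1)), tes, 1.0)
        out = fit_r2star(ech)
        assert abs(np.nanmean(out.data) - 15.0) / 15.0 < 0.05

    def test_too_few_echoes_rejected(self):
        mags = np.ones((2, 4, 4, 4))
        ech = EchoSeries(mags, np.zeros_like(mags), [0.006, 0.017], 1.0)
        with pytest.raises(ValueError, match="3 echoes"):
            fit_r2star(ech)


class TestEndToEnd:
    def test_pipeline_linearity_in_chi(self):
        """Scaling the phantom susceptibility scales the reconstruction
        (noiseless), within 1% on the bulk mean."""
        import dataclasses
        from dnqsm.phantom import synthesize_echoes

        spec = small_phantom_spec(background_poly_coeffs={},
                                  external_source_positions_mm=(),
                                  external_source_strengths=())
        cfgs = dict(sharp_cfg=SharpConfig(radii_voxels=(1, 2, 3, 4)))
        means = []
        for scale in (1.0, 2.0):
            sp = dataclasses.replace(
                spec, wall_chi_ppb=100.0 * scale, interior_chi_ppb=20.0 * scale
            )
            gt = make_dentate_phantom(sp)
            s0 = np.where(gt.brain_mask, 1.0, 0.0)
            ech = synthesize_echoes(gt.field_true_hz, s0, gt.r2star_true,
                                    voxel_size_mm=sp.voxel_size_mm)
            chi, _, _ = reconstruct_chi(ech, gt.brain_mask, **cfgs)
            means.append(chi.data_ppb[gt.dn_bulk_true.mask].mean())
        assert means[1] == pytest.approx(2.0 * means[0], rel=0.01)
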