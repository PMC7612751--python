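"""Forward simulation: beamlet sampling, cross-talk, dithering, noise, I/O."""

import numpy as np
import pytest

import eixpct as ei
from eixpct.phantom import ABSORBER, SOFT_TISSUE, PhantomVolume, project_sample, \
    shifted
from eixpct.scanner import (crosstalk_kernel, load_frameset, save_frameset,
                            simulate_dithered_projection, simulate_flat_dark,
                            simulate_frame)


def _uniform_absorber(transmission, geometry, nx=400, dx=2.0):
    """Phantom whose projection is a flat transmission map (no refraction)."""
    t = -np.log(transmission)
    beta_thickness = t * SOFT_TISSUE.beta / SOFT_TISSUE.mu
    d = np.zeros((1, nx, 1))
    b = np.full((1, nx, 1), beta_thickness)
    return PhantomVolume(d, b, spacing=(2.0, dx, 1.0))


class TestSimulateFrame:
    def test_vacuum_equals_i0_ic(self, ic_highres):
        # without cross-talk every used pixel reads exactly I0·IC(s)
        cfg = ei.highres_preset(detector={"crosstalk_fwhm": 0.0})
        s = ic_highres.apex - 9.0
        f = simulate_frame(cfg, None, s, ic=ic_highres)
        i0 = cfg.detector.i0_rate * cfg.acquisition.exposure_time
        expected = i0 * ic_highres.value(s)
        assert f.used_counts == pytest.approx(expected, rel=1e-9)

    def test_vacuum_flat_constant_with_crosstalk(self, highres, ic_highres):
        # cross-talk diverts a fixed fraction into masked columns: the flat
        # stays constant across used columns, below the no-cross-talk level
        s = ic_highres.apex - 9.0
        f = simulate_frame(highres, None, s, ic=ic_highres)
        i0 = highres.detector.i0_rate
        assert np.ptp(f.used_counts) == pytest.approx(0.0, abs=1e-9)
        assert f.used_counts[0, 0] < i0 * ic_highres.value(s)

    def test_pure_absorber_multiplicative(self, highres, ic_highres):
        s = ic_highres.apex - 9.0
        proj = project_sample(_uniform_absorber(0.5, highres.geometry, nx=1500),
                              highres.geometry)
        # interior beamlets (edge beamlets see cross-talk from the vacuum
        # beyond the phantom, one kernel half-width deep)
        f = simulate_frame(highres, proj, s, ic=ic_highres)
        vac = simulate_frame(highres, None, s, ic=ic_highres, like=f)
        inner = slice(5, -5)
        ratio = f.used_counts[0, inner] / vac.used_counts[0, inner]
        assert ratio == pytest.approx(0.5, rel=1e-6)

    def test_wedge_shift_follows_ic(self, highres, ic_highres):
        # uniform beamlet shift Δx: counts scale by IC(s−Δx)/IC(s)
        s = ic_highres.apex - 9.0
        g = 2.0 / highres.geometry.z_od_um  # Δx = +2 µm
        nx, dx = 600, 2.0
        d = (1e-5 + g * np.arange(nx) * dx)[None, :, None]
        vol = PhantomVolume(d, np.full_like(d, 1e-15), spacing=(2.0, dx, 1.0))
        proj = project_sample(vol, highres.geometry)
        proj.fill = "extend"
        f = simulate_frame(highres, proj, s, ic=ic_highres)
        vac = simulate_frame(highres, None, s, ic=ic_highres, like=f)
        inner = slice(2, -2)
        ratio = np.median(f.used_counts[0, inner] / vac.used_counts[0, inner])
        expected = ic_highres.value(s - 2.0) / ic_highres.value(s)
        assert ratio == pytest.approx(expected, rel=1e-3)

    def test_s_outside_table_rejected(self, highres, ic_highres):
        with pytest.raises(ValueError, match="outside"):
            simulate_frame(highres, None, 200.0, ic=ic_highres)

    def test_exposure_linearity(self, highres, ic_highres):
        s = ic_highres.apex - 9.0
        f1 = simulate_frame(highres, None, s, ic=ic_highres, exposure=1.0)
        f3 = simulate_frame(highres, None, s, ic=ic_highres, exposure=3.0)
        assert f3.counts == pytest.approx(3 * f1.counts, rel=1e-12)


class TestCrosstalk:
    def test_kernel_normalised(self, lowres, highres):
        for cfg in (lowres, highres):
            k = crosstalk_kernel(cfg)
            assert k.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.array_equal(k, k[::-1])

    def test_counts_conserved(self, highres, ic_highres):
        s = ic_highres.apex - 9.0
        proj = project_sample(_uniform_absorber(0.7, highres.geometry, nx=1500),
                              highres.geometry)
        with_ct = simulate_frame(highres, proj, s, ic=ic_highres)
        no_ct = simulate_frame(
            ei.highres_preset(detector={"crosstalk_fwhm": 0.0}), proj, s,
            ic=ic_highres, beamlets=with_ct.beamlet_x)
        # deep-interior total (all columns, whole periods) is preserved by
        # the normalised kernel to numerical precision
        assert with_ct.counts[0, 20:-20].sum() == pytest.approx(
            no_ct.counts[0, 20:-20].sum(), rel=1e-10)

    def test_skipped_columns_dark_without_crosstalk(self, ic_highres):
        cfg = ei.highres_preset(detector={"crosstalk_fwhm": 0.0,
                                          "dark_level": 7.0})
        s = ic_highres.apex - 9.0
        f = simulate_frame(cfg, None, s, ic=ic_highres)
        assert np.all(f.counts[:, ~f.used] == 7.0)


class TestDithering:
    def test_single_step_equals_frame(self, highres, ic_highres):
        proj = project_sample(_uniform_absorber(0.8, highres.geometry),
                              highres.geometry)
        s = ic_highres.apex - 9.0
        fs = simulate_dithered_projection(highres, proj, s=s, n_steps=1,
                                          step=0.0, ic=ic_highres)
        direct = simulate_frame(highres, proj, s, ic=ic_highres,
                                beamlets=fs[0].beamlet_x)
        assert np.array_equal(fs[0].counts, direct.counts)

    def test_coverage_warning(self, highres, ic_highres):
        proj = project_sample(_uniform_absorber(0.8, highres.geometry),
                              highres.geometry)
        with pytest.warns(UserWarning, match="coverage"):
            simulate_dithered_projection(highres, proj, n_steps=4, step=10.0,
                                         ic=ic_highres)

    def test_equivariance_shift_one_step(self, highres, ic_highres):
        # translating the phantom by one dither step and acquiring step k
        # equals acquiring step k+1 of the untranslated phantom (interior)
        step = 9.75
        vol = ei.make_strand_phantom(strand_width=39.0, strand_contrast=1.0,
                                     voxel_size=0.75, fov=585.0,
                                     background_radius=200.0)
        base = simulate_dithered_projection(highres, vol, n_steps=8, step=step,
                                            ic=ic_highres)
        moved = simulate_dithered_projection(highres, shifted(vol, step),
                                             n_steps=8, step=step,
                                             ic=ic_highres)
        inner = slice(1, -1)
        for k in range(7):
            a = moved[k].used_counts[0, inner]
            b = base[k + 1].used_counts[0, inner]
            assert a == pytest.approx(b, rel=1e-9)

    def test_full_period_translation_reproduces(self, highres, ic_highres):
        period = highres.beamlet_period
        vol = ei.make_strand_phantom(strand_width=39.0, strand_contrast=1.0,
                                     voxel_size=1.0, fov=624.0,
                                     background_radius=200.0)
        f0 = simulate_dithered_projection(highres, vol, n_steps=1, step=0.0,
                                          ic=ic_highres)[0]
        f1 = simulate_frame(highres, project_sample(vol, highres.geometry),
                            ic_highres.apex - 9.0, dither_offset=period,
                            ic=ic_highres, beamlets=f0.beamlet_x + period)
        # same sample positions sampled one period over: interior equal
        assert f1.used_counts[0, 1:-1] == pytest.approx(
            f0.used_counts[0, 1:-1], rel=1e-9)


class TestCT:
    def test_single_angle_equals_projection(self, highres, ic_highres):
        vol = ei.make_strand_phantom(strand_width=30.0, voxel_size=2.0,
                                     fov=400.0, background_radius=150.0)
        ct = ei.simulate_ct(highres, vol, n_angles=1, n_steps=2, step=39.0)
        direct = simulate_dithered_projection(highres, vol, n_steps=2,
                                              step=39.0, ic=ic_highres)
        assert np.allclose(ct[0].counts, direct[0].counts, rtol=1e-9)

    def test_jitter_offsets_integer_periods(self, highres):
        vol = ei.make_strand_phantom(strand_width=30.0, voxel_size=2.0,
                                     fov=400.0, background_radius=150.0)
        ct = ei.simulate_ct(highres, vol, n_angles=3, jitter="period",
                            jitter_seed=11, n_steps=1, step=0.0)
        period = highres.beamlet_period
        offs = {f.meta["jitter_offset"] for f in ct}
        for o in offs:
            assert o / period == pytest.approx(round(o / period), abs=1e-12)
        assert len(offs) > 1  # seed 11 produces distinct offsets

    def test_symmetric_phantom_half_turn(self, highres, ic_highres):
        vol = ei.make_strand_phantom(strand_width=30.0, strand_contrast=1.0,
                                     strand_offsets=((0.0, 0.0),),
                                     voxel_size=2.0, fov=400.0,
                                     background_radius=150.0)
        ct = ei.simulate_ct(highres, vol, n_angles=2, angular_range=360.0,
                            n_steps=1, step=0.0)
        # centred circularly-symmetric phantom: 180° view equals 0° view
        assert np.allclose(ct[1].used_counts, ct[0].used_counts, rtol=1e-3)


class TestFlatDarkAndNoise:
    def test_noise_free_flat_constant(self, highres, ic_highres):
        flat, dark = simulate_flat_dark(highres, ic=ic_highres)
        vals = flat[0].used_counts
        assert np.ptp(vals) == pytest.approx(0.0, abs=1e-9)

    def test_dark_mean(self, ic_highres):
        cfg = ei.highres_preset(detector={"dark_level": 12.0})
        _, dark = simulate_flat_dark(cfg, ic=ic_highres)
        assert dark[0].counts.mean() == pytest.approx(12.0)

    def test_poisson_variance_matches_mean(self, highres, ic_highres):
        flat, _ = simulate_flat_dark(highres, n_frames=100, noise="poisson",
                                     seed=42, ic=ic_highres)
        stack = np.stack([f.used_counts[0] for f in flat])
        mean = stack.mean()
        var = stack.var(axis=0).mean()
        n = stack.size
        # sample variance of Poisson ≈ mean within 3σ (σ_var ≈ mean·√(2/n))
        assert abs(var - mean) < 3 * mean * np.sqrt(2 / n)

    def test_noise_requires_seed(self, highres, ic_highres):
        with pytest.raises(ValueError, match="rng"):
            simulate_frame(highres, None, ic_highres.apex - 9.0,
                           ic=ic_highres, noise="poisson")

    def test_same_seed_identical(self, highres, ic_highres):
        a, _ = simulate_flat_dark(highres, noise="poisson", seed=5,
                                  ic=ic_highres)
        b, _ = simulate_flat_dark(highres, noise="poisson", seed=5,
                                  ic=ic_highres)
        assert np.array_equal(a[0].counts, b[0].counts)


class TestFrameIO:
    def test_tiff_roundtrip(self, tmp_path, highres, ic_highres):
        vol = ei.make_strand_phantom(strand_width=30.0, voxel_size=2.0,
                                     fov=400.0, background_radius=150.0)
        fs = simulate_dithered_projection(highres, vol, n_steps=2, step=39.0,
                                          ic=ic_highres)
        save_frameset(fs, tmp_path / "frames")
        back = load_frameset(tmp_path / "frames")
        assert len(back) == 2
        assert np.allclose(back[0].counts, fs[0].counts, rtol=1e-6)
        assert back[1].meta["dither_offset"] == fs[1].meta["dither_offset"]
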