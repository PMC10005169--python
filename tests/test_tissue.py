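"""Tissue optics and Monte-Carlo photon transport."""

import numpy as np
import pytest

from msimon.tissue import (
    SAMPLING_RANGES,
    ExtinctionTable,
    LayerOpticalProps,
    TissueSample,
    absorption_coefficient,
    build_pretraining_corpus,
    sample_tissue,
    scattering_coefficient,
    simulate_reflectance,
    simulate_slab,
)


class TestCoefficients:
    def test_zero_blood_volume_gives_zero_absorption(self, tab):
        wl = np.array([450.0, 550.0, 650.0])
        for s in (0.0, 0.5, 1.0):
            assert np.all(absorption_coefficient(0.0, s, wl, tab) == 0.0)

    def test_absorption_direct_evaluation(self):
        # mu_a = v_hb * s * eps * ln(10) * 150 / 64500 with eps = 1000
        tab = ExtinctionTable(
            wavelengths=np.array([400.0, 800.0]),
            eps_hbo2=np.array([1000.0, 1000.0]),
            eps_hb=np.array([0.0, 0.0]),
        )
        mu = absorption_coefficient(0.1, 1.0, np.array([600.0]), tab)
        assert mu[0] == pytest.approx(0.53549, abs=1e-5)

    def test_equal_extinctions_make_oxygenation_irrelevant(self):
        tab = ExtinctionTable(
            wavelengths=np.array([400.0, 800.0]),
            eps_hbo2=np.array([500.0, 500.0]),
            eps_hb=np.array([500.0, 500.0]),
        )
        wl = np.array([500.0])
        values = [absorption_coefficient(0.2, s, wl, tab)[0] for s in (0.0, 0.5, 1.0)]
        assert np.allclose(values, values[0])

    def test_wavelength_out_of_range_raises(self, tab):
        with pytest.raises(ValueError, match="range"):
            absorption_coefficient(0.1, 0.5, np.array([2000.0]), tab)

    def test_scattering_power_law(self):
        assert scattering_coefficient(20.0, 1.0, 0.9, np.array([500.0]))[0] == pytest.approx(200.0)
        # b = 0: flat in wavelength
        flat = scattering_coefficient(10.0, 0.0, 0.8, np.array([400.0, 900.0]))
        assert flat[0] == flat[1]
        # doubling wavelength at b = 1 halves mu_s
        v500, v1000 = scattering_coefficient(20.0, 1.0, 0.9, np.array([500.0, 1000.0]))
        assert v1000 == pytest.approx(v500 / 2.0)
        with pytest.raises(ValueError, match="g"):
            scattering_coefficient(10.0, 1.0, 1.0, np.array([500.0]))


class TestSampling:
    def test_draws_within_ranges_and_reproducible(self):
        samples = sample_tissue(1000, rng=42)
        arr = np.stack([s.as_array() for s in samples])  # (n, 3, 7)
        for j, (name, (lo, hi)) in enumerate(SAMPLING_RANGES.items()):
            assert arr[:, :, j].min() >= lo and arr[:, :, j].max() <= hi
        again = np.stack([s.as_array() for s in sample_tissue(1000, rng=42)])
        assert np.array_equal(arr, again)

    def test_uniform_mean_of_blood_volume(self):
        samples = sample_tissue(10_000, rng=7)
        v = np.array([layer.v_hb for s in samples for layer in s.layers])
        se = 0.30 / np.sqrt(12 * v.size)
        assert abs(v.mean() - 0.15) < 3 * se

    def test_layer_count_enforced(self):
        layer = LayerOpticalProps(0.1, 0.5, 20, 1, 0.9, 1.4, 0.1)
        with pytest.raises(ValueError, match="3 layers"):
            TissueSample([layer, layer])


class TestMonteCarlo:
    def test_pure_absorber_matches_beer_attenuation(self):
        # mu_s = 0, matched indices, d = 1 cm, mu_a = 1: no diffuse
        # reflectance, unscattered transmittance e^-1
        r, t, a = simulate_slab([1.0], [0.0], [0.0], [1.0], [1.0], 20_000, seed=3)
        assert r == 0.0
        se = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / 20_000)
        assert t == pytest.approx(np.exp(-1), abs=3 * max(se, 1e-3))

    def test_conservative_scatterer_reflects_nearly_everything(self):
        # mu_a = 0, matched indices, thickness >> transport length
        mu_s, g = 100.0, 0.0
        r, t, a = simulate_slab([0.0], [mu_s], [g], [1.0], [1.0], 10_000, seed=4)
        assert a == 0.0
        assert r >= 0.98

    def test_energy_conservation(self):
        r, t, a = simulate_slab(
            [5.0, 1.0, 2.0], [50.0, 80.0, 30.0], [0.9, 0.85, 0.8],
            [1.4, 1.37, 1.44], [0.05, 0.1, 0.05], 10_000, seed=5,
        )
        assert abs(r + t + a - 1.0) <= 1e-3

    def test_matches_independent_photon_loop(self):
        """Single matched-index layer vs a straightforward vectorised
        numpy photon simulation written independently of the kernel."""
        mu_a, mu_s, g, d = 10.0, 90.0, 0.75, 0.02
        n = 100_000
        r, t, a = simulate_slab([mu_a], [mu_s], [g], [1.0], [d], n, seed=6)

        rng = np.random.default_rng(99)
        mu_t = mu_a + mu_s
        alive = np.ones(n, dtype=bool)
        w = np.ones(n)
        z = np.zeros(n)
        uz = np.ones(n)
        ux = np.zeros(n)
        uy = np.zeros(n)
        refl = trans = 0.0
        while alive.any():
            idx = np.flatnonzero(alive)
            step = -np.log(rng.random(idx.size)) / mu_t
            z_new = z[idx] + step * uz[idx]
            up = z_new < 0
            down = z_new > d
            refl += w[idx][up].sum()
            trans += w[idx][down].sum()
            inside = ~(up | down)
            alive[idx[up | down]] = False
            ii = idx[inside]
            z[ii] = z_new[inside]
            w[ii] *= mu_s / mu_t
            # Henyey-Greenstein scatter
            u = rng.random(ii.size)
            tmp = (1 - g * g) / (1 - g + 2 * g * u)
            ct = (1 + g * g - tmp**2) / (2 * g)
            st = np.sqrt(np.clip(1 - ct**2, 0, None))
            phi = 2 * np.pi * rng.random(ii.size)
            cp, sp = np.cos(phi), np.sin(phi)
            near_pole = np.abs(uz[ii]) > 0.99999
            den = np.sqrt(np.clip(1 - uz[ii] ** 2, 1e-12, None))
            nux = st * (ux[ii] * uz[ii] * cp - uy[ii] * sp) / den + ux[ii] * ct
            nuy = st * (uy[ii] * uz[ii] * cp + ux[ii] * sp) / den + uy[ii] * ct
            nuz = -st * cp * den + uz[ii] * ct
            nux[near_pole] = (st * cp)[near_pole]
            nuy[near_pole] = (st * sp)[near_pole]
            nuz[near_pole] = (np.sign(uz[ii]) * ct)[near_pole]
            ux[ii], uy[ii], uz[ii] = nux, nuy, nuz
            # kill negligible weights (oracle bookkeeping, unbiased enough
            # at this tolerance)
            dead = w[ii] < 1e-6
            alive[ii[dead]] = False
        r_oracle = refl / n
        se = np.sqrt(r_oracle * (1 - r_oracle) / n)
        assert r == pytest.approx(r_oracle, abs=4 * se)

    def test_reflectance_monotone_in_top_absorption(self):
        from scipy.stats import spearmanr

        mu_as = np.linspace(1.0, 40.0, 8)
        refls = [
            simulate_slab([m], [80.0], [0.9], [1.4], [0.3], 10_000, seed=11)[0]
            for m in mu_as
        ]
        rho, _ = spearmanr(mu_as, refls)
        assert rho == -1.0

    def test_seed_determinism_bitwise(self, tab):
        sample = sample_tissue(1, rng=3)[0]
        wl = np.arange(500.0, 560.0, 2.0)
        a = simulate_reflectance(sample, wl, tab, n_photons=500, seed=8)
        b = simulate_reflectance(sample, wl, tab, n_photons=500, seed=8)
        assert np.array_equal(a.reflectance, b.reflectance)

    def test_mc_error_scales_inverse_sqrt(self):
        """Quadrupling photons should halve the standard error (factor 2 +- 0.5)."""
        args = ([5.0], [60.0], [0.85], [1.0], [0.1])
        small = [simulate_slab(*args, 1000, seed=s)[0] for s in range(30)]
        big = [simulate_slab(*args, 4000, seed=1000 + s)[0] for s in range(30)]
        ratio = np.std(small) / np.std(big)
        assert 1.5 <= ratio <= 2.5

    def test_photon_floor(self, tab):
        sample = sample_tissue(1, rng=0)[0]
        with pytest.raises(ValueError, match="photons"):
            simulate_reflectance(sample, np.array([500.0]), tab, n_photons=10)


class TestCorpus:
    def test_shape_range_and_absorption_monotonicity(self, cam, tab):
        bands, params = build_pretraining_corpus(
            60, cam, tab, n_photons=300, seed=21
        )
        assert bands.shape == (60, 16)
        assert params.shape == (60, 3, 7)
        assert np.all((bands >= 0) & (bands <= 1))
        # higher blood volume in the top layer darkens absorbing bands
        from scipy.stats import spearmanr

        v_hb_top = params[:, 0, 0]
        band_mean = bands.mean(axis=1)
        rho, _ = spearmanr(v_hb_top, band_mean)
        assert rho < 0
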