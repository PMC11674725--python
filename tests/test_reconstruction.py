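"""OSEM, post-filter, model-compensating reconstruction."""
from dataclasses import replace

import numpy as np
import pytest

import bremspect as bs
from bremspect.acquisition import SystemModel, projection_scale
from bremspect.errors import ConfigurationError, DegenerateInputError
from bremspect.reconstruction import advanced_config

W_MID = bs.STUDY_WINDOWS[1]


def _sinogram(mini_setup, n_views=8, noisy=True, seed=2):
    geom, grid, act, mu = mini_setup
    protocol = bs.AcquisitionProtocol(collimator=bs.he_collimator(), n_views=n_views)
    system = bs.make_system(grid, mu, protocol, W_MID)
    y90 = bs.yttrium90()
    expected = np.stack(
        [bs.forward_project(act, mu, protocol, w, y90) for w in bs.STUDY_WINDOWS]
    )
    if noisy:
        sino = bs.add_noise(expected, seed, protocol=protocol, grid=grid)
    else:
        sino = bs.SinogramSet(
            counts=expected, expected=expected, windows=bs.STUDY_WINDOWS,
            protocol=protocol, row=None, seed=seed, grid=grid,
        )
    return sino, system, protocol


class TestOSEM:
    def test_mlem_loglikelihood_monotone(self):
        """1-subset EM on a small noisy disc: Poisson log-lik never decreases."""
        grid = bs.VoxelGrid.centered((32, 32, 1), (8.0, 8.0, 8.0))
        x, y = np.meshgrid(np.arange(32) - 15.5, np.arange(32) - 15.5, indexing="ij")
        disc = ((x**2 + y**2) <= 8**2).astype(float)[..., None]
        act = bs.ActivityMap(grid=grid, values=disc, isotope="Y90")
        protocol = bs.AcquisitionProtocol(collimator=bs.he_collimator(), n_views=16)
        system = SystemModel(grid, n_views=16, attenuation=False, cdr=False,
                             septal=False, flat=False)
        expected = bs.forward_project(act, None, protocol, W_MID, bs.yttrium90(),
                                      system=system)
        sino = bs.add_noise(expected[None], seed=1, windows=(W_MID,),
                            protocol=protocol, grid=grid)
        cfg = bs.ReconConfig(iterations=15, subsets=1)
        ll = []
        bs.osem(sino, W_MID, system, cfg, loglik_out=ll)
        diffs = np.diff(ll)
        assert np.all(diffs >= -1e-7 * np.abs(np.array(ll[:-1])))

    def test_iterates_nonnegative(self, mini_setup):
        sino, system, _ = _sinogram(mini_setup)
        vol = bs.osem(sino, W_MID, system, bs.ReconConfig(iterations=5, subsets=8))
        assert vol.values.min() >= 0.0

    def test_zero_counts_rejected(self, mini_setup):
        sino, system, _ = _sinogram(mini_setup)
        sino.counts[...] = 0
        with pytest.raises(DegenerateInputError):
            bs.osem(sino, W_MID, system, bs.ReconConfig())

    def test_count_preservation(self, mini_setup):
        """Sensitivity-weighted recon total matches measured counts (<1%)."""
        sino, system, protocol = _sinogram(mini_setup)
        cfg = bs.ReconConfig(iterations=10, subsets=1)
        vol = bs.osem(sino, W_MID, system, cfg)
        scale = projection_scale(protocol, W_MID, bs.yttrium90())
        x = vol.values * vol.grid.voxel_volume_ml
        sens = system.adjoint(np.ones((system.n_views, system.n, system.nz))) * scale
        wi = sino.window_index(W_MID)
        gap = abs((sens * x).sum() - sino.counts[wi].sum()) / sino.counts[wi].sum()
        assert gap < 0.01

    def test_subsets_must_divide_views(self, mini_setup):
        sino, system, _ = _sinogram(mini_setup, n_views=8)
        with pytest.raises(bs.DomainError):
            bs.osem(sino, W_MID, system, bs.ReconConfig(iterations=1, subsets=3))

    def test_deterministic(self, mini_setup):
        sino, system, _ = _sinogram(mini_setup)
        cfg = bs.ReconConfig(iterations=3, subsets=8)
        a = bs.osem(sino, W_MID, system, cfg)
        b = bs.osem(sino, W_MID, system, cfg)
        assert a.values.tobytes() == b.values.tobytes()


class TestPostfilter:
    def _delta_volume(self):
        grid = bs.VoxelGrid.centered((64, 64, 9), (1.0, 1.0, 1.0))
        v = np.zeros(grid.dims)
        v[32, 32, 4] = 1.0
        return bs.ReconVolume(grid=grid, values=v)

    def test_zero_fwhm_is_identity(self, mini_setup):
        sino, system, _ = _sinogram(mini_setup)
        vol = bs.osem(sino, W_MID, system, bs.ReconConfig(iterations=2, subsets=8))
        out = bs.postfilter(vol, 0.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_mass_conserved(self, mini_setup):
        sino, system, _ = _sinogram(mini_setup)
        vol = bs.osem(sino, W_MID, system, bs.ReconConfig(iterations=2, subsets=8))
        out = bs.postfilter(vol, 5.0)
        assert out.values.sum() == pytest.approx(vol.values.sum(), rel=1e-9)

    def test_impulse_fwhm_recovered(self):
        """5 mm filter on a delta at 1 mm spacing yields a 5.0 +- 0.1 mm FWHM."""
        vol = self._delta_volume()
        out = bs.postfilter(vol, 5.0).values
        prof = out[:, 32, 4]
        half = prof.max() / 2.0
        above = np.where(prof >= half)[0]
        lo, hi = above[0], above[-1]

        def cross(i, j):
            return i + (half - prof[i]) / (prof[j] - prof[i]) * (j - i)

        fwhm = cross(hi, hi + 1) - cross(lo, lo - 1)
        assert fwhm == pytest.approx(5.0, abs=0.1)


class TestAdvancedRecon:
    def test_all_flags_off_reduces_to_osem_bitwise(self, mini_setup):
        _, grid, act, mu = mini_setup
        sino, _, protocol = _sinogram(mini_setup)
        bare = SystemModel(grid, n_views=protocol.n_views, attenuation=False,
                           cdr=False, septal=False, flat=False)
        cfg = bs.ReconConfig(iterations=3, subsets=8, attenuation=False, cdr=False,
                             crosstalk_compensation=False, mode="advanced",
                             post_filter_fwhm_mm=0.0)
        ref = bs.osem(sino, W_MID, bare, cfg)
        adv = bs.advanced_recon(sino, W_MID, {}, cfg)
        assert adv.values.tobytes() == ref.values.tobytes()

    def test_missing_mu_raises(self, mini_setup):
        sino, _, _ = _sinogram(mini_setup)
        with pytest.raises(ConfigurationError):
            bs.advanced_recon(sino, W_MID, {}, advanced_config())

    def test_missing_tc_estimate_raises(self, mini_setup):
        _, _, _, mu = mini_setup
        sino, _, _ = _sinogram(mini_setup)
        with pytest.raises(ConfigurationError):
            bs.advanced_recon(sino, W_MID, {"mu": mu}, advanced_config())

    def test_compensation_improves_crc_on_matched_data(self, mini_setup):
        """Noiseless 90Y data: modelled CDR beats plain OSEM on sphere contrast."""
        geom, grid, act, mu = mini_setup
        sino, sim_system, protocol = _sinogram(mini_setup, noisy=False)
        cfg_adv = replace(advanced_config(), iterations=10, subsets=8,
                          crosstalk_compensation=False)
        adv = bs.advanced_recon(sino, W_MID, {"mu": mu}, cfg_adv)
        plain_sys = SystemModel(grid, n_views=protocol.n_views, mu=mu,
                                attenuation=True, cdr=False, septal=False, flat=False)
        plain = bs.osem(sino, W_MID, plain_sys, bs.ReconConfig(iterations=10, subsets=8))
        vois = bs.build_vois(geom, grid, inner_radius_mm=14.0, outer_radius_mm=28.0,
                             length_mm=30.0)
        crc_adv = bs.compute_crc(adv, vois).crc_mean[20.0]
        crc_plain = bs.compute_crc(plain, vois).crc_mean[20.0]
        assert crc_adv > crc_plain
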