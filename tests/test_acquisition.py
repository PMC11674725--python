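"""Projector, noise model, experiment simulation."""
from dataclasses import replace

import numpy as np
import pytest

import bremspect as bs
from bremspect.acquisition import SystemModel, projection_scale
from bremspect.errors import DomainError

W_MID = bs.STUDY_WINDOWS[1]


def _protocol(kind="HE", **kw):
    return bs.AcquisitionProtocol(collimator=bs.collimator_by_kind(kind), **kw)


class TestProjector:
    def test_adjoint_identity(self, mini_setup):
        """<Px, y> == <x, P^T y> to float precision with all physics on."""
        _, grid, _, mu = mini_setup
        system = SystemModel(
            grid, n_views=12, mu=mu, collimator=bs.he_collimator(),
            window_label=W_MID.label,
        )
        rng = np.random.default_rng(3)
        x = rng.random(grid.dims)
        y = rng.random((12, grid.dims[0], grid.dims[2]))
        lhs = float((system.forward(x) * y).sum())
        rhs = float((x * system.adjoint(y)).sum())
        assert abs(lhs - rhs) / lhs < 1e-6

    def test_zero_activity_projects_to_zero(self, mini_setup):
        _, grid, _, mu = mini_setup
        system = SystemModel(
            grid, n_views=4, mu=mu, collimator=bs.he_collimator(),
            window_label=W_MID.label,
        )
        assert not system.forward(np.zeros(grid.dims)).any()

    def test_count_conservation_single_view(self, mini_setup):
        """No attenuation/blur: view-0 projection sum equals scaled activity."""
        _, grid, act, _ = mini_setup
        protocol = _protocol(n_views=2, scan_time_min=20.0)
        system = SystemModel(
            grid, n_views=2, attenuation=False, cdr=False, septal=False, flat=False
        )
        y90 = bs.yttrium90()
        proj = bs.forward_project(act, None, protocol, W_MID, y90, system=system)
        scale = projection_scale(protocol, W_MID, y90)
        # view 0 is the identity rotation: exact conservation
        assert proj[0].sum() == pytest.approx(act.total_mbq * scale, rel=1e-12)

    def test_expected_counts_linear_in_scan_time(self, mini_setup):
        _, grid, act, mu = mini_setup
        y90 = bs.yttrium90()
        p20 = _protocol(n_views=4, scan_time_min=20.0)
        p25 = _protocol(n_views=4, scan_time_min=25.0)
        e20 = bs.forward_project(act, mu, p20, W_MID, y90)
        e25 = bs.forward_project(act, mu, p25, W_MID, y90)
        np.testing.assert_allclose(e25, e20 * 25.0 / 20.0, rtol=1e-12)

    def test_psf_sigma_grows_with_distance(self):
        """Point sources at two depths blur per the configured distance law."""
        grid = bs.VoxelGrid.centered((48, 48, 1), (4.0, 4.0, 4.0))
        coll = bs.he_collimator()
        system = SystemModel(
            grid, n_views=2, attenuation=False, cdr=True, septal=False, flat=False,
            collimator=coll,
        )
        sigmas = []
        for depth in (8, 40):
            x = np.zeros(grid.dims)
            x[depth, 24, 0] = 1.0
            prof = system.forward(x, views=[0])[0][:, 0]
            centre = (prof * np.arange(48)).sum() / prof.sum()
            var = (prof * (np.arange(48) - centre) ** 2).sum() / prof.sum()
            sigmas.append(np.sqrt(var) * 4.0)  # mm
        expected = coll.sigma_mm(system.distance_mm[[8, 40]])
        assert sigmas[1] > sigmas[0]
        np.testing.assert_allclose(sigmas, expected, rtol=0.1)


class TestNoise:
    def test_zero_expectation_zero_counts(self):
        sino = bs.add_noise(np.zeros((2, 4, 4, 2)), seed=1)
        assert not sino.counts.any()

    def test_same_seed_identical(self):
        exp = np.full((1, 8, 8, 2), 37.2)
        a = bs.add_noise(exp, seed=42)
        b = bs.add_noise(exp, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert bs.add_noise(exp, seed=43).counts.tobytes() != a.counts.tobytes()

    def test_poisson_mean(self):
        """Mean of 1e4 independent draws at expectation 100 is 100 +- 3 SE."""
        exp = np.full((1, 100, 100, 1), 100.0)
        counts = bs.add_noise(exp, seed=7).counts
        se = 10.0 / 100.0  # sd 10, n = 1e4
        assert counts.mean() == pytest.approx(100.0, abs=3 * se)

    def test_negative_expectation_rejected(self):
        with pytest.raises(DomainError):
            bs.add_noise(np.full((1, 2, 2, 1), -1.0), seed=0)


class TestSimulateExperiment:
    def _maps(self, mini_setup, tc_mbq):
        geom, grid, act, mu = mini_setup
        maps = {bs.yttrium90(): act}
        if tc_mbq > 0:
            tc_map = bs.voxelize_activity(
                geom,
                bs.CompartmentActivity(
                    isotope="Tc99m", sphere_concentration=0.0,
                    background_concentration=1.0,
                ),
                grid,
            )
            tc_map.values *= tc_mbq / tc_map.total_mbq
            maps[bs.technetium99m()] = tc_map
        return maps

    def test_no_tc_row_has_pure_y90_expectation(self, mini_setup):
        geom, grid, act, mu = mini_setup
        row = bs.ExperimentRow(1, "90Y only", 20.0, 2, "HE", 3.2, 0.0, 0)
        protocol = _protocol(n_views=4)
        mu_maps = {w.label: mu for w in bs.STUDY_WINDOWS}
        reps = bs.simulate_experiment(row, self._maps(mini_setup, 0.0), mu_maps,
                                      protocol, seed=5)
        assert len(reps) == 2
        y90 = bs.yttrium90()
        for wi, w in enumerate(bs.STUDY_WINDOWS):
            direct = bs.forward_project(act, mu, protocol, w, y90)
            np.testing.assert_allclose(reps[0].expected[wi], direct, rtol=1e-12)

    def test_dual_expectation_is_sum_of_components(self, mini_setup):
        geom, grid, act, mu = mini_setup
        protocol = _protocol(n_views=4)
        mu_maps = {w.label: mu for w in bs.STUDY_WINDOWS}
        row = bs.ExperimentRow(5, "90Y+99mTc", 25.0, 1, "HE", 3.1, 189.0, 6)
        maps = self._maps(mini_setup, 189.0)
        reps = bs.simulate_experiment(row, maps, mu_maps, protocol, seed=5)
        for wi, w in enumerate(bs.STUDY_WINDOWS):
            parts = sum(
                bs.forward_project(m, mu, protocol, w, iso)
                for iso, m in maps.items()
            )
            np.testing.assert_allclose(reps[0].expected[wi], parts, rtol=1e-12)

    def test_repetitions_differ_only_by_seed(self, mini_setup):
        row = bs.ExperimentRow(1, "90Y only", 20.0, 3, "HE", 3.2, 0.0, 0)
        protocol = _protocol(n_views=4)
        _, _, act, mu = mini_setup
        mu_maps = {w.label: mu for w in bs.STUDY_WINDOWS}
        reps = bs.simulate_experiment(row, self._maps(mini_setup, 0.0), mu_maps,
                                      protocol, seed=9)
        assert [r.seed for r in reps] == [9, 10, 11]
        np.testing.assert_array_equal(reps[0].expected, reps[1].expected)
        assert reps[0].counts.tobytes() != reps[1].counts.tobytes()

    def test_tc_contamination_ordering_across_windows(self, mini_setup):
        """Tc-to-Y90 count ratio: 90-120 > 160-200 > 200-250 for any Tc row."""
        protocol = _protocol(n_views=4)
        tc, y90 = bs.technetium99m(), bs.yttrium90()
        ratios = []
        for w in bs.STUDY_WINDOWS:
            ratios.append(
                projection_scale(protocol, w, tc) / projection_scale(protocol, w, y90)
            )
        assert ratios[0] > ratios[1] > ratios[2]


class TestSchedule:
    def test_builtin_schedule_matches_published_design(self):
        sched = bs.load_schedule()
        assert [r.exp_id for r in sched] == [1, 2, 3, 4, 5, 6]
        assert [r.percent_tc for r in sched] == [0, 0, 15, 13, 6, 5]
        assert [r.scan_time_min for r in sched] == [20, 20, 20, 20, 25, 25]
        assert [r.collimator_kind for r in sched] == ["HE", "ME", "ME", "HE", "HE", "ME"]
        assert all(r.repetitions == 3 for r in sched)

    def test_inconsistent_percent_rejected(self):
        with pytest.raises(DomainError, match="inconsistent"):
            bs.ExperimentRow(9, "bad", 20.0, 1, "HE", 3.0, 450.0, 5)

    def test_he_septal_weights_below_me_everywhere(self):
        he, me = bs.he_collimator(), bs.me_collimator()
        for w in bs.STUDY_WINDOWS:
            assert he.septal_weight[w.label] < me.septal_weight[w.label]
            assert he.septal_weight[w.label] >= 0
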