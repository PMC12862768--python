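"""Brownian diffusion, PSF, photon emission, background and stream plumbing."""

import numpy as np
import pytest
from scipy import stats

from smfretsim.config import FixedModel, Population, ScenarioConfig, SwitchingModel
from smfretsim.dynamics import constant_trajectory
from smfretsim.engine import (
    EmissionConfig,
    PSFModel,
    SimulationBox,
    emit_photons,
    generate_background,
    merge_streams,
    propagate_brownian,
    psf_intensity,
    simulate_experiment,
)
from smfretsim.photons import ACCEPTOR, BACKGROUND_ID, DONOR, PhotonStream


@pytest.fixture
def box():
    return SimulationBox(4.0, 4.0, 6.0)


@pytest.fixture
def psf():
    return PSFModel(0.3, 0.3, 0.5)


def _emission(dt=1e-6, D_B=30.0, max_rate=200_000.0, bg_d=0.0, bg_a=0.0, **kw):
    return EmissionConfig(max_rate=max_rate, bg_donor=bg_d, bg_acceptor=bg_a,
                          dt=dt, D_B=D_B, **kw)


class TestBrownian:
    def test_near_zero_diffusion_keeps_positions(self, box):
        cfg = _emission(D_B=1e-300)
        p0 = np.array([[2.0, 2.0, 3.0]])
        pos = propagate_brownian(box, cfg, p0, 100, np.random.default_rng(0))
        np.testing.assert_allclose(pos, np.broadcast_to(p0, pos.shape), atol=1e-12)

    def test_increment_variance(self, box):
        # large box so the walk never reaches a wall within the test
        big = SimulationBox(1000.0, 1000.0, 1000.0)
        cfg = _emission(dt=1e-5, D_B=30.0)
        p0 = np.full((10, 3), 500.0)
        pos = propagate_brownian(big, cfg, p0, 100_000, np.random.default_rng(1))
        inc = np.diff(pos[:, :, 0].astype(float), axis=0).ravel()
        target = 2 * 30.0 * 1e-5
        se = target * np.sqrt(2.0 / inc.size)
        assert abs(inc.var() - target) < 3 * se

    def test_reflecting_boundary_stays_inside(self, box):
        cfg = _emission(dt=1e-4, D_B=30.0)
        p0 = np.array([[0.05, 3.9, 0.1], [3.9, 0.05, 5.9]])
        pos = propagate_brownian(box, cfg, p0, 20_000, np.random.default_rng(2))
        assert pos.min() >= 0.0
        assert np.all(pos <= box.lengths + 1e-6)

    def test_msd_grows_linearly_before_boundaries(self):
        big = SimulationBox(1000.0, 1000.0, 1000.0)
        cfg = _emission(dt=1e-5, D_B=30.0)
        p0 = np.full((200, 3), 500.0)
        pos = propagate_brownian(big, cfg, p0, 2000, np.random.default_rng(3))
        t = 2000 * 1e-5
        msd = np.mean(np.sum((pos[-1].astype(float) - 500.0) ** 2, axis=1))
        target = 6 * 30.0 * t
        se = target * np.sqrt(2.0 / 200)  # chi2-ish spread over molecules
        assert abs(msd - target) < 3 * se

    def test_initial_positions_validated(self, box):
        with pytest.raises(ValueError):
            propagate_brownian(box, _emission(), np.array([[9.0, 1.0, 1.0]]), 10)


class TestPSF:
    def test_peak_at_center(self, psf):
        assert psf_intensity(psf, [1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    @pytest.mark.parametrize("offset,axis", [(0.3, 0), (0.3, 1), (0.5, 2)])
    def test_one_sigma_offsets(self, psf, offset, axis):
        pos = np.zeros(3)
        pos[axis] = offset
        assert psf_intensity(psf, pos, np.zeros(3)) == pytest.approx(
            np.exp(-0.5), rel=1e-12)

    def test_vectorized(self, psf):
        pos = np.zeros((5, 3))
        np.testing.assert_allclose(psf_intensity(psf, pos, np.zeros(3)), 1.0)


class TestEmission:
    def _pinned(self, box, n_steps, dt=1e-6):
        return np.broadcast_to(box.center, (n_steps, 1, 3)).copy()

    def test_extreme_efficiencies_route_all_photons(self, box, psf):
        pos = self._pinned(box, 50_000)
        for e, chan in ((0.0, ACCEPTOR), (1.0, DONOR)):
            stream = emit_photons(pos, [e], _emission(), psf, center=box.center,
                                  rng=np.random.default_rng(4))
            assert len(stream) > 0
            assert np.sum(stream.channels == chan) == 0

    def test_pinned_molecule_total_rate(self, box, psf):
        # 1 s at the PSF center: Poisson(200000) total counts
        pos = self._pinned(box, 1_000_000)
        stream = emit_photons(pos, [0.5], _emission(), psf, center=box.center,
                              rng=np.random.default_rng(5))
        assert abs(len(stream) - 200_000) < 3 * np.sqrt(200_000)

    def test_acceptor_fraction_matches_efficiency(self, box, psf):
        pos = self._pinned(box, 200_000)
        e = 0.71
        stream = emit_photons(pos, [e], _emission(), psf, center=box.center,
                              rng=np.random.default_rng(6))
        frac = np.mean(stream.channels == ACCEPTOR)
        se = np.sqrt(e * (1 - e) / len(stream))
        assert abs(frac - e) < 3 * se

    def test_poisson_dispersion_of_per_second_counts(self, box, psf):
        # index of dispersion of 100 per-second counts within [0.9, 1.1]
        pos = self._pinned(box, 100_000, dt=1e-6)
        cfg = _emission(dt=1e-6, max_rate=3_000.0)
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(100):  # independent 0.1 s windows, rescaled
            stream = emit_photons(pos, [0.5], cfg, psf, center=box.center, rng=rng)
            counts.append(len(stream))
        counts = np.asarray(counts, dtype=float)
        assert 0.9 < counts.var() / counts.mean() < 1.1

    def test_efficiency_trajectory_drives_channel_split(self, box, psf):
        from smfretsim.dynamics import EfficiencyTrajectory

        n_steps, dt = 100_000, 1e-6
        half = n_steps * dt / 2
        clock = np.arange(n_steps) * dt
        traj = EfficiencyTrajectory(times=clock,
                                    efficiencies=(clock >= half).astype(float))
        pos = self._pinned(box, n_steps)
        stream = emit_photons(pos, [traj], _emission(), psf, center=box.center,
                              rng=np.random.default_rng(11))
        first = stream.times < half
        assert np.all(stream.channels[first] == DONOR)
        assert np.all(stream.channels[~first] == ACCEPTOR)

    def test_short_efficiency_trajectory_rejected(self, box, psf):
        pos = self._pinned(box, 1000)
        short = constant_trajectory(0.5, duration=1000 * 1e-6 / 2)
        with pytest.raises(ValueError, match="covers"):
            emit_photons(pos, [short], _emission(), psf, center=box.center)


class TestBackground:
    def test_channel_rates(self):
        cfg = _emission(bg_d=1800.0, bg_a=1200.0)
        stream = generate_background(cfg, 10.0, np.random.default_rng(8))
        nd = int(np.sum(stream.channels == DONOR))
        na = int(np.sum(stream.channels == ACCEPTOR))
        assert abs(nd - 18_000) < 3 * np.sqrt(18_000)
        assert abs(na - 12_000) < 3 * np.sqrt(12_000)
        assert np.all(stream.molecule_ids == BACKGROUND_ID)

    def test_zero_rates_empty(self):
        stream = generate_background(_emission(), 5.0, np.random.default_rng(9))
        assert len(stream) == 0

    def test_interarrival_exponentiality(self):
        # shape test with the estimated scale: a plain KS against the nominal
        # rate would mostly detect the sqrt(n) fluctuation of the realized count
        cfg = _emission(bg_d=1800.0, bg_a=0.0, dt=1e-7)
        stream = generate_background(cfg, 20.0, np.random.default_rng(10))
        gaps = np.diff(stream.times)
        res = stats.kstest(gaps, stats.expon(scale=gaps.mean()).cdf)
        assert res.pvalue > 0.01
        assert gaps.mean() == pytest.approx(1.0 / 1800.0, rel=0.05)


class TestMerge:
    def _stream(self, ts, tick=1e-6, chan=None, mol=None):
        n = len(ts)
        return PhotonStream(np.asarray(ts), chan if chan is not None else np.zeros(n, np.uint8),
                            mol if mol is not None else np.zeros(n, np.int32), tick)

    def test_merge_is_sorted_and_preserves_counts(self):
        a = self._stream([1, 5, 9])
        b = self._stream([2, 5, 7, 11])
        m = merge_streams([a, b])
        assert len(m) == 7
        assert np.all(np.diff(m.timestamps) >= 0)

    def test_merge_with_empty_is_identity(self):
        a = self._stream([3, 4])
        m = merge_streams([a, PhotonStream.empty(1e-6)])
        np.testing.assert_array_equal(m.timestamps, a.timestamps)

    def test_mixed_ticks_rejected(self):
        with pytest.raises(ValueError, match="tick"):
            merge_streams([self._stream([1]), self._stream([1], tick=2e-6)])

    def test_tie_break_deterministic(self):
        a = self._stream([5], chan=np.array([1], np.uint8), mol=np.array([2], np.int32))
        b = self._stream([5], chan=np.array([0], np.uint8), mol=np.array([7], np.int32))
        m = merge_streams([a, b])
        assert m.channels.tolist() == [0, 1]


class TestSimulateExperiment:
    def _tiny_scenario(self, seed=0, **kw):
        defaults = dict(
            name="tiny",
            populations=[Population(2, FixedModel(0.71)),
                         Population(1, SwitchingModel((0.9, 0.1), 10.0))],
            box=SimulationBox(3.0, 3.0, 4.0),
            psf=PSFModel(0.3, 0.3, 0.5),
            emission=EmissionConfig(max_rate=200_000.0, bg_donor=1800.0,
                                    bg_acceptor=1200.0, dt=2e-6, D_B=30.0),
            duration=0.5,
            seed=seed,
        )
        defaults.update(kw)
        return ScenarioConfig(**defaults)

    def test_same_seed_is_byte_identical(self):
        r1 = simulate_experiment(self._tiny_scenario(seed=13))
        r2 = simulate_experiment(self._tiny_scenario(seed=13))
        np.testing.assert_array_equal(r1.photons.timestamps, r2.photons.timestamps)
        np.testing.assert_array_equal(r1.photons.channels, r2.photons.channels)
        np.testing.assert_array_equal(r1.photons.molecule_ids, r2.photons.molecule_ids)

    def test_different_seed_differs(self):
        r1 = simulate_experiment(self._tiny_scenario(seed=13))
        r2 = simulate_experiment(self._tiny_scenario(seed=14))
        assert (len(r1.photons) != len(r2.photons)
                or not np.array_equal(r1.photons.timestamps, r2.photons.timestamps))

    def test_dark_molecules_give_background_only(self):
        sc = self._tiny_scenario(
            populations=[Population(1, FixedModel(0.5))],
            emission=EmissionConfig(max_rate=0.0, bg_donor=1800.0,
                                    bg_acceptor=1200.0, dt=2e-6, D_B=30.0))
        res = simulate_experiment(sc)
        assert len(res.photons) > 0
        assert np.all(res.photons.molecule_ids == BACKGROUND_ID)

    def test_ground_truth_records_populations(self):
        res = simulate_experiment(self._tiny_scenario(seed=15))
        assert len(res.truth.populations) == 2
        assert res.truth.molecule_ranges == [(0, 2), (2, 3)]
        assert "state_trajectories" in res.truth.populations[1]

    def test_donor_only_population_emits_no_acceptor_signal(self):
        sc = self._tiny_scenario(
            populations=[Population(2, FixedModel(0.0))],
            emission=EmissionConfig(max_rate=200_000.0, bg_donor=0.0,
                                    bg_acceptor=0.0, dt=2e-6, D_B=30.0))
        res = simulate_experiment(sc)
        assert len(res.photons) > 0
        assert np.sum(res.photons.channels == ACCEPTOR) == 0
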