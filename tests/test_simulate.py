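"""Reduced-order spray-plant simulation: particles, modal leaves, films, stages."""

import math

import numpy as np
import pandas as pd
import pytest

from weedspray.config import SimulationConfig
from weedspray.leafmech import LeafGeometry, LeafMaterial
from weedspray.nozzle import NozzleSpec, OperatingPoint
from weedspray.simulate import (AIRBORNE, ImpactEvent, ModalLeaf, Particle,
                                STAGES, WallFilm, classify_stage,
                                detect_impacts, film_update, leaf_step,
                                particle_step, run_simulation,
                                stage_timeline, stokes_relaxation_time)
from weedspray.synth import build_plant


def make_particle(**kw):
    defaults = dict(mass=4.19e-6, position=np.zeros(3),
                    velocity=np.array([0.0, 0.0, -10.0]),
                    relaxation_time=12.4, density=1000.0, radius=1e-3)
    defaults.update(kw)
    return Particle(**defaults)


def make_leaf(geom=None, mat=None, **kw):
    geom = geom or LeafGeometry(0.035, 0.015, 4e-4, 33.22)
    mat = mat or LeafMaterial(222.85e6, 700.0)
    return ModalLeaf.from_leaf(0, geom, mat, np.zeros(3), 0.0, **kw)


class TestParticleStep:
    def test_equilibrium_is_preserved(self):
        vc = np.array([0.3, -0.1, -2.0])
        p = make_particle(velocity=vc.copy(), density=1.225)
        p2 = particle_step(p, vc, 1e-3, air_density=1.225)
        np.testing.assert_allclose(p2.velocity, vc, rtol=1e-12)

    def test_exponential_decay_toward_still_air(self):
        p = make_particle(velocity=np.array([5.0, 0.0, 0.0]), density=1.225)
        dt = 0.37
        p2 = particle_step(p, np.zeros(3), dt, air_density=1.225)
        assert p2.velocity[0] == pytest.approx(5.0 * math.exp(-dt / 12.4), rel=1e-12)

    def test_stokes_relaxation_time(self):
        # 2 mm water droplet in air
        assert stokes_relaxation_time(1000.0, 2e-3) == pytest.approx(12.42, abs=5e-3)

    def test_position_advances_with_updated_velocity(self):
        p = make_particle()
        dt = 1e-3
        p2 = particle_step(p, np.zeros(3), dt)
        np.testing.assert_allclose(p2.position, p2.velocity * dt)

    def test_settling_toward_terminal_velocity(self):
        p = make_particle(velocity=np.zeros(3))
        p2 = p
        for _ in range(100):
            p2 = particle_step(p2, np.zeros(3), 0.05)
        assert p2.velocity[2] < p.velocity[2] + 1.0  # falling faster over time


class TestLeafStep:
    def test_rest_stays_at_rest(self):
        leaf = make_leaf()
        leaf2 = leaf_step(leaf, 0.0, 1e-3)
        assert leaf2.s == 0.0 and leaf2.v == 0.0

    def test_static_limit_under_constant_force(self):
        leaf = make_leaf()
        force = 1e-3
        for _ in range(4000):
            leaf = leaf_step(leaf, force, 1e-3)
        assert leaf.s == pytest.approx(force / leaf.stiffness, rel=1e-6)

    def test_free_vibration_period(self):
        """Free-vibration period matches 2 pi sqrt(M/K) within 0.5% at 1 ms."""
        leaf = make_leaf(damping_ratio=0.0)
        leaf.s = 1e-3
        period = 2.0 * math.pi / leaf.natural_frequency
        crossings = []
        prev_s, t = leaf.s, 0.0
        for _ in range(2000):
            leaf = leaf_step(leaf, 0.0, 1e-3)
            t += 1e-3
            if prev_s > 0 >= leaf.s:
                frac = prev_s / (prev_s - leaf.s)
                crossings.append(t - 1e-3 + frac * 1e-3)
            prev_s = leaf.s
        measured = np.mean(np.diff(crossings))
        assert measured == pytest.approx(period, rel=5e-3)

    def test_damped_oscillator_closed_form(self):
        """Newmark oscillation amplitude matches the analytic damped-envelope
        solution within 0.5% of the release amplitude over 0.5 s at 1 ms."""
        leaf = make_leaf(damping_ratio=0.05)
        s0 = 2e-3
        leaf.s = s0
        wn = leaf.natural_frequency
        zeta = leaf.damping / (2.0 * math.sqrt(leaf.stiffness * leaf.modal_mass))
        dt = 1e-3
        trace = [leaf.s]
        for _ in range(500):
            leaf = leaf_step(leaf, 0.0, dt)
            trace.append(leaf.s)
        trace = np.asarray(trace)
        peaks = [(k * dt, trace[k]) for k in range(1, 500)
                 if trace[k] > trace[k - 1] and trace[k] >= trace[k + 1]]
        assert len(peaks) >= 10
        envelope = lambda t: s0 / math.sqrt(1 - zeta**2) * math.exp(-zeta * wn * t)
        worst = max(abs(amp - envelope(t)) for t, amp in peaks)
        assert worst <= 5e-3 * s0

    def test_damped_energy_never_increases(self):
        leaf = make_leaf(damping_ratio=0.05)
        leaf.s = 1e-3
        prev = 0.5 * leaf.stiffness * leaf.s**2
        for _ in range(1000):
            leaf = leaf_step(leaf, 0.0, 1e-3)
            energy = 0.5 * leaf.stiffness * leaf.s**2 + 0.5 * leaf.modal_mass * leaf.v**2
            assert energy <= prev * (1 + 1e-9)
            prev = energy

    def test_modal_frequency_matches_cantilever_mode(self):
        """Constructed sqrt(K/M) equals the first bending frequency of the
        continuous cantilever within 2%."""
        geom = LeafGeometry(0.035, 0.015, 4e-4, 33.22)
        mat = LeafMaterial(222.85e6, 700.0)
        leaf = ModalLeaf.from_leaf(0, geom, mat, np.zeros(3), 0.0)
        ei = mat.elastic_modulus * geom.width * geom.thickness**3 / 12.0
        mu = mat.density * geom.width * geom.thickness
        omega_eb = 1.87510407**2 * math.sqrt(ei / (mu * geom.length**4))
        assert leaf.natural_frequency == pytest.approx(omega_eb, rel=0.02)


class TestDetectImpacts:
    def setup_method(self):
        self.leaf = make_leaf()
        u, w, n = self.leaf.axes()
        self.center = self.leaf.root + 0.5 * self.leaf.geom.length * u

    def _one_particle(self, speed):
        u, w, n = self.leaf.axes()
        p0 = self.center + 0.01 * n
        vel = -speed * n
        p1 = p0 + vel * 0.002
        return (np.array([p0]), np.array([p1]), np.array([vel]),
                np.array([4.19e-6]), np.array([1e-3]), np.array([True]))

    def test_no_particles_no_events(self):
        empty3 = np.empty((0, 3))
        events = detect_impacts(empty3, empty3, empty3, np.empty(0), np.empty(0),
                                np.empty(0, dtype=bool), [self.leaf])
        assert events == []

    def test_slow_particle_deposits_with_zero_restitution(self):
        args = self._one_particle(10.0)
        events = detect_impacts(*args, [self.leaf], restitution=0.0,
                                splash_threshold=15.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.outcome == "deposit"
        assert ev.mass == pytest.approx(4.19e-6)
        assert ev.normal_speed == pytest.approx(10.0)
        assert 0 <= ev.along <= self.leaf.geom.length

    def test_fast_particle_splashes(self):
        args = self._one_particle(20.0)
        events = detect_impacts(*args, [self.leaf], restitution=0.3,
                                splash_threshold=15.0)
        assert events[0].outcome == "splash"

    def test_intermediate_particle_rebounds(self):
        args = self._one_particle(10.0)
        events = detect_impacts(*args, [self.leaf], restitution=0.5,
                                splash_threshold=15.0, stick_speed=2.0)
        assert events[0].outcome == "rebound"

    def test_miss_produces_no_event(self):
        u, w, n = self.leaf.axes()
        p0 = self.leaf.root + (self.leaf.geom.length * 2.0) * u + 0.01 * n
        vel = -10.0 * n
        events = detect_impacts(np.array([p0]), np.array([p0 + vel * 0.002]),
                                np.array([vel]), np.array([1e-6]),
                                np.array([1e-3]), np.array([True]), [self.leaf])
        assert events == []


class TestWallFilm:
    def test_no_events_leaves_film_unchanged(self):
        film = WallFilm(LeafGeometry(0.035, 0.015, 4e-4, 33.22))
        before = film.thickness.copy()
        film_update(film, [])
        np.testing.assert_array_equal(film.thickness, before)

    def test_deposit_volume_is_conserved(self):
        film = WallFilm(LeafGeometry(0.035, 0.015, 4e-4, 33.22))
        vol = 4.19e-9
        film.deposit(0.0175, 0.0, vol, droplet_radius=1e-3)
        assert film.volume == pytest.approx(vol, rel=1e-9)

    def test_two_identical_deposits_double_the_central_thickness(self):
        film = WallFilm(LeafGeometry(0.035, 0.015, 4e-4, 33.22))
        film.deposit(0.0175, 0.0, 4.19e-9, droplet_radius=1e-3)
        h1 = film.central_thickness(0.0175, 0.0)
        film.deposit(0.0175, 0.0, 4.19e-9, droplet_radius=1e-3)
        assert film.central_thickness(0.0175, 0.0) == pytest.approx(2 * h1, rel=1e-9)

    def test_thickness_never_decreases(self):
        film = WallFilm(LeafGeometry(0.035, 0.015, 4e-4, 33.22))
        rng = np.random.default_rng(3)
        prev = film.thickness.copy()
        for _ in range(20):
            film.deposit(rng.uniform(0, 0.035), rng.uniform(-0.0075, 0.0075),
                         4e-9, droplet_radius=1e-3)
            assert np.all(film.thickness >= prev - 1e-18)
            prev = film.thickness.copy()

    def test_degenerate_patch_rejected(self):
        with pytest.raises(ValueError):
            LeafGeometry(0.0, 0.015, 4e-4, 33.22)


class TestStageClassifier:
    def _leaves(self):
        return [make_leaf()]

    def test_no_droplets_stays_in_targeted_movement(self):
        times = np.arange(1, 100) * 1e-3
        s = np.zeros((len(times), 1))
        labels = stage_timeline(times, s, None, self._leaves())
        assert set(labels) == {"targeted_movement"}

    def test_static_drop_beyond_threshold_is_drainage(self):
        leaves = self._leaves()
        geom = leaves[0].geom
        beta = math.radians(geom.beta_deg)
        s_past = geom.length * (beta + 0.35)  # rotated well past horizontal
        times = np.array([1e-3, 2e-3])
        s = np.full((2, 1), s_past)
        assert classify_stage(times, s, 0.0, leaves) == "strong_impact_drainage"

    def test_empty_history(self):
        assert classify_stage(np.empty(0), np.empty((0, 1)), None,
                              self._leaves()) == "targeted_movement"

    def test_stage_order_is_monotone(self):
        leaves = self._leaves()
        geom = leaves[0].geom
        beta = math.radians(geom.beta_deg)
        # ramp the posture up and let it fall back: labels must not regress
        ramp = np.concatenate([np.linspace(0, geom.length * (beta + 0.3), 50),
                               np.linspace(geom.length * (beta + 0.3), 0, 50)])
        times = (np.arange(len(ramp)) + 1) * 1e-3
        labels = stage_timeline(times, ramp[:, None], 0.0, leaves)
        ranks = [STAGES.index(lbl) for lbl in labels]
        assert ranks == sorted(ranks)
        assert ranks[-1] == 3


@pytest.fixture(scope="module")
def default_run():
    plant = build_plant(seed=0)
    op = OperatingPoint.at_pressure(0.4e6, NozzleSpec())
    return run_simulation(SimulationConfig(), plant, op, seed=1)


class TestRunSimulation:
    def test_zero_duration_gives_empty_series(self):
        plant = build_plant(seed=0)
        op = OperatingPoint.at_pressure(0.4e6, NozzleSpec())
        res = run_simulation(SimulationConfig(duration=0.0), plant, op, seed=1)
        assert len(res.times) == 0
        assert res.max_xi == 0.0
        assert len(res.ledger) == 0

    def test_mass_ledger_balances(self, default_run):
        assert default_run.mass_balance_error() < 1e-9

    def test_ledger_states_partition_sprayed_mass(self, default_run):
        last = default_run.ledger.iloc[-1]
        total = sum(last[c] for c in ("airborne", "deposited", "rebounded",
                                      "splashed", "ground"))
        assert total == pytest.approx(last["sprayed"], rel=1e-9)

    def test_seed_determinism(self):
        plant = build_plant(seed=0)
        op = OperatingPoint.at_pressure(0.4e6, NozzleSpec())
        cfg = SimulationConfig(duration=0.2)
        a = run_simulation(cfg, plant, op, seed=7)
        b = run_simulation(SimulationConfig(duration=0.2), build_plant(seed=0),
                           op, seed=7)
        pd.testing.assert_frame_equal(a.ledger, b.ledger)
        pd.testing.assert_frame_equal(a.xi, b.xi)
        assert a.stages == b.stages

    def test_deformation_is_positive_and_bounded(self, default_run):
        assert 0.0 < default_run.max_xi <= 0.43
        assert np.isfinite(default_run.xi.values).all()

    def test_stage_sequence_monotone_without_drainage(self, default_run):
        ranks = [STAGES.index(lbl) for lbl in default_run.stages]
        assert ranks == sorted(ranks)
        assert "strong_impact_drainage" not in default_run.stages

    def test_film_volume_bounded_by_deposited_volume(self, default_run):
        film_volume = sum(f.volume for f in default_run.films)
        deposited = default_run.ledger["deposited"].iloc[-1] / 1000.0
        assert film_volume <= deposited * (1 + 1e-9)

    def test_excessive_step_size_rejected(self):
        plant = build_plant(seed=0)
        op = OperatingPoint.at_pressure(0.4e6, NozzleSpec())
        with pytest.raises(ValueError):
            run_simulation(SimulationConfig(dt=1.0), plant, op, seed=1)
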