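"""Langevin permeation model: potential, dynamics, event detection."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from hemesam.permeation import (MorseParams, PermeationConfig, Trajectory,
                                bound_fraction, config_for_sequence,
                                detect_coordination, morse_energy,
                                nonspecific_contacts, permeation_profile,
                                simulate_permeation)


class TestMorse:
    def test_minimum_at_equilibrium(self):
        m = MorseParams(D_e=6.0, a=20.0, r_e=0.2)
        assert morse_energy(m.r_e, m) == pytest.approx(-6.0)

    def test_dissociation_limit(self):
        m = MorseParams(D_e=6.0, a=20.0, r_e=0.0)
        r = m.r_e + 20.0 / m.a
        assert abs(morse_energy(r, m)) < 6.0 * 1e-8

    def test_harmonic_curvature_by_finite_differences(self):
        m = MorseParams(D_e=4.0, a=15.0, r_e=0.3)
        h = 1e-5
        d2 = (morse_energy(m.r_e + h, m) - 2 * morse_energy(m.r_e, m)
              + morse_energy(m.r_e - h, m)) / h**2
        assert d2 == pytest.approx(2 * m.D_e * m.a**2, rel=1e-4)

    def test_negative_separation_rejected(self):
        with pytest.raises(ValueError):
            morse_energy(-0.1, MorseParams())


class TestConfig:
    def test_unstable_timestep_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="dt"):
            PermeationConfig(dt=1e-2)

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            PermeationConfig(monolayer_top=7.0, box_height=6.0)

    def test_sequence_presets(self):
        assert config_for_sequence("PAA").his_depths == ()
        assert len(config_for_sequence("PHH").his_depths) == 2
        with pytest.raises(ValueError):
            config_for_sequence("XYZ")

    def test_hash_stable_and_sensitive(self):
        c1 = config_for_sequence("PHH", seed=1)
        c2 = config_for_sequence("PHH", seed=1)
        c3 = config_for_sequence("PHH", seed=2)
        assert c1.hash() == c2.hash() != c3.hash()


def _short(sequence="PHH", **kw):
    kw.setdefault("n_steps", 5000)
    kw.setdefault("n_replicas", 2)
    kw.setdefault("n_heme", 10)
    return config_for_sequence(sequence, **kw)


class TestSimulate:
    def test_walls_and_count_conservation(self):
        trajs = simulate_permeation(_short(seed=1))
        for t in trajs:
            assert t.z.shape[0] == 10            # exact count every frame
            assert np.all(t.z >= 0.0)
            assert np.all(t.z <= t.config.box_height)

    def test_determinism_byte_identical(self):
        a = simulate_permeation(_short(seed=3))
        b = simulate_permeation(_short(seed=3))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.z, tb.z)

    def test_replicas_differ(self):
        trajs = simulate_permeation(_short(seed=3))
        assert not np.array_equal(trajs[0].z, trajs[1].z)

    def test_free_diffusion_uniform_equilibrium(self):
        """No sites, flat barrier: the long-run z-histogram is uniform
        on [0, box] (KS test on late-time samples)."""
        cfg = PermeationConfig(n_heme=30, box_height=4.0, monolayer_top=2.0,
                               his_depths=(), barrier_height=0.0,
                               dt=5e-4, n_steps=60_000, save_every=20,
                               n_replicas=3, seed=4)
        trajs = simulate_permeation(cfg)
        # thin past the slowest diffusive relaxation (~L^2/pi^2 D = 1.6
        # time units = 160 frames) so KS sees ~independent samples
        samp = np.concatenate(
            [t.z[:, t.z.shape[1] // 2::200].ravel() for t in trajs])
        stat = kstest(samp / 4.0, "uniform")
        assert stat.pvalue > 0.01

    def test_deep_well_low_temperature_capture(self):
        """Near-zero temperature with one deep site: every particle
        ends within capture distance of the site."""
        cfg = PermeationConfig(
            n_heme=10, box_height=2.0, monolayer_top=1.5,
            his_depths=(1.0,), morse=MorseParams(D_e=200.0, a=10.0),
            barrier_height=0.0, kT=0.02, dt=2e-4, n_steps=80_000,
            save_every=400, n_replicas=1, seed=5)
        trajs = simulate_permeation(cfg)
        assert np.all(np.abs(trajs[0].z[:, -1] - 1.0) < 0.3)

    def test_boltzmann_density_oracle(self):
        """Long-run z-density matches exp(-U/kT)/Z from independent
        quadrature (total-variation distance < 0.05)."""
        cfg = PermeationConfig(n_heme=30, box_height=4.0, monolayer_top=2.0,
                               his_depths=(1.2,),
                               morse=MorseParams(D_e=3.0, a=10.0),
                               barrier_height=1.0, dt=2e-4,
                               n_steps=150_000, save_every=50,
                               n_replicas=3, seed=6)
        trajs = simulate_permeation(cfg)
        edges = np.linspace(0.0, 4.0, 41)
        p = np.array([quad(lambda z: np.exp(-cfg.total_energy(z)), a, b,
                           limit=200)[0]
                      for a, b in zip(edges[:-1], edges[1:])])
        p /= p.sum()
        samp = np.concatenate(
            [t.z[:, t.z.shape[1] // 2:].ravel() for t in trajs])
        emp, _ = np.histogram(samp, bins=edges)
        tv = 0.5 * np.abs(emp / emp.sum() - p).sum()
        assert tv < 0.05


class TestCoordination:
    def _scripted(self, zpath, sites=(1.0,)):
        cfg = PermeationConfig(n_heme=1, box_height=6.0, monolayer_top=3.0,
                               his_depths=tuple(sites), n_steps=10,
                               n_replicas=1)
        z = np.asarray(zpath, float)[None, :]
        return Trajectory(np.arange(z.shape[1], dtype=float), z,
                          "rep0", cfg)

    def test_never_approaching_no_events(self):
        t = self._scripted([5.0, 5.2, 4.8, 5.1, 5.0])
        assert detect_coordination(t) == []
        assert np.all(t.bound_site == -1)

    def test_single_crossing_one_formation_one_rupture(self):
        t = self._scripted([3.0, 1.1, 1.0, 1.2, 2.0, 3.0])
        events = detect_coordination(t, capture_r=0.3, release_r=0.5)
        assert len(events) == 1
        ev = events[0]
        assert ev.t_form == 1.0 and ev.t_rupture == 4.0

    def test_hysteresis_suppresses_chatter(self):
        """Oscillation between capture_r and release_r stays bound."""
        t = self._scripted([1.0, 1.35, 1.05, 1.4, 1.1, 1.38])
        events = detect_coordination(t, capture_r=0.3, release_r=0.5)
        assert len(events) == 1 and events[0].t_rupture is None

    def test_site_occupancy_capped_first_come(self):
        cfg = PermeationConfig(n_heme=2, box_height=6.0, monolayer_top=3.0,
                               his_depths=(1.0,), n_steps=10, n_replicas=1)
        z = np.array([[1.0, 1.0, 1.0], [1.05, 1.05, 1.05]])
        t = Trajectory(np.arange(3.0), z, "rep0", cfg)
        detect_coordination(t)
        assert np.sum(t.bound_site[:, 0] >= 0) == 1

    def test_invalid_hysteresis_rejected(self):
        t = self._scripted([5.0, 5.0])
        with pytest.raises(ValueError):
            detect_coordination(t, capture_r=0.5, release_r=0.3)

    def test_equilibrium_formation_rupture_balance(self):
        """At equilibrium the formation and rupture counts agree within
        Poisson counting error."""
        cfg = PermeationConfig(n_heme=20, box_height=3.0, monolayer_top=2.0,
                               his_depths=(1.0,),
                               morse=MorseParams(D_e=2.5, a=10.0),
                               barrier_height=0.0, dt=2e-4,
                               n_steps=150_000, save_every=25,
                               n_replicas=1, seed=7)
        traj = simulate_permeation(cfg)[0]
        # discard the transient third
        nf = traj.z.shape[1]
        sub = Trajectory(traj.times[nf // 3:], traj.z[:, nf // 3:],
                         traj.replica_id, cfg)
        events = detect_coordination(sub)
        n_form = sum(1 for e in events if e.t_form > sub.times[0])
        n_rupt = sum(1 for e in events if e.t_rupture is not None)
        assert abs(n_form - n_rupt) <= 3 * np.sqrt(max(n_form + n_rupt, 1))


class TestProfilesAndFractions:
    def test_single_replica_sd_zero(self):
        trajs = simulate_permeation(_short(n_replicas=1, seed=8))
        prof = permeation_profile(trajs, n_windows=3)
        assert np.all(prof.sd == 0.0)

    def test_identical_replicas_sd_zero(self):
        t = simulate_permeation(_short(n_replicas=1, seed=9))[0]
        clone = Trajectory(t.times, t.z.copy(), "rep1", t.config)
        prof = permeation_profile([t, clone], n_windows=2)
        assert np.allclose(prof.sd, 0.0)
        assert np.allclose(prof.mean,
                           permeation_profile([t], n_windows=2).mean)

    def test_histograms_count_conserving(self):
        trajs = simulate_permeation(_short(seed=10))
        prof = permeation_profile(trajs, n_windows=4)
        sums = prof.mean.sum(axis=1)
        assert np.allclose(sums, trajs[0].z.shape[0], rtol=1e-9)

    def test_inconsistent_boxes_rejected(self):
        a = simulate_permeation(_short(seed=1, n_replicas=1))[0]
        cfg2 = config_for_sequence("PHH", n_steps=5000, n_replicas=1,
                                   n_heme=10, box_height=8.0)
        b = simulate_permeation(cfg2)[0]
        with pytest.raises(ValueError):
            permeation_profile([a, b])

    def test_no_sites_bound_fraction_identically_zero(self):
        trajs = simulate_permeation(_short("PAA", seed=11))
        _, so, hb, _, _ = bound_fraction(trajs)
        assert np.all(so == 0.0) and np.all(hb == 0.0)

    def test_bound_fractions_in_unit_interval(self):
        trajs = simulate_permeation(_short("PAH", seed=12, n_steps=20_000))
        _, so, hb, _, _ = bound_fraction(trajs)
        assert np.all((0 <= so) & (so <= 1)) and np.all((0 <= hb) & (hb <= 1))

    def test_nonspecific_contacts_definition(self):
        trajs = simulate_permeation(_short("PAH", seed=13, n_steps=20_000))
        times, ns, _ = nonspecific_contacts(trajs)
        # all above the monolayer at t=0 by construction
        assert ns[0] == 0.0
        assert np.all(ns >= 0)

    def test_nonspecific_contacts_uniform_fraction(self):
        """Free diffusion: expected in-slab count = n*(top/box)."""
        cfg = PermeationConfig(n_heme=30, box_height=4.0, monolayer_top=1.5,
                               his_depths=(), barrier_height=0.0,
                               dt=5e-4, n_steps=60_000, save_every=30,
                               n_replicas=3, seed=14)
        trajs = simulate_permeation(cfg)
        _, ns, _ = nonspecific_contacts(trajs)
        late = ns[len(ns) // 2:].mean()
        assert late == pytest.approx(30 * 1.5 / 4.0, rel=0.1)
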