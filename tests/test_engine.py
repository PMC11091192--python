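"""Engine tests: SAW initial states, integrator physics, replica running."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import chrom4d as c4
from chrom4d import _kernels
from chrom4d.engine import Simulator, init_saw_conformation, kinetic_temperature


def _homopolymer(n, affinity=0.0):
    aff = np.array([[affinity]])
    return c4.PolymerModel(bead_types=np.zeros(n, dtype=int), type_labels=["U"],
                           g_bp=5000.0, affinity_matrix=aff)


class TestSawInit:
    def test_single_bead_at_box_centre(self):
        conf = init_saw_conformation(1, 20.0, seed=0)
        assert np.allclose(conf.beads[0], [10.0, 10.0, 10.0])

    def test_deterministic_given_seed(self):
        a = init_saw_conformation(10, 20.0, seed=7)
        b = init_saw_conformation(10, 20.0, seed=7)
        np.testing.assert_array_equal(a.beads, b.beads)

    def test_unit_bonds_and_excluded_volume(self):
        conf = init_saw_conformation(50, 20.0, seed=3)
        np.testing.assert_allclose(conf.bond_lengths(), 1.0, atol=1e-12)
        # brute-force all-pairs scan: no two beads closer than 1 sigma
        assert pdist(conf.beads).min() >= 1.0 - 1e-12

    def test_box_too_small_raises(self):
        with pytest.raises((RuntimeError, ValueError)):
            init_saw_conformation(500, 4.0, seed=0)


class TestIntegrator:
    def test_nve_energy_conservation(self):
        """With friction and noise off, BAOAB is velocity Verlet.  After a
        short thermalisation, total energy drift over 1e4 NVE steps at
        dt = 0.01 stays below the declared bound of 0.02 kBT per particle
        (energy bookkeeping oracle via the all-pairs potential)."""
        model = _homopolymer(30)
        cfg = c4.SimulationConfig(box_L=15.0, n_equil_steps=0,
                                  n_production_steps=10_000, sample_interval=10_000,
                                  rng_seed=5)
        sim = Simulator(model, cfg)
        rng = np.random.default_rng(5)
        x, v = sim._init_arrays(rng)
        img = np.zeros_like(x, dtype=np.int64)
        f = np.zeros_like(x)
        n = x.shape[0]
        cap = sim._nlist_capacity()
        pi = np.zeros(cap, dtype=np.int64)
        pj = np.zeros(cap, dtype=np.int64)
        st = np.zeros(1, dtype=np.int64)
        xb = x.copy()
        rc2 = (sim._rc_nb + sim.SKIN) ** 2
        st[0] = _kernels._build_pairs(x, cfg.box_L, rc2, pi, pj)
        e = np.empty(0, dtype=np.int64)
        _kernels._forces(x, f, cfg.box_L, sim.is_binder, sim.type_id, sim.n_beads,
                         sim.eps_lj, model.r_int, sim.R0, sim.K_fene,
                         e, e, 0.0, 1.1, pi, pj, st[0])
        # thermalise away from the stiff lattice start (thermostat on) ...
        noise = rng.standard_normal((3000, n, 3))
        ke_tr = np.empty(3000)
        status = _kernels._run_chunk(
            x, img, v, f, noise, cfg.dt, 0.5, cfg.T, 1.0, cfg.box_L,
            sim.is_binder, sim.type_id, sim.n_beads, sim.eps_lj, model.r_int,
            sim.R0, sim.K_fene, e, e, 0.0, 1.1, pi, pj, st, xb,
            sim.SKIN, sim._rc_nb, ke_tr,
        )
        assert status == _kernels.OK
        # ... then integrate at zeta = 0 and compare start/end total energy
        e0 = ke_tr[-1] + sim.potential_energy(x + img * cfg.box_L)
        noise = np.zeros((10_000, n, 3))
        ke_tr = np.empty(10_000)
        status = _kernels._run_chunk(
            x, img, v, f, noise, cfg.dt, 0.0, cfg.T, 1.0, cfg.box_L,
            sim.is_binder, sim.type_id, sim.n_beads, sim.eps_lj, model.r_int,
            sim.R0, sim.K_fene, e, e, 0.0, 1.1, pi, pj, st, xb,
            sim.SKIN, sim._rc_nb, ke_tr,
        )
        assert status == _kernels.OK
        e1 = ke_tr[-1] + sim.potential_energy(x + img * cfg.box_L)
        assert abs(e1 - e0) < 0.02 * n

    def test_deterministic_step_given_seed(self):
        model = _homopolymer(20)
        cfg = c4.SimulationConfig(box_L=12.0, n_equil_steps=0,
                                  n_production_steps=500, sample_interval=500,
                                  rng_seed=9)
        sim = Simulator(model, cfg)
        t1 = sim.run_replica(seed=9)
        t2 = sim.run_replica(seed=9)
        np.testing.assert_array_equal(t1.positions(), t2.positions())

    def test_fene_invariant_along_trajectory(self, small_homopolymer_traj):
        for frame in small_homopolymer_traj.frames:
            frame.check_fene()
        assert max(f.bond_lengths().max() for f in small_homopolymer_traj.frames) < 1.6

    def test_verlet_list_forces_match_all_pairs(self):
        """Neighbour-list contract: forces identical (to round-off) to the
        all-pairs reference on a small mixed bead/binder system."""
        model = c4.build_compartment_model(n_beads=30, block_size=15)
        cfg = c4.SimulationConfig(box_L=10.0, rng_seed=1)
        sim = Simulator(model, cfg)
        rng = np.random.default_rng(4)
        x, _ = sim._init_arrays(rng)
        f_list = sim.forces(x, all_pairs=False)
        f_ref = sim.forces(x, all_pairs=True)
        np.testing.assert_allclose(f_list, f_ref, atol=1e-10)


class TestRunReplicas:
    def test_schedule_arithmetic(self):
        model = _homopolymer(15)
        cfg = c4.SimulationConfig(box_L=10.0, n_equil_steps=10_000,
                                  n_production_steps=10_000, sample_interval=1000,
                                  n_replicas=1, rng_seed=2)
        ens = c4.run_replicas(model, cfg)
        traj = ens.trajectories[0]
        assert len(traj) == 10
        times = traj.times()
        assert times[0] == 11_000 and times[-1] == 20_000
        assert np.all(np.diff(times) == 1000)

    def test_distinct_seeds_give_distinct_states(self):
        model = _homopolymer(15)
        cfg = c4.SimulationConfig(box_L=10.0, n_equil_steps=500,
                                  n_production_steps=500, sample_interval=500,
                                  n_replicas=2, rng_seed=3)
        ens = c4.run_replicas(model, cfg)
        a, b = ens.trajectories
        assert not np.allclose(a.frames[-1].beads, b.frames[-1].beads)

    def test_replica_seeds_distinct(self):
        cfg = c4.SimulationConfig(n_replicas=30, rng_seed=123)
        seeds = cfg.replica_seeds()
        assert len(set(seeds)) == 30


class TestThermostatAndCollapse:
    def test_kinetic_temperature_short_run(self):
        """Coarse equipartition sanity check on a short run (the long-run
        5% check runs with the acceptance suite)."""
        model = _homopolymer(50)
        cfg = c4.SimulationConfig(box_L=15.0, n_equil_steps=2000,
                                  n_production_steps=10_000, sample_interval=10_000,
                                  rng_seed=6)
        sim = Simulator(model, cfg)
        ke = []
        sim.run_replica(seed=6, ke_log=ke)
        kes = np.concatenate([tr for t0, tr in ke if t0 >= 2000])
        kT = kinetic_temperature(kes, 50).mean()
        assert kT == pytest.approx(1.0, rel=0.1)

    def test_binders_collapse_the_chain(self):
        """Coil-globule: cognate binders above the transition shrink the
        mean radius of gyration of a homopolymer vs the eps = 0 coil."""
        from chrom4d.metrics import gyration_shape

        def mean_rg(affinity):
            model = _homopolymer(40, affinity)
            counts = {0: 20} if affinity > 0 else {0: 0}
            cfg = c4.SimulationConfig(box_L=12.0, n_equil_steps=15_000,
                                      n_production_steps=15_000, sample_interval=3000,
                                      n_replicas=2, rng_seed=21,
                                      binder_counts=counts)
            ens = c4.run_replicas(model, cfg)
            return np.mean([np.sqrt(gyration_shape(f.beads).rg2)
                            for t in ens for f in t.frames])

        assert mean_rg(3.5) < 0.8 * mean_rg(0.0)
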