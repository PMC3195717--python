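import numpy as np
import pytest

import dissipy as d
from dissipy.enm import kinetic_energy, spring_energies
from dissipy.errors import IndexErrorInput, InputError
from dissipy.units import KB_KCAL_MOL, KCAL_MOL_TO_INTERNAL

from conftest import naive_verlet


def _pairs(net):
    return set(zip(net.spring_i.tolist(), net.spring_j.tolist()))


class TestBuildNetwork:
    def test_collinear_cutoff_6(self):
        s = d.synth_structure(3, "chain", spacing=5.0)
        net = d.build_network(s, cutoff=6.0)
        assert _pairs(net) == {(0, 1), (1, 2)}
        np.testing.assert_allclose(net.rest_length, [5.0, 5.0])

    def test_collinear_cutoff_11(self):
        s = d.synth_structure(3, "chain", spacing=5.0)
        net = d.build_network(s, cutoff=11.0)
        assert _pairs(net) == {(0, 1), (0, 2), (1, 2)}

    def test_complete_graph(self):
        s = d.synth_structure(8, "globule", seed=1)
        net = d.build_network(s, cutoff=1e6)
        assert net.n_springs == 8 * 7 // 2

    def test_rest_lengths_give_zero_initial_pe(self, globule60_net):
        assert spring_energies(globule60_net,
                               globule60_net.positions).sum() == 0.0

    def test_isolated_bead_warns(self, caplog):
        s = d.synth_structure(3, "chain", spacing=50.0)
        import logging
        with caplog.at_level(logging.WARNING, logger="dissipy.enm"):
            net = d.build_network(s, cutoff=5.0)
        assert net.n_springs == 0
        assert "isolated" in caplog.text

    def test_bad_cutoff(self, chain20):
        with pytest.raises(InputError):
            d.build_network(chain20, cutoff=-1.0)


class TestInitState:
    def test_zero_temperature(self, chain20_net):
        st = d.init_state(chain20_net, temperature=0.0, seed=4)
        assert np.all(st.velocities == 0.0)

    def test_determinism(self, chain20_net):
        a = d.init_state(chain20_net, 310.0, seed=9)
        b = d.init_state(chain20_net, 310.0, seed=9)
        assert np.array_equal(a.velocities, b.velocities)
        assert np.array_equal(a.positions, b.positions)

    def test_net_momentum_removed(self, globule60_net):
        st = d.init_state(globule60_net, 310.0, seed=2)
        p = (globule60_net.masses[:, None] * st.velocities).sum(axis=0)
        np.testing.assert_allclose(p, 0.0, atol=1e-12)

    def test_equipartition_over_seeds(self, chain20_net):
        # removing net momentum leaves 3(N-1) quadratic dof:
        # E[KE] = (3/2)(N-1) kB T exactly
        n = chain20_net.n_beads
        temps = [kinetic_energy(chain20_net,
                                d.init_state(chain20_net, 310.0, seed=s)).sum()
                 for s in range(400)]
        expected = 1.5 * (n - 1) * KB_KCAL_MOL * 310.0
        assert np.mean(temps) == pytest.approx(expected, rel=0.03)


class TestIntegrate:
    def test_fixed_point(self, chain20_net):
        st = d.init_state(chain20_net, 0.0, seed=0)
        frames = d.integrate(chain20_net, st,
                             d.SimulationConfig(n_steps=100, save_interval=10))
        for fr in frames:
            np.testing.assert_array_equal(fr.positions, st.positions)
            np.testing.assert_array_equal(fr.velocities, st.velocities)

    def test_two_bead_oscillator_frequency(self):
        # analytic: omega = sqrt(k (1/m1 + 1/m2)), relative coordinate
        # oscillates as r0 + d cos(omega t)
        m1, m2, k, r0, stretch = 80.0, 140.0, 2.0, 3.8, 0.2
        s = d.ProteinStructure(residues=[
            d.Residue(1, "ALA", "A", m1, np.zeros(3)),
            d.Residue(2, "GLY", "A", m2, np.array([r0 + stretch, 0, 0])),
        ])
        net = d.build_network(s, cutoff=10.0, stiffness=k)
        net.rest_length[:] = r0
        st = d.SystemState(positions=s.positions,
                           velocities=np.zeros((2, 3)))
        cfg = d.SimulationConfig(timestep=0.5, n_steps=8000, save_interval=1)
        frames = d.integrate(net, st, cfg)
        sep = np.array([np.linalg.norm(f.positions[1] - f.positions[0])
                        for f in frames])
        t = np.array([f.time for f in frames])
        omega = np.sqrt(k * KCAL_MOL_TO_INTERNAL * (1 / m1 + 1 / m2))
        np.testing.assert_allclose(sep, r0 + stretch * np.cos(omega * t),
                                   atol=0.01 * stretch)

    def test_energy_drift(self, globule60_net):
        st = d.init_state(globule60_net, 310.0, seed=8)
        e0 = d.total_energy(globule60_net, st)
        frames = d.integrate(globule60_net, st,
                             d.SimulationConfig(n_steps=10_000,
                                                save_interval=1000))
        e1 = d.total_energy(globule60_net, frames[-1])
        assert abs(e1 - e0) / abs(e0) <= 1e-4

    def test_matches_brute_force_integrator(self):
        # independent oracle: pure-python velocity Verlet
        s = d.synth_structure(5, "chain", spacing=3.8)
        net = d.build_network(s, cutoff=4.0)
        st = d.init_state(net, 310.0, seed=6)
        springs = list(zip(net.spring_i.tolist(), net.spring_j.tolist(),
                           net.stiffness.tolist(), net.rest_length.tolist()))
        x_ref, v_ref, _ = naive_verlet(net.masses.tolist(), springs,
                                       st.positions, st.velocities,
                                       dt=1.0, n_steps=200)
        frames = d.integrate(net, st, d.SimulationConfig(n_steps=200,
                                                         save_interval=200))
        np.testing.assert_allclose(frames[-1].positions, x_ref, atol=1e-10)
        np.testing.assert_allclose(frames[-1].velocities, v_ref, atol=1e-10)


class TestPerResidueEnergy:
    def test_all_zero_at_rest(self, chain20_net):
        st = d.init_state(chain20_net, 0.0, seed=0)
        assert np.all(d.per_residue_energy(chain20_net, st) == 0.0)

    def test_stretched_spring_split(self):
        k, r0, stretch = 1.5, 3.8, 0.4
        s = d.ProteinStructure(residues=[
            d.Residue(1, "ALA", "A", 110.0, np.zeros(3)),
            d.Residue(2, "ALA", "A", 110.0, np.array([r0, 0, 0])),
        ])
        net = d.build_network(s, cutoff=5.0, stiffness=k)
        st = d.SystemState(
            positions=np.array([[0, 0, 0], [r0 + stretch, 0, 0.0]]),
            velocities=np.zeros((2, 3)))
        e = d.per_residue_energy(net, st)
        np.testing.assert_allclose(e, 0.25 * k * stretch ** 2)

    def test_partition_sums_to_total(self, globule60_net, rng):
        st = d.init_state(globule60_net, 310.0, seed=3)
        st.positions += rng.normal(0, 0.05, st.positions.shape)
        e = d.per_residue_energy(globule60_net, st)
        total = d.total_energy(globule60_net, st)
        assert e.sum() == pytest.approx(total, rel=1e-9)


class TestApplyPerturbation:
    def test_f1_identity(self, chain20_net):
        st = d.init_state(chain20_net, 310.0, seed=1)
        out = d.apply_perturbation(st, d.Perturbation(frozenset({3}), 1.0))
        assert np.array_equal(out.velocities, st.velocities)
        assert np.array_equal(out.positions, st.positions)

    def test_ke_times_f_squared(self, chain20_net):
        st = d.init_state(chain20_net, 310.0, seed=1)
        ke0 = kinetic_energy(chain20_net, st)
        out = d.apply_perturbation(st, d.Perturbation(frozenset({5}), 4.0))
        ke1 = kinetic_energy(chain20_net, out)
        assert ke1[4] == pytest.approx(16.0 * ke0[4], rel=1e-12)
        np.testing.assert_array_equal(np.delete(ke1, 4), np.delete(ke0, 4))

    def test_total_energy_bookkeeping(self, chain20_net):
        st = d.init_state(chain20_net, 310.0, seed=2)
        ke0 = kinetic_energy(chain20_net, st)
        out = d.apply_perturbation(st, d.Perturbation(frozenset({2, 7}), 2.0))
        de = (d.total_energy(chain20_net, out)
              - d.total_energy(chain20_net, st))
        assert de == pytest.approx(3.0 * (ke0[1] + ke0[6]), rel=1e-12)

    def test_unknown_index(self, chain20_net):
        st = d.init_state(chain20_net, 310.0, seed=1)
        with pytest.raises(IndexErrorInput):
            d.apply_perturbation(st, d.Perturbation(frozenset({99}), 2.0))


class TestEquilibrate:
    def test_deterministic_and_near_target(self, globule60_net):
        cfg = d.SimulationConfig(equilibration_steps=500, temperature=310.0)
        st = d.init_state(globule60_net, 310.0, seed=7)
        a = d.equilibrate(globule60_net, st, cfg)
        b = d.equilibrate(globule60_net, st, cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)
        n = globule60_net.n_beads
        ke = kinetic_energy(globule60_net, a).sum()
        target = 1.5 * n * KB_KCAL_MOL * 310.0
        # NVE wanders between rescales; just require the right ballpark
        assert 0.5 * target < ke < 1.5 * target


class TestRunPair:
    def test_f1_bit_identical(self, chain20_net):
        st = d.init_state(chain20_net, 310.0, seed=4)
        cfg = d.SimulationConfig(n_steps=200, save_interval=10)
        p, r = d.run_pair(chain20_net, st,
                          d.Perturbation(frozenset({1}), 1.0), cfg)
        assert np.array_equal(p.energies, r.energies)
        assert np.array_equal(p.times, r.times)

    def test_frame0_difference_localized(self, chain20_net):
        st = d.init_state(chain20_net, 310.0, seed=4)
        ke0 = kinetic_energy(chain20_net, st)
        cfg = d.SimulationConfig(n_steps=50, save_interval=10)
        f = 4.0
        p, r = d.run_pair(chain20_net, st,
                          d.Perturbation(frozenset({3}), f), cfg)
        diff0 = p.energies[:, 0] - r.energies[:, 0]
        assert diff0[2] == pytest.approx((f ** 2 - 1) * ke0[2], rel=1e-12)
        np.testing.assert_array_equal(np.delete(diff0, 2), 0.0)

    def test_determinism(self, chain20_net):
        cfg = d.SimulationConfig(n_steps=100, save_interval=10, seed=5)
        pert = d.Perturbation(frozenset({2}), 3.0)
        st1 = d.init_state(chain20_net, 310.0, seed=5)
        st2 = d.init_state(chain20_net, 310.0, seed=5)
        p1, r1 = d.run_pair(chain20_net, st1, pert, cfg)
        p2, r2 = d.run_pair(chain20_net, st2, pert, cfg)
        assert np.array_equal(p1.energies, p2.energies)
        assert np.array_equal(r1.energies, r2.energies)

    def test_causality_disconnected_component(self):
        # two 5-bead chains 100 A apart: no spring path between them
        import dissipy.structures as ds
        res = []
        for i in range(5):
            res.append(ds.Residue(i + 1, "ALA", "A", 110.0,
                                  np.array([3.8 * i, 0.0, 0.0])))
        for i in range(5):
            res.append(ds.Residue(i + 6, "ALA", "A", 110.0,
                                  np.array([3.8 * i, 100.0, 0.0])))
        s = ds.ProteinStructure(residues=res)
        net = d.build_network(s, cutoff=5.0)
        st = d.init_state(net, 310.0, seed=3)
        cfg = d.SimulationConfig(n_steps=500, save_interval=10)
        p, r = d.run_pair(net, st, d.Perturbation(frozenset({1}), 4.0), cfg)
        delta = p.energies - r.energies
        np.testing.assert_array_equal(delta[5:], 0.0)

    def test_later_divergence_down_the_chain(self, chain20_net):
        # brute-force re-run oracle: the naive integrator applied to the
        # perturbed and reference states reproduces the divergence
        st = d.init_state(chain20_net, 310.0, seed=11)
        cfg = d.SimulationConfig(n_steps=3000, save_interval=10)
        pert = d.Perturbation(frozenset({1}), 4.0)
        p, r = d.run_pair(chain20_net, st, pert, cfg)
        delta = np.abs(p.energies - r.energies)
        first = [np.argmax(delta[i] > 1e-9) if np.any(delta[i] > 1e-9) else -1
                 for i in range(20)]
        # the divergence front moves monotonically down the chain; any
        # still-silent residues sit at the far end
        responded = [f for f in first if f >= 0]
        assert len(responded) >= 10
        assert responded == sorted(responded)
        assert first[len(responded):] == [-1] * (20 - len(responded))
        springs = list(zip(chain20_net.spring_i.tolist(),
                           chain20_net.spring_j.tolist(),
                           chain20_net.stiffness.tolist(),
                           chain20_net.rest_length.tolist()))
        pst = d.apply_perturbation(st, pert)
        xp, _, _ = naive_verlet(chain20_net.masses.tolist(), springs,
                                pst.positions, pst.velocities, 1.0, 300)
        xr, _, _ = naive_verlet(chain20_net.masses.tolist(), springs,
                                st.positions, st.velocities, 1.0, 300)
        assert np.linalg.norm(xp - xr) > 0


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"timestep": 0.0}, {"save_interval": 0}, {"cutoff": -1.0},
    ])
    def test_bad_config(self, kwargs):
        with pytest.raises(InputError):
            d.SimulationConfig(**kwargs)

    def test_bad_perturbation(self):
        with pytest.raises(InputError):
            d.Perturbation(frozenset(), 2.0)
        with pytest.raises(InputError):
            d.Perturbation(frozenset({1}), 0.0)
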