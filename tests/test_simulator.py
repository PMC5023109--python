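"""Transport-step correctness, furrow tracking and perturbations."""

import numpy as np
import pytest

from eyedisc import (
    EyeDiscSimulation,
    ModelParameters,
    Perturbation,
    initial_state,
    make_ellipse_mesh,
    track_mf,
)
from eyedisc import fem
from eyedisc.errors import ConfigurationRejected
from eyedisc.simulator import apply_perturbation

HOUR = 3600.0


def total_mass(sim, species="Hh"):
    m = fem.lumped_mass(sim.mesh.points, sim.mesh.tris)
    return float(m @ getattr(sim.state, f"c_{species}"))


class TestTransportStep:
    def test_mass_conserved_without_reactions_or_growth(self):
        """Zero-flux pure diffusion conserves each species' total mass."""
        p = ModelParameters(target_edge=5.0)
        sim = EyeDiscSimulation(p, growth=False, reactions=False, hh_influx=False)
        # localized initial blob of Hh so diffusion actually does something;
        # transport must still conserve mass despite the nonzero decay term
        # being disabled only through delta -> we keep decay, so use Hth mass
        # balance against its exact exponential instead; here: zero decay proxy
        sim.state.c_Hh[:] = np.exp(
            -((sim.mesh.points[:, 0] + 20) ** 2 + sim.mesh.points[:, 1] ** 2) / 100.0
        )
        m = fem.lumped_mass(sim.mesh.points, sim.mesh.tris)
        masses = [float(m @ sim.state.c_Hh)]
        # remove decay for the conservation check
        sim.base_params = p.replace(delta_Hh=1e-300)
        for _ in range(20):
            sim.step(250.0)
            masses.append(total_mass(sim, "Hh"))
        per_step = np.abs(np.diff(masses)) / masses[0]
        assert per_step.max() < 1e-6

    def test_single_species_decay_matches_closed_form(self):
        """Total mass after T equals M0 exp(-delta T) within 0.1%."""
        p = ModelParameters(target_edge=5.0, dt_max=100.0)
        sim = EyeDiscSimulation(p, growth=False, reactions=False, hh_influx=False)
        sim.state.c_Hh[:] = 1.0
        M0 = total_mass(sim, "Hh")
        T = 1.0 * HOUR
        n = int(T / 100.0)
        for _ in range(n):
            sim.step(100.0)
        expected = M0 * np.exp(-p.delta_Hh * T)
        assert total_mass(sim, "Hh") == pytest.approx(expected, rel=1e-3)

    def test_small_dt_consistency(self):
        """Halving dt changes the state only at the splitting-error level."""
        def run(dt, steps):
            p = ModelParameters(target_edge=6.0, dt_max=250.0)
            sim = EyeDiscSimulation(p, growth=False)
            for _ in range(steps):
                sim.step(dt)
            return sim.state.c_Hh

        c1 = run(250.0, 8)
        c2 = run(125.0, 16)
        denom = max(np.abs(c1).max(), 1e-12)
        assert np.abs(c1 - c2).max() / denom < 0.05

    def test_determinism(self):
        """Identical configurations produce bitwise-identical trajectories."""
        def run():
            sim = EyeDiscSimulation(ModelParameters(target_edge=6.0))
            res = sim.run(8.0, output_every_h=1.0)
            return res.PL_um, res.area_total

        PL1, A1 = run()
        PL2, A2 = run()
        np.testing.assert_array_equal(PL1, PL2)
        np.testing.assert_array_equal(A1, A2)

    def test_partition_of_unity_maintained(self):
        sim = EyeDiscSimulation(ModelParameters(target_edge=6.0))
        for _ in range(30):
            sim.step(250.0)
        np.testing.assert_allclose(
            sim.state.Pi + sim.state.Theta + sim.state.Phi, 1.0, atol=1e-12
        )
        for c in sim.state.concentrations().values():
            assert np.all(c >= 0)


class TestGrowthConsistency:
    def test_area_tracks_source_integral(self):
        """Growth-only run: area matches the dA/dt = S*A closed form within 2%."""
        p = ModelParameters(target_edge=5.0)
        sim = EyeDiscSimulation(p, reactions=False, hh_influx=False)
        # keep every cell a progenitor so S = k0 uniformly: disable Hth decay
        sim.base_params = p.replace(delta_Hth=1e-300, p_Hth=1e-300)
        A0 = sim.mesh.area
        T = 5.0 * HOUR
        n = int(T / 250.0)
        for _ in range(n):
            sim.step(250.0)
        # dilution lowers c_Hth but it must stay above theta for Pi = 1;
        # with growth-only exact solution A(t) = A0 exp(k0 t)
        assert sim.state.Pi.min() == 1.0
        expected = A0 * np.exp(p.k0 * T)
        assert sim.mesh.area == pytest.approx(expected, rel=0.02)

    def test_anisotropy_of_uniform_growth(self):
        from eyedisc.flow import anisotropy, growth_source, solve_velocity

        p = ModelParameters(target_edge=5.0)
        sim = EyeDiscSimulation(p)
        S = growth_source(np.ones(sim.mesh.n_nodes), 0.0, p)
        v = solve_velocity(sim.mesh, S, p)
        assert anisotropy(sim.mesh, v.u) == pytest.approx(1.0, abs=0.05)


class TestTrackMF:
    def test_initial_state_has_no_furrow(self):
        p = ModelParameters(target_edge=5.0)
        sim = EyeDiscSimulation(p)
        assert track_mf(sim.state, sim.mesh, p) == 0.0

    def test_fully_differentiated_returns_full_length(self):
        p = ModelParameters(target_edge=5.0)
        sim = EyeDiscSimulation(p)
        sim.state.c_Hth[:] = 0.0
        PL = track_mf(sim.state, sim.mesh, p)
        assert PL == pytest.approx(sim.mesh.L_AP, rel=0.02)

    def test_interpolated_crossing(self):
        """PL is the sub-element interpolated crossing of theta_Hth."""
        p = ModelParameters(target_edge=5.0)
        sim = EyeDiscSimulation(p)
        x_rel = np.asarray(sim.mesh.x_relative(sim.mesh.points[:, 0]))
        # linear Hth ramp crossing theta at exactly x_rel = 30
        sim.state.c_Hth = p.theta_Hth + (x_rel - 30.0) * 0.01
        np.maximum(sim.state.c_Hth, 0.0, out=sim.state.c_Hth)
        assert track_mf(sim.state, sim.mesh, p) == pytest.approx(30.0, abs=0.5)


class TestPerturbations:
    def test_scale_factor_one_is_identity(self):
        p = ModelParameters(target_edge=6.0)
        r1 = EyeDiscSimulation(p).run(6.0)
        r2 = EyeDiscSimulation(
            p, perturbations=[Perturbation("p_Hh", 1.0)]
        ).run(6.0)
        np.testing.assert_array_equal(r1.PL_um, r2.PL_um)
        np.testing.assert_array_equal(r1.area_total, r2.area_total)

    def test_global_scaling(self):
        p = ModelParameters()
        eff = apply_perturbation(p, [Perturbation("p_Hh", 0.5)], t_h=1.0)
        assert eff.p_Hh == pytest.approx(0.5 * p.p_Hh)
        # not yet active
        eff = apply_perturbation(p, [Perturbation("p_Hh", 0.5, t_on_h=10.0)], t_h=1.0)
        assert eff.p_Hh == p.p_Hh

    def test_set_mode_and_unknown_parameter(self):
        p = ModelParameters()
        eff = apply_perturbation(p, [Perturbation("eta", 1e-5, mode="set")], 0.0)
        assert eff.eta == 1e-5
        with pytest.raises(ConfigurationRejected):
            apply_perturbation(p, [Perturbation("nonsense", 1.0)], 0.0)

    def test_clone_mask_advects_with_tissue(self):
        """Clone node sets ride with the mesh, so the marked region keeps
        its identity while the disc grows."""
        p = ModelParameters(target_edge=6.0)
        pert = Perturbation("p_Hh", 0.0, region={"center": (20.0, 0.0), "radius": 12.0},
                            t_on_h=0.0)
        sim = EyeDiscSimulation(p, perturbations=[pert])
        sim.step(250.0)
        mask0 = sim.clone_masks[0].copy()
        n_marked = int(mask0.sum())
        assert n_marked > 0
        for _ in range(40):
            sim.step(250.0)
        # no remesh in this window: identical node identity
        assert int(sim.clone_masks[0].sum()) == n_marked
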