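"""Nonlinear FE solver: cavity volume, equilibrium, oracles, invariants."""

import numpy as np
import pytest

from embryoheart import fem, geometry as g
from embryoheart.constitutive import (
    MMHG_TO_PA,
    ActiveParams,
    FungParams,
    NORMAL_FUNG,
)


@pytest.fixture(scope="module")
def inflated(ventricle_coarse):
    prob = fem.ventricle_problem(ventricle_coarse, NORMAL_FUNG)
    state = fem.solve_pressure_step(prob, 0.38 * MMHG_TO_PA)
    return prob, state


class TestCavityVolume:
    def test_closed_sphere(self):
        m = g.ventricle_shell_mesh(
            semi_axes=(1.0, 1.0, 1.0),
            wall_thickness=0.2,
            base_crop_fraction=0.0,
            target_element_count=6000,
        )
        assert fem.cavity_volume(m) == pytest.approx(4 / 3 * np.pi, rel=0.01)

    def test_rigid_translation_invariance(self, ventricle_coarse):
        u = np.tile([0.3, -0.2, 0.15], (ventricle_coarse.n_nodes, 1))
        assert fem.cavity_volume(ventricle_coarse, u) == pytest.approx(
            fem.cavity_volume(ventricle_coarse), rel=1e-12
        )

    def test_uniform_dilation(self, ventricle_coarse):
        lam = 1.07
        u = (lam - 1.0) * ventricle_coarse.nodes
        # dilation about the origin moves the basal plane too; use a closed
        # shell where the scaling argument is exact
        m = g.ventricle_shell_mesh(
            semi_axes=(1.0, 1.0, 1.0),
            wall_thickness=0.2,
            base_crop_fraction=0.0,
            target_element_count=1500,
        )
        u = (lam - 1.0) * m.nodes
        assert fem.cavity_volume(m, u) == pytest.approx(
            lam**3 * fem.cavity_volume(m), rel=1e-10
        )

    def test_volume_gradient_consistency(self, ventricle_coarse):
        # dV/du from the triple-product formula vs finite differences
        m = ventricle_coarse
        surf = fem.PressureSurface(
            g.surface_corner_triangles(m, "endo"), m.cavity_point, m.nodes
        )
        rng = np.random.default_rng(0)
        x = m.nodes + 0.01 * rng.standard_normal(m.nodes.shape)
        grad = surf.grad(x, m.n_nodes)
        for nid in rng.choice(np.unique(surf.tris), 5, replace=False):
            for k in range(3):
                xp = x.copy()
                xp[nid, k] += 1e-6
                xm = x.copy()
                xm[nid, k] -= 1e-6
                fd = (surf.volume(xp) - surf.volume(xm)) / 2e-6
                assert fd == pytest.approx(grad[nid, k], rel=1e-6, abs=1e-12)


class TestEquilibrium:
    def test_zero_pressure_zero_displacement(self, ventricle_coarse):
        prob = fem.ventricle_problem(ventricle_coarse, NORMAL_FUNG)
        state = fem.solve_pressure_step(prob, 0.0, n_steps=1)
        assert np.abs(state.displacement).max() < 1e-10

    def test_thick_shell_linear_limit(self):
        """Small-pressure inflation vs the incompressible Lame solution.

        With equal Fung exponents b the small-strain response is isotropic
        with shear modulus mu = C*b; the thick-sphere solution gives
        u(a) = p a^3 b^3 / (4 mu (b^3 - a^3) a^2).
        """
        a, b_out = 1.0, 1.3
        m = g.ventricle_shell_mesh(
            semi_axes=(a, a, a),
            wall_thickness=b_out - a,
            base_crop_fraction=0.0,
            target_element_count=2500,
        )
        bexp = 20.0
        fung = FungParams(C=30.0, b_ff=bexp, b_xx=bexp, b_fx=bexp)
        mu = fung.C * bexp
        p = 0.01 * mu  # small strain
        fixed = np.zeros((m.n_nodes, 3), dtype=bool)
        # pin rigid modes only (closed shell)
        imin = int(np.argmin(m.nodes[:, 2]))
        imax = int(np.argmax(m.nodes[:, 2]))
        iy = int(np.argmax(m.nodes[:, 0]))
        fixed[imin] = True
        fixed[imax, 0] = True
        fixed[imax, 1] = True
        fixed[iy, 1] = True
        surf = fem.PressureSurface(
            g.surface_corner_triangles(m, "endo"), np.zeros(3), m.nodes
        )
        cfg = fem.SolverConfig(bulk_modulus=200 * mu)
        prob = fem.FEProblem(m, fung, None, cfg, fixed, surf)
        state = prob.solve(pressure=p, n_steps=2)
        endo = np.unique(m.surfaces["endo"])
        r = np.linalg.norm(m.nodes[endo], axis=1)
        ur = np.einsum(
            "ni,ni->n", state.displacement[endo], m.nodes[endo] / r[:, None]
        )
        u_lame = p * a * b_out**3 / (4 * mu * (b_out**3 - a**3))
        assert np.mean(ur) == pytest.approx(u_lame, rel=0.10)

    def test_stiffness_scaling(self, ventricle_coarse):
        # doubling C halves the small-strain compliance
        p_small = 2.0  # Pa, linear regime
        u_ref = None
        for scale in (1.0, 2.0):
            fung = FungParams(C=19.7 * scale)
            prob = fem.ventricle_problem(ventricle_coarse, fung)
            st = fem.solve_pressure_step(prob, p_small, n_steps=1)
            if u_ref is None:
                u_ref = np.abs(st.displacement).max()
            else:
                ratio = np.abs(st.displacement).max() / u_ref
                assert ratio == pytest.approx(0.5, abs=0.05)

    def test_volume_pressure_round_trip(self, inflated):
        prob, state = inflated
        st2 = fem.solve_volume_step(prob, state.volume, n_steps=2)
        assert st2.pressure == pytest.approx(state.pressure, rel=1e-3)

    def test_zero_pressure_volume_target(self, ventricle_coarse):
        prob = fem.ventricle_problem(ventricle_coarse, NORMAL_FUNG)
        v0 = fem.cavity_volume(ventricle_coarse)
        st = fem.solve_volume_step(prob, v0, n_steps=1)
        assert abs(st.pressure) < 0.5  # Pa

    def test_isovolumic_pressure_transient(self, inflated):
        # holding the volume while the activation rises and decays makes
        # the cavity pressure rise then fall back
        prob, state = inflated
        prob.active = ActiveParams(T_max=3000.0)
        p = []
        st = state
        for t in (60.0, 110.0, 1000.0):
            st = fem.solve_volume_step(
                prob, state.volume, t_active=t, act_scale=1.0, start=st, n_steps=2
            )
            p.append(st.pressure)
        assert p[1] > p[0] > state.pressure
        assert p[2] == pytest.approx(state.pressure, rel=0.05)

    def test_near_incompressibility(self, inflated):
        prob, state = inflated
        jmin, jmax = prob.jacobian_range(state.displacement)
        assert jmin > 0.98 and jmax < 1.02

    def test_energy_consistency(self, ventricle_coarse):
        # external pressure work equals stored energy for the conservative
        # enclosed-volume load (passive inflation)
        prob = fem.ventricle_problem(ventricle_coarse, NORMAL_FUNG)
        ps = np.linspace(0.0, 30.0, 7)
        states = [fem.solve_pressure_step(prob, 0.0, n_steps=1)]
        for p in ps[1:]:
            states.append(
                fem.solve_pressure_step(prob, float(p), start=states[-1], n_steps=1)
            )
        vols = np.array([s.volume for s in states])
        work = float(np.trapezoid(ps, vols))
        energy = prob.strain_energy_total(states[-1].displacement)
        assert work == pytest.approx(energy, rel=0.01)

    def test_node_reordering_invariance(self):
        m = g.cylinder_disc_mesh(radius=0.2, thickness=0.1, n_rad=2, n_theta=6,
                                 n_z=1, order=2)
        rng = np.random.default_rng(3)
        perm = rng.permutation(m.n_nodes)
        inv = np.argsort(perm)

        def solve(mesh):
            fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
            fixed[np.unique(mesh.surfaces["bottom"])] = True
            surf = fem.PressureSurface(
                g.surface_corner_triangles(mesh, "top"), np.zeros(3), mesh.nodes
            )
            prob = fem.FEProblem(mesh, NORMAL_FUNG, None, fem.SolverConfig(),
                                 fixed, surf)
            return prob.solve(pressure=5.0, n_steps=1).displacement

        u1 = solve(m)
        m2 = g.FEMesh(
            nodes=m.nodes[inv],
            elems=perm[m.elems],
            surfaces={k: perm[v] for k, v in m.surfaces.items()},
            fiber=m.fiber[inv],
        )
        u2 = solve(m2)
        assert np.allclose(u1, u2[perm], atol=1e-8)


class TestMPAForward:
    def test_zero_pressure_zero_length(self, small_slab_problem):
        L = fem.mpa_forward(
            NORMAL_FUNG, np.array([0.0]), problem=small_slab_problem
        )
        assert L[0] == 0.0

    def test_monotone_in_suction_and_stiffness(self, small_slab_problem):
        press = np.array([0.0, -15.0, -30.0, -45.0, -60.0])
        L1 = fem.mpa_forward(NORMAL_FUNG, press, problem=small_slab_problem)
        assert np.all(np.diff(L1) > 0)  # increasing with |pressure|
        L2 = fem.mpa_forward(
            FungParams(C=2 * 19.7), press, problem=small_slab_problem
        )
        assert np.all(L2[1:] < L1[1:])  # stiffer aspirates less

    def test_positive_pressure_rejected(self, small_slab_problem):
        with pytest.raises(ValueError):
            fem.mpa_forward(NORMAL_FUNG, np.array([5.0]), problem=small_slab_problem)
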