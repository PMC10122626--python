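"""Motion model, analysis layer, strain and wall thickness."""

import numpy as np
import pytest
import scipy.stats

from embryoheart import geometry as g, kinematics as kin, synthdata as sd

from conftest import fit_ground_truth_model


@pytest.fixture(scope="module")
def fitted_model(motion_mesh, wall_sample_points):
    mf = sd.make_motion_field(motion_mesh, sd.MotionSpec())
    return mf, fit_ground_truth_model(motion_mesh, wall_sample_points, mf)


class TestMotionModelFit:
    def test_zero_displacement(self, motion_mesh):
        pts = motion_mesh.nodes[::7]
        phases = np.linspace(0, 100.0, 8, endpoint=False)
        fields = [(t, pts, np.zeros_like(pts)) for t in phases]
        model = kin.fit_motion_model(fields, period=100.0, n_cells=3)
        assert np.allclose(model.coeffs, 0.0)
        assert model.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_round_trip_accuracy(self, motion_mesh, wall_sample_points, fitted_model):
        mf, model = fitted_model
        pts = motion_mesh.nodes[::5]
        t = mf.period / 2
        u_true = mf(pts, t)
        u_fit = model.displacement(pts, t)
        peak = np.abs(u_true).max()
        assert np.abs(u_fit - u_true).max() < 0.01 * peak * 10  # < 10% pointwise
        assert np.sqrt(np.mean((u_fit - u_true) ** 2)) < 0.01 * peak

    def test_periodicity_exact(self, fitted_model, motion_mesh):
        _, model = fitted_model
        pts = motion_mesh.nodes[::11]
        u0 = model.displacement(pts, 0.0)
        uT = model.displacement(pts, model.period)
        assert np.abs(u0 - uT).max() < 1e-12

    def test_noise_robustness(self, motion_mesh, wall_sample_points):
        mf = sd.make_motion_field(motion_mesh, sd.MotionSpec())
        pts = wall_sample_points
        phases = np.linspace(0, mf.period, 9, endpoint=False)
        rng = np.random.default_rng(0)
        sigma = 0.002  # mm, ~2% of peak displacement
        clean = mf.sample_fields(pts, phases)
        noisy = [(t, p, u + rng.normal(0, sigma, u.shape)) for t, p, u in clean]
        m_clean = kin.fit_motion_model(clean, mf.period, n_cells=5)
        m_noisy = kin.fit_motion_model(noisy, mf.period, n_cells=5)
        # compare in prediction space (boundary control points are only
        # weakly identifiable): the smoothing fit averages the noise down
        eval_pts = motion_mesh.nodes[::5]
        du = m_noisy.displacement(eval_pts, mf.period / 2) - m_clean.displacement(
            eval_pts, mf.period / 2
        )
        assert np.sqrt(np.mean(du**2)) < sigma
        assert np.abs(du).max() < 3 * sigma

    def test_insufficient_phases(self, motion_mesh):
        pts = motion_mesh.nodes[::7]
        fields = [(t, pts, np.zeros_like(pts)) for t in (0.0, 10.0, 20.0)]
        with pytest.raises(ValueError, match="phases"):
            kin.fit_motion_model(fields, period=100.0, n_harmonics=3)

    def test_sparse_coverage_error(self):
        pts = np.zeros((4, 3)) + [[0, 0, 0], [0.01, 0, 0], [0, 0.01, 0], [0, 0, 0.01]]
        fields = [(t, pts, np.zeros_like(pts)) for t in np.linspace(0, 90, 8)]
        with pytest.raises(ValueError, match="control points"):
            # huge lattice over a tiny data cloud leaves most of it dead
            kin.fit_motion_model(fields, period=100.0, n_cells=8, margin=50.0)


class TestAnalysisLayer:
    def test_sphere_layer_radius(self):
        m = g.ventricle_shell_mesh(
            semi_axes=(1.0, 1.0, 1.0),
            wall_thickness=0.2,
            base_crop_fraction=0.0,
            target_element_count=2000,
        )
        layer = kin.extract_analysis_layer(m, offset=0.035)
        r = np.linalg.norm(layer.points, axis=1)
        assert np.mean(r) == pytest.approx(1.2 - 0.035, abs=0.01)

    def test_zero_offset_is_epicardium(self, motion_mesh):
        layer = kin.extract_analysis_layer(motion_mesh, offset=0.0)
        ids = layer.vertex_ids
        assert np.allclose(layer.points, motion_mesh.nodes[ids])

    def test_frame_orthogonality(self, motion_layer):
        lay = motion_layer
        assert np.allclose(np.einsum("ni,ni->n", lay.circ, lay.long_), 0, atol=1e-10)
        assert np.allclose(np.einsum("ni,ni->n", lay.circ, lay.normal), 0, atol=1e-10)
        assert np.allclose(np.einsum("ni,ni->n", lay.long_, lay.normal), 0, atol=1e-10)
        for v in (lay.circ, lay.long_, lay.normal):
            assert np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-10)


class TestStrain:
    def _affine_model(self, layer, F_target, period=100.0):
        """Fit the motion model to an exact affine deformation."""
        pts = layer.points
        lo = pts.min(axis=0) - 0.3
        hi = pts.max(axis=0) + 0.3
        grid = np.stack(
            np.meshgrid(*[np.linspace(l, h, 8) for l, h in zip(lo, hi)],
                        indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        A = np.asarray(F_target) - np.eye(3)
        fields = []
        for t in np.linspace(0, period, 9, endpoint=False):
            s = 0.5 * (1 - np.cos(2 * np.pi * t / period))
            fields.append((t, grid, s * grid @ A.T))
        return kin.fit_motion_model(fields, period, n_cells=3)

    def test_uniaxial_stretch_closed_form(self, motion_layer):
        # stretch 1.1 along the circumferential direction of one point
        lay = motion_layer
        k = 7
        c = lay.circ[k]
        F = np.eye(3) + 0.1 * np.outer(c, c)
        model = self._affine_model(lay, F)
        sf = kin.compute_strain(model, lay, t=50.0)  # peak of the envelope
        E_cc = sf.E_surface[k, 0, 0]
        assert E_cc == pytest.approx((1.1**2 - 1) / 2, abs=2e-3)

    def test_rigid_rotation_objectivity(self, motion_layer):
        th = 0.3
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        model = self._affine_model(motion_layer, R)
        sf = kin.compute_strain(model, motion_layer, t=50.0)
        assert np.abs(sf.E_surface).max() < 5e-4  # fit tolerance, not physics

    def test_strain_zero_at_ed(self, fitted_model, motion_layer):
        _, model = fitted_model
        sf = kin.compute_strain(model, motion_layer, t=0.0)
        assert np.abs(sf.E_surface).max() < 1e-12

    def test_peak_strain_recovery(self, fitted_model, motion_layer):
        # phantom built with -0.139 peak strain on the analysis layer
        mf, model = fitted_model
        sf = kin.compute_strain(model, motion_layer, mf.period / 2)
        e_min, _, _ = kin.principal_directions(sf)
        assert e_min.mean() == pytest.approx(-0.139, abs=0.005)


class TestPrincipalDirections:
    def _field(self, layer, E2):
        n = len(layer.points)
        return kin.StrainField(
            layer=layer, E_surface=np.broadcast_to(E2, (n, 2, 2)).copy(), phase=0.0
        )

    def test_diagonal_case(self, motion_layer):
        sf = self._field(motion_layer, np.diag([-0.2, 0.1]))
        e_min, dir3, deg = kin.principal_directions(sf)
        assert np.allclose(e_min, -0.2)
        assert not deg.any()
        assert np.allclose(np.abs(np.einsum("ni,ni->n", dir3, motion_layer.circ)), 1.0)

    def test_isotropic_tie_flag(self, motion_layer):
        sf = self._field(motion_layer, -0.1 * np.eye(2))
        e_min, dir3, deg = kin.principal_directions(sf)
        assert deg.all()
        assert np.allclose(e_min, -0.1)

    def test_eigenvector_property(self, motion_layer):
        rng = np.random.default_rng(0)
        A = 0.1 * rng.standard_normal((len(motion_layer.points), 2, 2))
        E2 = 0.5 * (A + np.swapaxes(A, -1, -2))
        sf = kin.StrainField(layer=motion_layer, E_surface=E2, phase=0.0)
        e_min, dir3, deg = kin.principal_directions(sf)
        T = np.stack([motion_layer.circ, motion_layer.long_], axis=-1)
        v2 = np.einsum("nij,ni->nj", T, dir3)
        res = np.einsum("nij,nj->ni", E2, v2) - e_min[:, None] * v2
        assert np.abs(res).max() < 1e-8

    def test_random_direction_field_uniform_angles(
        self, motion_mesh, motion_layer, wall_sample_points
    ):
        # phantom with spatially varying contraction direction: recovered
        # minimum-principal angles should be close to uniform
        mf = sd.make_motion_field(
            motion_mesh, sd.MotionSpec(direction_mode="random-uniform", seed=3)
        )
        model = fit_ground_truth_model(motion_mesh, wall_sample_points, mf)
        sf = kin.compute_strain(model, motion_layer, mf.period / 2)
        _, dir3, deg = kin.principal_directions(sf)
        assert deg.mean() < 0.05
        ang = np.arctan2(
            np.einsum("ni,ni->n", dir3, motion_layer.long_),
            np.einsum("ni,ni->n", dir3, motion_layer.circ),
        ) % np.pi
        hist, _ = np.histogram(ang, bins=8, range=(0, np.pi))
        _, p = scipy.stats.chisquare(hist)
        assert p > 0.01


class TestWallThickness:
    @pytest.mark.parametrize("t_true", [0.18, 0.24])
    def test_uniform_shell(self, t_true):
        m = sd.make_ventricle_mesh(
            sd.VentricleSpec(wall_thickness=t_true, target_element_count=900)
        )
        rep = kin.measure_wall_thickness(m, n=30, seed=1)
        assert rep.mean == pytest.approx(t_true, abs=0.01)
        assert len(rep.samples) == 30
        assert np.all(rep.samples > 0)
        assert rep.samples.min() <= rep.mean <= rep.samples.max()

    def test_concentric_spheres_exact(self):
        m = g.ventricle_shell_mesh(
            semi_axes=(1.0, 1.0, 1.0),
            wall_thickness=0.15,
            base_crop_fraction=0.0,
            target_element_count=6000,
        )
        rep = kin.measure_wall_thickness(m, n=30, seed=0)
        # every normal ray crosses exactly the shell thickness
        assert rep.samples == pytest.approx(0.15, abs=2e-3)

    def test_seeded_reproducibility(self, motion_mesh):
        r1 = kin.measure_wall_thickness(motion_mesh, n=10, seed=42)
        r2 = kin.measure_wall_thickness(motion_mesh, n=10, seed=42)
        assert np.array_equal(r1.samples, r2.samples)


class TestSpatialAverage:
    def test_matches_pointwise_for_homogeneous_field(self, fitted_model, motion_layer):
        mf, model = fitted_model
        t = mf.period / 2
        avg = kin.spatial_average_strain(model, motion_layer, [0.0, t])
        e_min, _, _ = kin.principal_directions(
            kin.compute_strain(model, motion_layer, t)
        )
        assert avg[0] == pytest.approx(0.0, abs=1e-12)
        assert avg[1] == pytest.approx(e_min.mean(), rel=1e-12)

    def test_two_region_mean(self, motion_layer):
        n = len(motion_layer.points)
        E2 = np.zeros((n, 2, 2))
        E2[: n // 2] = np.diag([-0.1, 0.0])
        E2[n // 2 :] = np.diag([-0.3, 0.0])
        sf = kin.StrainField(layer=motion_layer, E_surface=E2, phase=0.0)
        e_min, _, _ = kin.principal_directions(sf)
        if n % 2 == 0:
            assert e_min.mean() == pytest.approx(-0.2)
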