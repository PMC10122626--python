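"""Synthetic-data generators: motion ground truth, cine phantom, waveforms."""

import numpy as np
import pytest

from embryoheart import cine, fem, synthdata as sd
from embryoheart.constitutive import CYCLE_PERIOD_MS


class TestSpecs:
    def test_invalid_ventricle_specs(self):
        with pytest.raises(ValueError):
            sd.VentricleSpec(wall_thickness=0.8)
        with pytest.raises(ValueError):
            sd.VentricleSpec(semi_axes=(0.0, 0.7, 1.0))
        with pytest.raises(ValueError):
            sd.VentricleSpec(base_crop_fraction=1.5)

    def test_invalid_motion_specs(self):
        with pytest.raises(ValueError):
            sd.MotionSpec(peak_surface_strain=-0.6)
        with pytest.raises(ValueError):
            sd.MotionSpec(period=-10.0)

    def test_invalid_mpa_specs(self):
        with pytest.raises(ValueError):
            sd.MPAGroundTruth(pressures_mmhg=(0.0, -10.0, -5.0))
        with pytest.raises(ValueError):
            sd.MPAGroundTruth(pressures_mmhg=(5.0,))

    def test_mesh_determinism(self):
        spec = sd.VentricleSpec(target_element_count=700)
        m1 = sd.make_ventricle_mesh(spec)
        m2 = sd.make_ventricle_mesh(spec)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.elems, m2.elems)


class TestMotionField:
    def test_zero_strain_is_identity(self, motion_mesh):
        mf = sd.make_motion_field(motion_mesh, sd.MotionSpec(peak_surface_strain=0.0))
        pts = motion_mesh.nodes[::9]
        for t in (0.0, 100.0, 250.0):
            assert np.allclose(mf(pts, t), 0.0)

    def test_zero_at_end_diastole(self, motion_mesh):
        mf = sd.make_motion_field(motion_mesh, sd.MotionSpec())
        assert np.abs(mf(motion_mesh.nodes[::9], 0.0)).max() == 0.0

    def test_periodicity(self, motion_mesh):
        mf = sd.make_motion_field(motion_mesh, sd.MotionSpec())
        pts = motion_mesh.nodes[::9]
        assert np.abs(mf(pts, 0.0) - mf(pts, mf.period)).max() < 1e-9

    @pytest.mark.parametrize("mode,seed", [("isotropic", 0), ("random-uniform", 3)])
    def test_volume_preservation(self, motion_mesh, mode, seed):
        spec = sd.MotionSpec(direction_mode=mode, seed=seed)
        mf = sd.make_motion_field(motion_mesh, spec)
        J = mf.jacobian(motion_mesh.nodes[::15], mf.period / 2)
        assert np.abs(J - 1).max() <= spec.volume_preserving_tol

    def test_calibrated_layer_strain(self, motion_mesh, motion_layer):
        for eps in (-0.139, -0.198):
            mf = sd.make_motion_field(
                motion_mesh, sd.MotionSpec(peak_surface_strain=eps)
            )
            assert mf._layer_emin_mean(motion_layer) == pytest.approx(eps, abs=1e-3)

    def test_determinism(self, motion_mesh):
        spec = sd.MotionSpec(direction_mode="random-uniform", seed=5)
        u1 = sd.make_motion_field(motion_mesh, spec)(motion_mesh.nodes[::9], 100.0)
        u2 = sd.make_motion_field(motion_mesh, spec)(motion_mesh.nodes[::9], 100.0)
        assert np.array_equal(u1, u2)


@pytest.fixture(scope="module")
def rendered(motion_mesh):
    mf = sd.make_motion_field(motion_mesh, sd.MotionSpec())
    cspec = sd.CineSpec(
        frames_per_cycle=12, n_cycles=8, n_planes=2,
        phase_offset_per_plane=40.0, seed=2,
    )
    return mf, sd.render_cine_stack(motion_mesh, mf, cspec)


class TestCineRendering:
    def test_static_noise_free_frames_identical(self, motion_mesh):
        mf = sd.make_motion_field(motion_mesh, sd.MotionSpec(peak_surface_strain=0.0))
        cspec = sd.CineSpec(
            frames_per_cycle=4, n_cycles=2, n_planes=1, blood_intensity=0.0,
            noise_sigma=0.0,
        )
        stack = sd.render_cine_stack(motion_mesh, mf, cspec)
        f = stack.planes[0]
        assert np.allclose(f, f[0])

    def test_period_round_trip(self, rendered):
        mf, stack = rendered
        per = cine.estimate_cardiac_period(stack.planes[0], stack.frame_interval)
        assert per == pytest.approx(mf.period, abs=stack.frame_interval)

    def test_phase_offset_round_trip(self, rendered):
        mf, stack = rendered
        st = cine.align_plane_phases(stack)
        dt = stack.frame_interval
        assert st.plane_phase[0] == 0.0
        assert st.plane_phase[1] == pytest.approx(40.0, abs=dt)

    def test_blood_pool_variance_contrast(self, rendered, motion_mesh):
        # decorrelated blood noise should out-vary the advected speckle
        mf, stack = rendered
        per = cine.estimate_cardiac_period(stack.planes[0], stack.frame_interval)
        ens = cine.ensemble_average(stack.planes[0], stack.frame_interval, per)
        q = ens.quadratic.mean(axis=0)
        # analytic masks on the reference geometry (plane 0)
        axes = motion_mesh.endo_axes
        outer = axes + motion_mesh.wall_thickness
        zp = stack.plane_z[0]
        px = stack.pixel_size / 1000.0
        H, W = q.shape
        xs = -outer[0] - 4 * px + (np.arange(W) + 0.5) * px
        ys = -outer[1] - 4 * px + (np.arange(H) + 0.5) * px
        PX, PY = np.meshgrid(xs, ys, indexing="xy")
        rho_in = np.sqrt((PX / axes[0]) ** 2 + (PY / axes[1]) ** 2 + (zp / axes[2]) ** 2)
        rho_out = np.sqrt(
            (PX / outer[0]) ** 2 + (PY / outer[1]) ** 2 + (zp / outer[2]) ** 2
        )
        blood_mask = rho_in < 0.75  # deep inside the cavity at all phases
        tissue_mask = (rho_in > 1.12) & (rho_out < 0.97)  # mid-wall at all phases
        assert blood_mask.sum() > 20 and tissue_mask.sum() > 20
        assert q[blood_mask].mean() > 3 * q[tissue_mask].mean()

    def test_out_of_volume_plane_warns(self, motion_mesh):
        mf = sd.make_motion_field(motion_mesh, sd.MotionSpec(peak_surface_strain=0.0))
        cspec = sd.CineSpec(
            frames_per_cycle=4, n_cycles=2, n_planes=60, plane_spacing=200.0,
        )
        with pytest.warns(UserWarning, match="outside"):
            sd.render_cine_stack(motion_mesh, mf, cspec)


class TestVolumeWaveform:
    def test_heart_rate_period(self):
        wf = sd.make_volume_waveform()
        assert wf.period == pytest.approx(60000.0 / 164.0)
        assert CYCLE_PERIOD_MS == pytest.approx(365.85, abs=0.01)

    def test_zero_stroke_constant(self):
        wf = sd.make_volume_waveform(edv=1.2, stroke_volume=0.0)
        assert np.allclose(wf.volumes, 1.2)

    def test_extrema(self):
        wf = sd.make_volume_waveform(edv=1.5, stroke_volume=0.5)
        assert wf.edv == pytest.approx(1.5)
        assert wf.esv == pytest.approx(1.0, abs=1e-4)
        assert wf.volume_at(0.0) == pytest.approx(1.5)

    def test_periodic_net_volume_change(self):
        wf = sd.make_volume_waveform()
        t = np.linspace(0, wf.period, 400)
        v = wf.volume_at(t)
        assert v[0] == pytest.approx(v[-1], rel=1e-9)  # integral of dV/dt = 0


class TestMPADataset:
    def test_zero_pressure_zero_length(self, small_slab_geom, small_slab_problem):
        gt = sd.MPAGroundTruth(pressures_mmhg=(0.0, -10.0))
        p, L = sd.make_mpa_dataset(gt, geom=small_slab_geom,
                                   problem=small_slab_problem)
        assert L[0] == 0.0
        assert L[1] > 0.0

    def test_noise_reproducible(self, small_slab_geom, small_slab_problem):
        gt = sd.MPAGroundTruth(pressures_mmhg=(0.0, -20.0, -40.0),
                               noise_sigma=1.0, seed=9)
        _, L1 = sd.make_mpa_dataset(gt, geom=small_slab_geom,
                                    problem=small_slab_problem)
        _, L2 = sd.make_mpa_dataset(gt, geom=small_slab_geom,
                                    problem=small_slab_problem)
        assert np.array_equal(L1, L2)
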