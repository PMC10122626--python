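import numpy as np
import pytest

from embryoheart import fem, geometry, kinematics, synthdata


@pytest.fixture(scope="session")
def ventricle_coarse():
    """Small quadratic ventricle mesh shared across FEM tests."""
    return synthdata.make_ventricle_mesh(
        synthdata.VentricleSpec(target_element_count=700)
    )


@pytest.fixture(scope="session")
def motion_mesh():
    """Mesh used by the motion/strain round-trip tests."""
    return synthdata.make_ventricle_mesh(
        synthdata.VentricleSpec(target_element_count=800)
    )


@pytest.fixture(scope="session")
def motion_layer(motion_mesh):
    return kinematics.extract_analysis_layer(motion_mesh)


@pytest.fixture(scope="session")
def wall_sample_points(motion_mesh):
    """Dense material sample points for motion-model fits."""
    rng = np.random.default_rng(11)
    dense = synthdata._sample_wall_points(motion_mesh, 12000, rng)
    return np.concatenate([motion_mesh.nodes, dense])


def fit_ground_truth_model(mesh, pts, mfield, n_phases=9, n_cells=6):
    phases = np.linspace(0, mfield.period, n_phases, endpoint=False)
    return kinematics.fit_motion_model(
        mfield.sample_fields(pts, phases), mfield.period, n_harmonics=3,
        n_cells=n_cells,
    )


@pytest.fixture(scope="session")
def small_slab_geom():
    """Coarse aspiration slab geometry for inverse-fit tests."""
    return fem.MPAGeometry(n_theta=6, n_z=2)


@pytest.fixture(scope="session")
def small_slab_problem(small_slab_geom):
    from embryoheart.constitutive import NORMAL_FUNG

    return fem.mpa_slab_problem(NORMAL_FUNG, small_slab_geom)
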