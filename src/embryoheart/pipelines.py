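"""End-to-end study pipelines on synthetic ventricles.

Each function runs one complete analysis the way the study would on real
data, with synthetic inputs generated in place of images or aspiration
records: stiffness recovery through the inverse aspiration fit, the
volume-constrained cardiac cycle with active-tension calibration, the
wall-thickness measurement study, and the mesh-refinement consistency
check.  They return plain dictionaries of the headline numbers.
"""

from __future__ import annotations

import numpy as np

from . import calibration as cal, fem, geometry, kinematics, synthdata as sd
from .constitutive import ActiveParams, FungParams, MMHG_TO_PA

__all__ = [
    "GROUPS",
    "recover_stiffness",
    "calibrated_cycle",
    "thickness_study",
    "refinement_check",
]

# group definitions: passive stiffness (Table values), LV wall thickness,
# and the peak-systolic / end-diastolic pressure targets (mmHg)
GROUPS = {
    "normal": dict(C=19.7, wall=0.18, p_max=3.1, p_ed=0.38),
    "lal": dict(C=27.6, wall=0.24, p_max=2.6, p_ed=0.28),
}


def recover_stiffness(
    c_true: float,
    geom: fem.MPAGeometry | None = None,
    c_init_factor: float = 2.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> dict:
    """Generate a synthetic aspiration record and invert it for C.

    The record is produced by the forward aspiration model at the true
    stiffness (0 to -60 mmHg, 60 um pipette); the inverse fit starts from
    ``c_init_factor`` times the truth.
    """
    geom = geom or fem.MPAGeometry()
    gt = sd.MPAGroundTruth(true_C=c_true, noise_sigma=noise_sigma, seed=seed)
    pressures, lengths = sd.make_mpa_dataset(gt, geom=geom)
    c_hat, diag = cal.fit_C_from_mpa(
        pressures, lengths, geom=geom, c_init=c_init_factor * c_true
    )
    n_elements = fem.mpa_slab_problem(FungParams(c_true), geom).mesh.n_elems
    return {
        "C_true": c_true,
        "C_recovered": c_hat,
        "n_elements": n_elements,
        "pressures_mmhg": pressures,
        "lengths_um": lengths,
        "diagnostics": diag,
    }


def _element_fibers(problem: fem.FEProblem) -> np.ndarray:
    f = problem.f0.mean(axis=1)
    return f / np.linalg.norm(f, axis=1, keepdims=True)


def calibrated_cycle(
    group: str = "normal",
    target_elements: int = 3000,
    n_steps: int = 20,
    sv_fraction: float = 0.3,
    seed: int = 0,
) -> dict:
    """Full cycle pipeline: mesh, unloading, waveform, T_max calibration.

    Builds the idealized ventricle for the group, back-computes the
    load-free geometry at the group's end-diastolic pressure, assembles
    the 164 bpm volume waveform with isovolumic insertion, and calibrates
    the peak active tension against the group's peak-pressure target.
    """
    g = GROUPS[group]
    fung = FungParams(C=g["C"])
    targets = cal.PressureTargets.from_mmhg(g["p_max"], g["p_ed"])
    mesh = sd.make_ventricle_mesh(
        sd.VentricleSpec(
            wall_thickness=g["wall"], target_element_count=target_elements,
            seed=seed,
        )
    )
    V_ed = fem.cavity_volume(mesh)
    unloaded, p_start = cal.compute_unloaded_geometry(mesh, fung, targets.p_ed)
    waveform = cal.insert_isovolumic_phases(
        sd.make_volume_waveform(edv=V_ed, stroke_volume=sv_fraction * V_ed)
    )
    tmax, result = cal.calibrate_tmax(
        unloaded, fung, ActiveParams(), waveform, targets, n_steps=n_steps
    )
    summary = cal.summarize_stress(result, _element_fibers(result.problem))
    return {
        "group": group,
        "edv_mm3": V_ed,
        "unloaded_volume_mm3": fem.cavity_volume(unloaded),
        "T_max_Pa": tmax,
        "peak_pressure_mmhg": result.peak_pressure / MMHG_TO_PA,
        "target_mmhg": g["p_max"],
        "result": result,
        "stress_summary": summary,
        "unloaded_mesh": unloaded,
        "ed_mesh": mesh,
        "waveform": waveform,
    }


def thickness_study(
    wall_thickness: float = 0.24,
    target_elements: int = 3000,
    n_locations: int = 30,
    seeds=range(10),
) -> dict:
    """Random-normal-ray thickness measurement on a uniform shell."""
    mesh = sd.make_ventricle_mesh(
        sd.VentricleSpec(
            wall_thickness=wall_thickness, target_element_count=target_elements
        )
    )
    reports = [
        kinematics.measure_wall_thickness(mesh, n=n_locations, seed=int(s))
        for s in seeds
    ]
    means = np.array([r.mean for r in reports])
    return {
        "true_thickness": wall_thickness,
        "mean_over_seeds": float(means.mean()),
        "per_seed_means": means,
        "reports": reports,
    }


def refinement_check(
    target_elements: int = 3000,
    t_max: float = 2000.0,
    inflate_factor: float = 1.15,
    group: str = "normal",
) -> dict:
    """Spatial-mean Cauchy stress change under uniform mesh refinement.

    Solves an end-diastolic inflation (volume-constrained) plus a peak
    isovolumic activation on the base mesh and on its uniformly refined
    (geometry-preserving) counterpart; the refined solve is warm-started
    from the prolongated coarse solution.  Returns the relative change of
    the volume-weighted mean Frobenius stress norm in percent.
    """
    g = GROUPS[group]
    fung = FungParams(C=g["C"])
    active = ActiveParams(T_max=t_max)
    mesh = sd.make_ventricle_mesh(
        sd.VentricleSpec(
            wall_thickness=g["wall"], target_element_count=target_elements
        )
    )
    t_peak = active.t0

    def solve_mean(m, warm=None):
        prob = fem.ventricle_problem(m, fung, active)
        V = fem.cavity_volume(m) * inflate_factor
        if warm is None:
            st = prob.solve(volume=V)
            st = prob.solve(start=st, volume=V, t_active=t_peak, act_scale=1.0,
                            n_steps=3)
        else:
            st = prob.solve(start=warm, volume=V, t_active=t_peak, act_scale=1.0,
                            n_steps=1)
        sig = prob.cauchy_stress(st.displacement, t_active=t_peak, act_scale=1.0)
        frob = np.linalg.norm(sig.reshape(len(sig), 9), axis=1)
        w = prob.wdetJ.sum(axis=1)
        return float((frob * w).sum() / w.sum()), st

    f_base, st_base = solve_mean(mesh)
    import gc

    gc.collect()
    refined = geometry.refine_uniform(mesh)
    u0 = refined.prolongation @ st_base.displacement
    warm = fem.CavityState(
        pressure=st_base.pressure,
        volume=fem.cavity_volume(refined, u0),
        displacement=u0,
        t_active=t_peak,
        activation=1.0,
    )
    f_ref, _ = solve_mean(refined, warm=warm)
    return {
        "mean_frobenius_base_Pa": f_base,
        "mean_frobenius_refined_Pa": f_ref,
        "relative_change_percent": 100.0 * abs(f_base - f_ref) / f_ref,
        "n_elements": (mesh.n_elems, refined.n_elems),
    }
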