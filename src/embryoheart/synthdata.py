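"""Synthetic inputs with known ground truth for the whole pipeline.

Generates everything the analysis consumes, in place of animal data:

* idealized ventricle meshes (thick-walled truncated ellipsoids sized to
  the HH25 chick ventricle: end-diastolic width ~1.4 mm, wall 0.18 /
  0.24 mm for the normal / ligated left ventricle);
* analytic cyclic contraction fields with prescribed peak surface strain
  and exact volume preservation (an incompressible shell contraction,
  optionally perturbed by a seeded divergence-free field so that the local
  direction of greatest contraction varies randomly over the wall);
* speckle-textured cine renderings of that motion over many cardiac
  cycles, with a decorrelated blood pool so the quadratic ensemble
  brightens blood while the arithmetic ensemble enhances tissue;
* smooth periodic volume-time waveforms;
* micropipette-aspiration pressure/length records produced by the forward
  aspiration model, with optional measurement noise.

The defaults encode the study conditions: 164 bpm heart rate, 50 um plane
spacing, >= 20 imaged cycles, a 60 um pipette aspirating from 0 to
-60 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fem, kinematics
from .constitutive import CYCLE_PERIOD_MS, FungParams
from .geometry import FEMesh, ventricle_shell_mesh

__all__ = [
    "VentricleSpec",
    "MotionSpec",
    "CineSpec",
    "MPAGroundTruth",
    "MotionField",
    "make_ventricle_mesh",
    "make_motion_field",
    "render_cine_stack",
    "make_volume_waveform",
    "make_mpa_dataset",
]


@dataclass(frozen=True)
class VentricleSpec:
    """Idealized ventricle geometry (lengths mm).

    Default semi-axes give an end-diastolic width (2a) of 1.44 mm with a
    plausible 1.4:1 long-to-short aspect ratio -- the width matches the
    imaged hearts, the aspect ratio is a modelling convention.
    """

    semi_axes: tuple = (0.72, 0.72, 1.0)
    wall_thickness: float = 0.18
    base_crop_fraction: float = 0.3
    target_element_count: int = 3000
    seed: int = 0

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi_axes must be positive")
        if not 0 < self.wall_thickness < min(self.semi_axes):
            raise ValueError("wall_thickness must be in (0, min(semi_axes))")
        if not 0 <= self.base_crop_fraction < 1:
            raise ValueError("base_crop_fraction must be in [0, 1)")


@dataclass(frozen=True)
class MotionSpec:
    """Ground-truth cyclic contraction.

    ``peak_surface_strain`` (negative = contraction) is the in-plane
    Green-Lagrange strain on the sub-epicardial analysis layer at peak
    contraction.  ``direction_mode`` is "isotropic" (equibiaxial in-plane
    contraction; the strain is met in every tangent direction) or
    "random-uniform" (a seeded divergence-free perturbation makes the
    principal contraction direction vary over the wall with a near-uniform
    angle distribution; the strain along it is met on spatial average).
    """

    period: float = CYCLE_PERIOD_MS
    peak_surface_strain: float = -0.139
    direction_mode: str = "isotropic"
    anisotropy: float = 0.05
    layer_offset: float = 0.035  # mm; calibration surface for the strain
    volume_preserving_tol: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")
        if abs(self.peak_surface_strain) >= 0.5:
            raise ValueError("|peak_surface_strain| must be below 0.5")
        if self.direction_mode not in ("isotropic", "random-uniform"):
            raise ValueError(f"unknown direction_mode {self.direction_mode!r}")


@dataclass(frozen=True)
class CineSpec:
    """Synthetic cine acquisition."""

    pixel_size: float = 20.0  # um
    plane_spacing: float = 50.0  # um
    frames_per_cycle: int = 15
    n_cycles: int = 20
    n_planes: int = 3
    speckle_density: float = 4000.0  # per mm^3 of wall
    speckle_sigma_px: float = 1.2
    slice_thickness: float = 30.0  # um
    blood_intensity: float = 1.0
    noise_sigma: float = 0.0
    phase_offset_per_plane: float = 0.0  # ms
    seed: int = 0

    def __post_init__(self):
        if self.plane_spacing <= 0:
            raise ValueError("plane_spacing must be positive")
        if self.n_cycles < 2:
            raise ValueError("need at least two imaged cycles")


@dataclass(frozen=True)
class MPAGroundTruth:
    """Ground truth for synthetic aspiration records.

    Vacuum pressures in mmHg (non-positive, non-increasing, down to
    -60 mmHg); ``noise_sigma`` in um of aspirated length.
    """

    true_C: float = 19.7  # Pa
    pipette_inner_radius: float = 60.0  # um
    pressures_mmhg: tuple = (0.0, -12.0, -24.0, -36.0, -48.0, -60.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.pressures_mmhg)
        if np.any(p > 0) or np.any(np.diff(p) > 0):
            raise ValueError("pressures must be non-positive and non-increasing")
        if self.pipette_inner_radius <= 0:
            raise ValueError("pipette radius must be positive")


def make_ventricle_mesh(spec: VentricleSpec = VentricleSpec(), order: int = 2,
                        fiber_mode: str = "circumferential") -> FEMesh:
    """Watertight labelled tet mesh of the idealized ventricle."""
    return ventricle_shell_mesh(
        semi_axes=spec.semi_axes,
        wall_thickness=spec.wall_thickness,
        base_crop_fraction=spec.base_crop_fraction,
        target_element_count=spec.target_element_count,
        order=order,
        fiber_mode=fiber_mode,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# analytic motion ground truth
# ---------------------------------------------------------------------------


class MotionField:
    """Analytic cyclic displacement ``u(X, t)`` with known peak strain.

    The base map scales every normalized-ellipsoidal shell by
    ``rho -> (rho^3 + k(t))^(1/3)`` (exactly volume preserving; in-plane
    strain is equibiaxial on each shell).  ``k`` is calibrated so the
    in-plane strain at the analysis-layer radius equals the prescribed
    peak at peak contraction.  In "random-uniform" mode a divergence-free
    Fourier-mode field is superposed to create spatially varying principal
    directions.
    """

    def __init__(self, mesh: FEMesh, spec: MotionSpec):
        if mesh.endo_axes is None:
            raise ValueError("mesh lacks ellipsoid metadata for analytic motion")
        self.axes = np.asarray(mesh.endo_axes, dtype=float)
        self.spec = spec
        self.period = spec.period
        eps = spec.peak_surface_strain
        # calibration surface: the sub-epicardial analysis layer
        layer = kinematics.extract_analysis_layer(mesh, offset=spec.layer_offset)
        rho_layer = float(np.mean(np.linalg.norm(layer.points / self.axes, axis=1)))
        self._modes = None
        if spec.direction_mode == "random-uniform":
            self._build_modes(mesh, layer)
        lam = np.sqrt(1.0 + 2.0 * eps)
        self.k_peak = rho_layer**3 * (lam**3 - 1.0)
        if eps != 0.0:
            self._calibrate_k(layer, eps)

    def _layer_emin_mean(self, layer, h: float = 1e-5) -> float:
        """Analytic layer-mean minimum-principal in-plane strain at peak."""
        t_peak = 0.5 * self.period
        X = layer.points
        F = np.empty((len(X), 3, 3))
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = h
            F[:, :, j] = (self(X + dx, t_peak) - self(X - dx, t_peak)) / (2 * h)
        F += np.eye(3)
        E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))
        T = np.stack([layer.circ, layer.long_], axis=-1)
        E2 = np.swapaxes(T, -1, -2) @ E @ T
        return float(np.linalg.eigvalsh(E2)[:, 0].mean())

    def _calibrate_k(self, layer, eps: float) -> None:
        """Secant on k so the layer-mean e_min equals the prescribed peak.

        On a spherical shell the closed-form k is already exact; on an
        ellipsoid the offset layer is not a constant-radius surface, so
        the residual spatial anisotropy shifts the mean slightly.
        """
        k0 = self.k_peak
        f0 = self._layer_emin_mean(layer) - eps
        k1 = k0 * 1.05
        for _ in range(6):
            self.k_peak = k1
            f1 = self._layer_emin_mean(layer) - eps
            if abs(f1) < 2e-4 or f1 == f0:
                break
            k0, k1 = k1, k1 - f1 * (k1 - k0) / (f1 - f0)
            f0 = f1
            self.k_peak = k1

    # -- temporal envelope: 0 at ED (t=0), 1 at peak contraction (T/2)
    def envelope(self, t):
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(t) / self.period))

    def _build_modes(self, mesh: FEMesh, layer) -> None:
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        K = 32
        wavelens = rng.uniform(0.9, 2.2, K)  # mm
        wdirs = rng.standard_normal((K, 3))
        wdirs /= np.linalg.norm(wdirs, axis=1, keepdims=True)
        w = wdirs * (2 * np.pi / wavelens)[:, None]
        p = rng.standard_normal((K, 3))
        p /= np.linalg.norm(p, axis=1, keepdims=True)
        phases = rng.uniform(0, 2 * np.pi, K)
        amps = rng.normal(0.0, 1.0, K)
        self._modes = (w, np.cross(w, p), phases, amps)
        # scale so the mean in-plane strain anisotropy at the layer matches
        self._mode_scale = 1.0
        G = self._perturb_grad(layer.points)
        S = 0.5 * (G + np.swapaxes(G, -1, -2))
        T = np.stack([layer.circ, layer.long_], axis=-1)
        S2 = np.swapaxes(T, -1, -2) @ S @ T
        wvals = np.linalg.eigvalsh(S2)
        aniso = float(np.mean(wvals[:, 1] - wvals[:, 0]))
        self._mode_scale = spec.anisotropy / max(aniso, 1e-12)

    def _perturb(self, X: np.ndarray) -> np.ndarray:
        w, wxp, phases, amps = self._modes
        ph = X @ w.T + phases  # (n, K)
        return -self._mode_scale * np.sin(ph) @ (amps[:, None] * wxp)

    def _perturb_grad(self, X: np.ndarray) -> np.ndarray:
        w, wxp, phases, amps = self._modes
        ph = X @ w.T + phases
        # du_i/dx_j = -scale * cos(ph_k) * w_kj * (a_k wxp_ki)
        return -self._mode_scale * np.einsum(
            "nk,ki,kj->nij", np.cos(ph), amps[:, None] * wxp, w
        )

    def __call__(self, X: np.ndarray, t) -> np.ndarray:
        """Displacement (mm) of material points X at cycle time t (ms)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        s = self.envelope(t)
        if self.k_peak == 0.0 and self._modes is None:
            return np.zeros_like(X)
        # compose the (divergence-free) perturbation with the shell map so
        # the volume error stays second order in the perturbation amplitude
        Xw = X if self._modes is None else X + s * self._perturb(X)
        y = Xw / self.axes
        rho = np.linalg.norm(y, axis=-1)
        k = self.k_peak * s
        rho3 = np.maximum(rho**3 + k, 1e-12)
        scale = np.where(
            rho > 1e-12, (rho3 ** (1.0 / 3.0)) / np.maximum(rho, 1e-12), 1.0
        )
        return Xw * scale[..., None] - X

    def sample_fields(self, points: np.ndarray, phases) -> list:
        """(t, points, u) tuples ready for the motion-model fit."""
        return [(float(t), points, self(points, t)) for t in np.asarray(phases)]

    def jacobian(self, X: np.ndarray, t, h: float = 1e-5) -> np.ndarray:
        """det F by central finite differences (volume-preservation check)."""
        X = np.atleast_2d(X)
        F = np.empty((len(X), 3, 3))
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = h
            F[:, :, j] = (self(X + dx, t) - self(X - dx, t)) / (2 * h)
        F += np.eye(3)
        return np.linalg.det(F)


def make_motion_field(mesh: FEMesh, mspec: MotionSpec = MotionSpec()) -> MotionField:
    """Analytic ground-truth motion; u(X, 0) = 0 at end-diastole."""
    return MotionField(mesh, mspec)


# ---------------------------------------------------------------------------
# cine rendering
# ---------------------------------------------------------------------------


def _sample_wall_points(mesh: FEMesh, density: float, rng) -> np.ndarray:
    axes = mesh.endo_axes
    t = mesh.wall_thickness
    outer = axes + t
    z_hi = mesh.base_z if mesh.base_z is not None else outer[2]
    lo = np.array([-outer[0], -outer[1], -outer[2]])
    hi = np.array([outer[0], outer[1], z_hi])
    box_vol = np.prod(hi - lo)
    # wall volume estimate for the expected point count
    target = max(int(density * mesh.volume()), 10)
    pts = []
    while sum(len(p) for p in pts) < target:
        cand = rng.uniform(lo, hi, (4 * target, 3))
        rho_in = np.linalg.norm(cand / axes, axis=1)
        rho_out = np.linalg.norm(cand / outer, axis=1)
        keep = (rho_in >= 1.0) & (rho_out <= 1.0)
        pts.append(cand[keep])
    return np.concatenate(pts)[:target]


def render_cine_stack(mesh: FEMesh, u: MotionField, cspec: CineSpec = CineSpec()):
    """Speckle-phantom cine stacks of the moving ventricle.

    Tissue is rendered as Gaussian speckles advected by ``u``; the blood
    pool as temporally decorrelated noise inside the (deformed) cavity, so
    the quadratic ensemble brightens blood as in vivo.  Plane ``k`` starts
    acquisition ``k * phase_offset_per_plane`` later.  Planes outside the
    mesh bounding box yield empty images with a warning.
    """
    import warnings

    from .cine import CineStack

    rng = np.random.default_rng(cspec.seed)
    axes = mesh.endo_axes
    outer = axes + mesh.wall_thickness
    period = u.period
    frame_interval = period / cspec.frames_per_cycle
    n_frames = cspec.frames_per_cycle * cspec.n_cycles

    px = cspec.pixel_size / 1000.0  # mm
    margin = 4 * px
    x0, x1 = -outer[0] - margin, outer[0] + margin
    y0, y1 = -outer[1] - margin, outer[1] + margin
    W = int(np.ceil((x1 - x0) / px))
    H = int(np.ceil((y1 - y0) / px))
    xs = x0 + (np.arange(W) + 0.5) * px
    ys = y0 + (np.arange(H) + 0.5) * px

    z_mid = 0.5 * ((mesh.base_z if mesh.base_z is not None else outer[2]) - outer[2])
    dz = cspec.plane_spacing / 1000.0
    plane_z = z_mid + dz * (np.arange(cspec.n_planes) - (cspec.n_planes - 1) / 2)

    speckles = _sample_wall_points(mesh, cspec.speckle_density, rng)
    amp = rng.uniform(0.5, 1.0, len(speckles))
    sig_px = cspec.speckle_sigma_px
    sig_z = cspec.slice_thickness / 1000.0
    win = int(np.ceil(3 * sig_px))
    off = np.arange(-win, win + 1)
    OX, OY = np.meshgrid(off, off, indexing="xy")

    base_z = mesh.base_z if mesh.base_z is not None else np.inf
    zlo = mesh.nodes[:, 2].min()
    planes = []
    for kp, zp in enumerate(plane_z):
        if zp < zlo - 0.05 or zp > base_z + 0.05:
            warnings.warn(f"plane {kp} at z={zp:.3f} mm lies outside the mesh")
        frames = np.zeros((n_frames, H, W), dtype=np.float32)
        t_start = kp * cspec.phase_offset_per_plane
        # blood mask geometry per frame computed on the pixel grid
        PX, PY = np.meshgrid(xs, ys, indexing="xy")
        for j in range(n_frames):
            t = (t_start + j * frame_interval) % period
            img = np.zeros((H, W))
            pos = speckles + u(speckles, t)
            wz = np.exp(-((pos[:, 2] - zp) ** 2) / (2 * sig_z**2))
            vis = wz > 0.05
            if np.any(vis):
                cx = (pos[vis, 0] - x0) / px - 0.5
                cy = (pos[vis, 1] - y0) / px - 0.5
                ix = np.rint(cx).astype(int)
                iy = np.rint(cy).astype(int)
                fx = cx - ix
                fy = cy - iy
                g = (
                    amp[vis][:, None, None]
                    * wz[vis][:, None, None]
                    * np.exp(
                        -((OX[None] - fx[:, None, None]) ** 2 +
                          (OY[None] - fy[:, None, None]) ** 2)
                        / (2 * sig_px**2)
                    )
                )
                gx = (ix[:, None, None] + OX[None]).ravel()
                gy = (iy[:, None, None] + OY[None]).ravel()
                ok = (gx >= 0) & (gx < W) & (gy >= 0) & (gy < H)
                np.add.at(img, (gy[ok], gx[ok]), g.ravel()[ok])
            # blood pool: decorrelated noise inside the deformed cavity
            if cspec.blood_intensity > 0:
                s = u.envelope(t)
                rho_cur3 = (PX / axes[0]) ** 2 + (PY / axes[1]) ** 2 + (zp / axes[2]) ** 2
                rho_ref3 = np.maximum(rho_cur3, 0.0) ** 1.5 - u.k_peak * s
                blood = (rho_ref3 < 1.0) & (zp <= base_z)
                img[blood] += cspec.blood_intensity * rng.random(int(blood.sum()))
            if cspec.noise_sigma > 0:
                img += rng.normal(0.0, cspec.noise_sigma, img.shape)
            frames[j] = img
        planes.append(frames)
    return CineStack(
        planes=planes,
        frame_interval=frame_interval,
        plane_spacing=cspec.plane_spacing,
        pixel_size=cspec.pixel_size,
        plane_z=plane_z,
    )


# ---------------------------------------------------------------------------
# waveforms and aspiration records
# ---------------------------------------------------------------------------


def make_volume_waveform(
    period: float = CYCLE_PERIOD_MS,
    edv: float = 1.5,
    stroke_volume: float = 0.45,
    n_samples: int = 200,
):
    """Smooth periodic cavity-volume waveform; max = EDV at t = 0.

    The default stroke volume (30% of the default EDV) keeps end-systole
    near the load-free cavity volume of the soft HH25 wall, within the
    modest ejection fractions of the early embryonic ventricle.
    """
    from .calibration import VolumeWaveform

    t = np.linspace(0.0, period, n_samples, endpoint=False)
    v = edv - stroke_volume * 0.5 * (1.0 - np.cos(2 * np.pi * t / period))
    return VolumeWaveform(times=t, volumes=v, period=period)


def make_mpa_dataset(
    gt: MPAGroundTruth = MPAGroundTruth(),
    exponents: tuple = (29.9, 13.3, 26.6),
    geom=None,
    problem=None,
):
    """(pressures mmHg, aspirated lengths um) from the forward model.

    Lengths are produced by :func:`embryoheart.fem.mpa_forward` with the
    ground-truth stiffness, plus optional Gaussian noise.
    """
    if geom is None:
        geom = fem.MPAGeometry(pipette_radius=gt.pipette_inner_radius / 1000.0)
    fung = FungParams(gt.true_C, *exponents)
    lengths = fem.mpa_forward(
        fung, np.asarray(gt.pressures_mmhg), geom=geom, problem=problem
    )
    if gt.noise_sigma > 0:
        rng = np.random.default_rng(gt.seed)
        lengths = lengths + rng.normal(0.0, gt.noise_sigma, len(lengths))
    return np.asarray(gt.pressures_mmhg, dtype=float), lengths
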