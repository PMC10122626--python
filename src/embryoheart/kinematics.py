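"""Myocardial strain kinematics from cyclic displacement fields.

Displacement fields sampled over the cardiac cycle are regularized by a
global motion model: a truncated Fourier series in time (periodic by
construction) times a tensor-product cubic B-spline field in space.  From
the fitted model, Green-Lagrange strain is evaluated on an analysis layer
offset 35 um inward from the epicardial surface, relative to the
end-diastolic configuration; the strain tensor is projected onto the local
circumferential-longitudinal tangent plane before eigen-decomposition, so
the minimum-principal eigenvector is the in-plane direction of greatest
contraction.  Wall thickness is measured by casting inward normal rays
from random area-uniform epicardial points to the endocardial surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import (
    FEMesh,
    surface_corner_triangles,
    surface_vertex_normals,
)

__all__ = [
    "MotionModel",
    "AnalysisLayer",
    "StrainField",
    "WallThicknessReport",
    "fit_motion_model",
    "extract_analysis_layer",
    "compute_strain",
    "principal_directions",
    "measure_wall_thickness",
    "spatial_average_strain",
]


# ---------------------------------------------------------------------------
# cubic B-spline lattice
# ---------------------------------------------------------------------------


def _bspline_weights(u: np.ndarray):
    """Cubic B-spline basis (4 weights) and derivatives at fraction u."""
    u = np.asarray(u)
    u2, u3 = u * u, u * u * u
    B = np.stack(
        [
            (1 - u) ** 3 / 6,
            (3 * u3 - 6 * u2 + 4) / 6,
            (-3 * u3 + 3 * u2 + 3 * u + 1) / 6,
            u3 / 6,
        ],
        axis=-1,
    )
    dB = np.stack(
        [
            -((1 - u) ** 2) / 2,
            (3 * u2 - 4 * u) / 2 * 1.0 + 0 * u,
            (-3 * u2 + 2 * u + 1) / 2,
            u2 / 2,
        ],
        axis=-1,
    )
    return B, dB


@dataclass
class _Lattice:
    origin: np.ndarray  # (3,)
    spacing: np.ndarray  # (3,)
    n_cells: np.ndarray  # (3,) cells per axis; n_ctrl = n_cells + 3

    @property
    def n_ctrl(self) -> np.ndarray:
        return self.n_cells + 3

    @property
    def size(self) -> int:
        return int(np.prod(self.n_ctrl))

    def support(self, X: np.ndarray, deriv: bool = False):
        """Sparse support of points: (indices (n,64), weights, [dweights])."""
        X = np.atleast_2d(X)
        t = (X - self.origin) / self.spacing
        if np.any(t < -1e-9) or np.any(t > self.n_cells + 1e-9):
            raise ValueError("point outside motion-model lattice support")
        t = np.clip(t, 0.0, self.n_cells - 1e-12)
        i = np.floor(t).astype(int)
        i = np.minimum(i, self.n_cells - 1)
        u = t - i
        Bs, dBs = zip(*(_bspline_weights(u[:, ax]) for ax in range(3)))
        # tensor products over (4,4,4)
        W = np.einsum("na,nb,nc->nabc", Bs[0], Bs[1], Bs[2]).reshape(-1, 64)
        nx, ny, nz = self.n_ctrl
        offs = np.arange(4)
        ia = (i[:, 0, None] + offs)[:, :, None, None]
        ib = (i[:, 1, None] + offs)[:, None, :, None]
        ic = (i[:, 2, None] + offs)[:, None, None, :]
        idx = ((ia * ny + ib) * nz + ic).reshape(-1, 64)
        if not deriv:
            return idx, W
        dW = []
        for ax in range(3):
            parts = [Bs[0], Bs[1], Bs[2]]
            parts[ax] = dBs[ax] / self.spacing[ax]
            dW.append(
                np.einsum("na,nb,nc->nabc", *parts).reshape(-1, 64)
            )
        return idx, W, np.stack(dW, axis=-1)  # (n, 64, 3)


def _temporal_basis(t, period: float, n_harmonics: int, deriv: bool = False):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    w = 2 * np.pi / period
    cols = [np.ones_like(t)]
    for h in range(1, n_harmonics + 1):
        cols += [np.cos(h * w * t), np.sin(h * w * t)]
    return np.stack(cols, axis=-1)  # (nt, 2H+1)


@dataclass
class MotionModel:
    """Cyclic displacement field: Fourier (time) x cubic B-splines (space).

    ``coeffs`` has shape (3, n_ctrl_total, 2*n_harmonics+1); evaluation at
    ``t`` and ``t + period`` is identical by construction.
    """

    lattice: _Lattice
    period: float
    n_harmonics: int
    coeffs: np.ndarray
    residual_rms: float = 0.0
    undetermined: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def _check_support(self, idx: np.ndarray, W: np.ndarray) -> None:
        if len(self.undetermined) == 0:
            return
        bad = np.isin(idx, self.undetermined)
        if np.any(np.abs(W)[bad] > 1e-3):
            raise ValueError(
                "evaluation point relies on undetermined control points "
                "(displacement fields did not cover this region)"
            )

    def displacement(self, X: np.ndarray, t: float) -> np.ndarray:
        idx, W = self.lattice.support(X)
        self._check_support(idx, W)
        Tb = _temporal_basis(t, self.period, self.n_harmonics)[0]
        c = np.einsum("cmh,h->cm", self.coeffs, Tb)  # (3, M)
        return np.einsum("nk,cnk->nc", W, c[:, idx])

    def grad(self, X: np.ndarray, t: float) -> np.ndarray:
        """Displacement gradient du_i/dX_j, shape (n, 3, 3)."""
        idx, W, dW = self.lattice.support(X, deriv=True)
        self._check_support(idx, W)
        Tb = _temporal_basis(t, self.period, self.n_harmonics)[0]
        c = np.einsum("cmh,h->cm", self.coeffs, Tb)
        return np.einsum("nkj,cnk->ncj", dW, c[:, idx])


def fit_motion_model(
    fields,
    period: float,
    n_harmonics: int = 3,
    n_cells: int = 5,
    margin: float = 0.05,
    ridge: float = 1e-8,
) -> MotionModel:
    """Least-squares fit of the cyclic motion model to displacement fields.

    ``fields`` is a sequence of ``(t_ms, points (n,3), displacements
    (n,3))`` covering at least ``2*n_harmonics + 1`` distinct phases.
    Control points with no data support raise an error naming them; a tiny
    relative ridge stabilizes the remaining weakly-determined boundary
    control points.
    """
    fields = list(fields)
    phases = {round(float(f[0]), 9) for f in fields}
    if len(phases) < 2 * n_harmonics + 1:
        raise ValueError(
            f"need >= {2 * n_harmonics + 1} distinct phases for "
            f"{n_harmonics} harmonics, got {len(phases)}"
        )
    allpts = np.concatenate([np.atleast_2d(f[1]) for f in fields], axis=0)
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    lo -= margin * span
    hi += margin * span
    ncell = np.full(3, int(n_cells))
    lattice = _Lattice(origin=lo, spacing=(hi - lo) / ncell, n_cells=ncell)

    M = lattice.size
    nt = 2 * n_harmonics + 1

    def spatial_matrix(pts):
        idx, W = lattice.support(pts)
        n = len(pts)
        return sp.csr_matrix(
            (W.ravel(), (np.repeat(np.arange(n), 64), idx.ravel())),
            shape=(n, M),
        )

    shared = all(
        np.shape(f[1]) == np.shape(fields[0][1])
        and np.array_equal(np.atleast_2d(f[1]), np.atleast_2d(fields[0][1]))
        for f in fields[1:]
    )
    n_obs = sum(len(np.atleast_2d(f[1])) for f in fields)
    if shared:
        # separable least squares: the design is the Kronecker product of
        # one spatial matrix S with the temporal basis T, so the normal
        # equations reduce to (S'S) C (T'T) = S' U T per component
        pts0 = np.atleast_2d(fields[0][1])
        S = spatial_matrix(pts0)
        StS = (S.T @ S).tocsr()
        Tmat = np.stack(
            [_temporal_basis(f[0], period, n_harmonics)[0] for f in fields]
        )  # (F, nt)
        TtT = Tmat.T @ Tmat
        diag = StS.diagonal()
        support = diag
        dead = np.where(support <= 0)[0]
        if len(dead) > 0.25 * M:
            raise ValueError(
                "rank-deficient fit: control points without data support: "
                f"{dead[:20].tolist()}{'...' if len(dead) > 20 else ''}"
            )
        lam = ridge * (diag.max() if diag.max() > 0 else 1.0)
        solve_s = sp.linalg.factorized((StS + lam * sp.eye(M)).tocsc())
        coeffs = np.empty((3, M, nt))
        TtT_inv = np.linalg.inv(TtT + ridge * np.trace(TtT) / nt * np.eye(nt))
        for c in range(3):
            U = np.stack([np.atleast_2d(f[2])[:, c] for f in fields], axis=1)
            rhs = (S.T @ U) @ Tmat  # (M, nt)
            Y = np.column_stack([solve_s(rhs[:, k]) for k in range(nt)])
            coeffs[c] = Y @ TtT_inv
    else:
        AtA = sp.csr_matrix((M * nt, M * nt))
        Atb = np.zeros((M * nt, 3))
        for t_ms, pts, disp in fields:
            pts = np.atleast_2d(pts)
            idx, W = lattice.support(pts)
            Tb = _temporal_basis(t_ms, period, n_harmonics)[0]
            n = len(pts)
            r = np.repeat(np.arange(n), 64 * nt)
            c = (idx[:, :, None] * nt + np.arange(nt)).reshape(n, -1)
            v = (W[:, :, None] * Tb).reshape(n, -1)
            Ap = sp.csr_matrix((v.ravel(), (r, c.ravel())), shape=(n, M * nt))
            AtA = AtA + (Ap.T @ Ap)
            Atb += Ap.T @ np.atleast_2d(disp)
        AtA = AtA.tocsr()
        diag = AtA.diagonal()
        support = diag.reshape(M, nt).sum(axis=1)
        dead = np.where(support <= 0)[0]
        if len(dead) > 0.25 * M:
            raise ValueError(
                "rank-deficient fit: control points without data support: "
                f"{dead[:20].tolist()}{'...' if len(dead) > 20 else ''}"
            )
        lam = ridge * (diag.max() if diag.max() > 0 else 1.0)
        solve = sp.linalg.factorized((AtA + lam * sp.eye(M * nt)).tocsc())
        coef = np.stack([solve(Atb[:, c]) for c in range(3)], axis=0)
        coeffs = coef.reshape(3, M, nt)
    coeffs[:, dead, :] = 0.0
    model = MotionModel(
        lattice=lattice,
        period=period,
        n_harmonics=n_harmonics,
        coeffs=coeffs,
        residual_rms=0.0,
        undetermined=dead,
    )
    ss = 0.0
    for t_ms, pts, disp in fields:
        ss += float(((model.displacement(pts, t_ms) - disp) ** 2).sum())
    model.residual_rms = float(np.sqrt(ss / (3 * n_obs)))
    return model


# ---------------------------------------------------------------------------
# analysis layer / frames
# ---------------------------------------------------------------------------


@dataclass
class AnalysisLayer:
    """Sub-epicardial sample points with local surface frames.

    ``circ`` and ``long_`` are orthonormal tangent vectors (circumferential
    / longitudinal, both orthogonal to the outward normal).
    """

    points: np.ndarray
    normal: np.ndarray
    circ: np.ndarray
    long_: np.ndarray
    vertex_ids: np.ndarray
    offset: float


def _ray_triangle_distances(origins, directions, tri_pts):
    """Smallest positive hit distance per ray against a triangle soup.

    Moller-Trumbore, vectorized over rays x triangles; NaN where a ray
    misses every triangle.
    """
    v0 = tri_pts[:, 0]
    e1 = tri_pts[:, 1] - v0
    e2 = tri_pts[:, 2] - v0
    out = np.full(len(origins), np.nan)
    for i, (o, d) in enumerate(zip(origins, directions)):
        p = np.cross(d, e2)
        det = np.einsum("tj,tj->t", e1, p)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - v0
        uu = np.einsum("tj,tj->t", s, p) * inv
        q = np.cross(s, e1)
        vv = np.einsum("j,tj->t", d, q) * inv
        tt = np.einsum("tj,tj->t", e2, q) * inv
        hit = ok & (uu >= -1e-9) & (vv >= -1e-9) & (uu + vv <= 1 + 1e-9) & (tt > 1e-9)
        if np.any(hit):
            out[i] = tt[hit].min()
    return out


def _long_axis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    return axis if axis[2] >= 0 else -axis


def extract_analysis_layer(
    mesh: FEMesh, offset: float = 0.035, axis: np.ndarray | None = None
) -> AnalysisLayer:
    """Layer points offset inward from the epicardial surface (mm).

    Each point carries circumferential/longitudinal tangent unit vectors
    derived from the chamber long axis (principal axis of the epicardial
    point cloud unless given).  Points whose local wall is thinner than the
    offset are dropped with a warning.
    """
    ids, normals = surface_vertex_normals(mesh, "epi")
    pts = mesh.nodes[ids]
    if axis is None:
        axis = _long_axis(pts)
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    endo_tris = mesh.nodes[surface_corner_triangles(mesh, "endo")]
    if offset > 0:
        depth = _ray_triangle_distances(pts, -normals, endo_tris)
        keep = ~(np.isnan(depth)) & (depth > offset)
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(
                f"{dropped} layer points dropped (offset exceeds local wall depth)"
            )
    else:
        keep = np.ones(len(pts), dtype=bool)
    pts = pts[keep]
    normals = normals[keep]
    ids = ids[keep]
    layer_pts = pts - offset * normals
    circ = np.cross(np.broadcast_to(axis, normals.shape), normals)
    cn = np.linalg.norm(circ, axis=1)
    good = cn > 1e-8  # drop apex pole points (circumferential undefined)
    circ = circ[good] / cn[good, None]
    normals = normals[good]
    layer_pts = layer_pts[good]
    ids = ids[good]
    lon = np.cross(normals, circ)
    lon /= np.linalg.norm(lon, axis=1, keepdims=True)
    return AnalysisLayer(
        points=layer_pts,
        normal=normals,
        circ=circ,
        long_=lon,
        vertex_ids=ids,
        offset=offset,
    )


# ---------------------------------------------------------------------------
# strain
# ---------------------------------------------------------------------------


@dataclass
class StrainField:
    """In-plane Green-Lagrange strain samples on the analysis layer."""

    layer: AnalysisLayer
    E_surface: np.ndarray  # (n, 2, 2), basis (circ, long)
    phase: float  # ms

    def __len__(self):
        return len(self.E_surface)


def compute_strain(
    model: MotionModel, layer: AnalysisLayer, t: float, t_ed: float = 0.0
) -> StrainField:
    """In-plane Green-Lagrange strain at phase ``t`` relative to end-diastole.

    F(t) = I + grad u(t); the relative deformation F(t) F(t_ed)^-1 defines
    E = (F^T F - I)/2, which is projected onto each point's tangent plane:
    E(t_ed) vanishes identically.
    """
    G = model.grad(layer.points, t)
    G0 = model.grad(layer.points, t_ed)
    F = G + np.eye(3)
    F0 = G0 + np.eye(3)
    Frel = F @ np.linalg.inv(F0)
    E = 0.5 * (np.swapaxes(Frel, -1, -2) @ Frel - np.eye(3))
    T = np.stack([layer.circ, layer.long_], axis=-1)  # (n, 3, 2)
    E2 = np.swapaxes(T, -1, -2) @ E @ T
    E2 = 0.5 * (E2 + np.swapaxes(E2, -1, -2))
    return StrainField(layer=layer, E_surface=E2, phase=t)


def principal_directions(strain: StrainField, tol: float = 1e-8):
    """Minimum-principal in-plane strain and its 3D direction per point.

    Returns ``(e_min, dir_min, degenerate)``.  ``dir_min`` is the
    eigenvector of the 2x2 in-plane tensor mapped back to 3D, its sign
    fixed to a non-negative circumferential component.  Isotropic in-plane
    strain (eigenvalue tie within ``tol``) sets the degenerate flag and
    reports the circumferential direction.
    """
    E2 = strain.E_surface
    w, v = np.linalg.eigh(E2)
    e_min = w[..., 0]
    vec2 = v[..., :, 0]  # (n, 2) in (circ, long) basis
    degenerate = (w[..., 1] - w[..., 0]) < tol * np.maximum(
        1.0, np.abs(w).max(axis=-1)
    )
    vec2 = np.where(degenerate[:, None], np.array([1.0, 0.0]), vec2)
    flip = vec2[:, 0] < 0
    vec2[flip] *= -1
    layer = strain.layer
    dir3 = vec2[:, :1] * layer.circ + vec2[:, 1:2] * layer.long_
    dir3 /= np.linalg.norm(dir3, axis=1, keepdims=True)
    return e_min, dir3, degenerate


def spatial_average_strain(
    model: MotionModel,
    layer: AnalysisLayer,
    phases: np.ndarray,
    t_ed: float = 0.0,
):
    """Unweighted spatial mean of the minimum-principal strain per phase."""
    means = []
    for t in np.asarray(phases, dtype=float):
        e_min, _, _ = principal_directions(compute_strain(model, layer, t, t_ed))
        means.append(float(e_min.mean()))
    return np.asarray(means)


# ---------------------------------------------------------------------------
# wall thickness
# ---------------------------------------------------------------------------


@dataclass
class WallThicknessReport:
    chamber: str
    samples: np.ndarray  # mm
    seed: int

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def sd(self) -> float:
        return float(self.samples.std(ddof=1))


def measure_wall_thickness(
    mesh: FEMesh,
    n: int = 30,
    seed: int = 0,
    chamber: str = "LV",
    max_resample: int = 200,
) -> WallThicknessReport:
    """Wall thickness at ``n`` random area-uniform epicardial locations.

    At each sampled point the thickness is the distance along the inward
    surface normal to the endocardial surface; rays that miss the
    endocardium are resampled (and counted in a warning).
    """
    rng = np.random.default_rng(seed)
    epi_tris = surface_corner_triangles(mesh, "epi")
    tri_pts = mesh.nodes[epi_tris]
    cross = np.cross(
        tri_pts[:, 1] - tri_pts[:, 0], tri_pts[:, 2] - tri_pts[:, 0]
    )
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    p_area = areas / areas.sum()
    # smooth (area-weighted vertex) normals, barycentric-interpolated at the
    # sample point: per-facet normals wobble on the skinny apex triangles
    vids, vnormals = surface_vertex_normals(mesh, "epi")
    vmap = np.zeros(mesh.n_nodes, dtype=np.int64)
    vmap[vids] = np.arange(len(vids))
    endo_tris_pts = mesh.nodes[surface_corner_triangles(mesh, "endo")]
    samples = []
    misses = 0
    attempts = 0
    while len(samples) < n:
        if attempts > n + max_resample:
            raise RuntimeError("too many rays missed the endocardial surface")
        attempts += 1
        f = rng.choice(len(areas), p=p_area)
        r1, r2 = rng.random(2)
        s1 = np.sqrt(r1)
        w = np.array([1 - s1, s1 * (1 - r2), s1 * r2])
        a, b, c = tri_pts[f]
        pt = w[0] * a + w[1] * b + w[2] * c
        nrm = (w[:, None] * vnormals[vmap[epi_tris[f]]]).sum(axis=0)
        nrm /= np.linalg.norm(nrm)
        d = _ray_triangle_distances(pt[None], -nrm[None], endo_tris_pts)[0]
        if np.isnan(d):
            misses += 1
            continue
        samples.append(d)
    if misses:
        warnings.warn(f"{misses} thickness rays missed the endocardium; resampled")
    return WallThicknessReport(
        chamber=chamber, samples=np.asarray(samples), seed=seed
    )
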