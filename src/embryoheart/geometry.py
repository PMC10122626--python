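"""Tetrahedral meshes of idealized embryonic ventricles and test specimens.

The ventricle is modelled as a thick-walled truncated ellipsoid: the
endocardial surface is an ellipsoid with semi-axes ``(a, b, c)`` (long axis
along +z, apex at ``z = -c``), the epicardial surface is the parallel
surface offset outward by a uniform wall thickness, and the base is cropped
flat at a plane ``z = z_base``.  Meshes are built from a structured
(meridional x circumferential x transmural) grid of hexahedra (wedges at the
apex pole) which are split into tetrahedra through cell centres with a
face-diagonal rule that keeps the mesh conforming.  Linear (4-node) and
quadratic (10-node, VTK ordering) tetrahedra are supported; quadratic
midside nodes on the endo/epicardial boundaries are projected onto the
analytic surfaces so the discrete geometry is curved.

A cylindrical disc generator with the same machinery provides the tissue
slab used by the micropipette-aspiration forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FEMesh",
    "ventricle_shell_mesh",
    "cylinder_disc_mesh",
    "to_quadratic",
    "refine_uniform",
    "surface_corner_triangles",
    "surface_vertex_normals",
]

# VTK tet-10 edge ordering: midside node k sits on edge _TET_EDGES[k].
_TET_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
# Outward-oriented corner faces of a positive-volume tet.
_TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))


@dataclass
class FEMesh:
    """Tetrahedral mesh with labelled boundary surfaces and a fiber field.

    ``elems`` holds 4 columns for linear and 10 for quadratic tets (VTK
    ordering).  ``surfaces`` maps ``"endo" | "epi" | "base" | ...`` to facet
    connectivity arrays (3 or 6 columns).  ``fiber`` is the per-node unit
    reference direction of active tension ``e_f0``.
    """

    nodes: np.ndarray
    elems: np.ndarray
    surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    fiber: np.ndarray | None = None
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    # Analytic geometry metadata (set by the generators; used for midside
    # projection, synthetic motion and cavity closure).
    endo_axes: np.ndarray | None = None
    wall_thickness: float | None = None
    base_z: float | None = None
    cavity_point: np.ndarray | None = None

    @property
    def order(self) -> int:
        return 1 if self.elems.shape[1] == 4 else 2

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def copy(self) -> "FEMesh":
        return replace(
            self,
            nodes=self.nodes.copy(),
            elems=self.elems.copy(),
            surfaces={k: v.copy() for k, v in self.surfaces.items()},
            fiber=None if self.fiber is None else self.fiber.copy(),
        )

    def with_nodes(self, nodes: np.ndarray) -> "FEMesh":
        m = self.copy()
        m.nodes = np.asarray(nodes, dtype=float)
        return m

    def volume(self) -> float:
        """Total solid volume, integrating det(J) over the elements."""
        from . import fem  # local import to avoid a cycle

        return fem.mesh_volume(self)


# ---------------------------------------------------------------------------
# structured grid -> tets
# ---------------------------------------------------------------------------


def _split_cells(hexes: list, wedges: list, nodes: list) -> np.ndarray:
    """Split hexes (8 ids) and wedges (6 ids) into conforming tets.

    Each cell gets a centre node; quadrilateral faces are split along the
    diagonal through their smallest global node id, so shared faces are
    split identically in both adjacent cells.
    """
    tets = []

    def quad_tets(q, centre):
        # q = (n0, n1, n2, n3) cyclic; diagonal through min node id
        i = int(np.argmin(q))
        a, b, c, d = q[i], q[(i + 1) % 4], q[(i + 2) % 4], q[(i + 3) % 4]
        tets.append((a, b, c, centre))
        tets.append((a, c, d, centre))

    def tri_tet(t, centre):
        tets.append((t[0], t[1], t[2], centre))

    for h in hexes:
        # h indexed as corners of a hex: (000,100,110,010, 001,101,111,011)
        centre = len(nodes)
        nodes.append(np.mean([nodes[i] for i in h], axis=0))
        n0, n1, n2, n3, n4, n5, n6, n7 = h
        quad_tets((n0, n3, n2, n1), centre)  # bottom (outward -w)
        quad_tets((n4, n5, n6, n7), centre)  # top
        quad_tets((n0, n1, n5, n4), centre)
        quad_tets((n1, n2, n6, n5), centre)
        quad_tets((n2, n3, n7, n6), centre)
        quad_tets((n3, n0, n4, n7), centre)
    for w in wedges:
        # w = (p0, a0, b0, p1, a1, b1): triangle faces (p0,a0,b0) / (p1,a1,b1)
        centre = len(nodes)
        nodes.append(np.mean([nodes[i] for i in w], axis=0))
        p0, a0, b0, p1, a1, b1 = w
        tri_tet((p0, b0, a0), centre)
        tri_tet((p1, a1, b1), centre)
        quad_tets((p0, a0, a1, p1), centre)
        quad_tets((a0, b0, b1, a1), centre)
        quad_tets((b0, p0, p1, b1), centre)
    return np.array(tets, dtype=np.int64)


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    v = np.einsum(
        "ei,ei->e",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0],
    )
    flip = v < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary triangles (corner nodes of linear tets)."""
    faces = np.concatenate([tets[:, list(f)] for f in _TET_FACES], axis=0)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return faces[counts[inv] == 1]


def _classify_faces(
    faces: np.ndarray, node_sets: dict[str, np.ndarray], n_nodes: int
) -> dict[str, np.ndarray]:
    """Label boundary faces by membership of all corners in a node set.

    ``node_sets`` is checked in order, so e.g. "base" may take precedence
    over "endo"/"epi" for faces lying entirely in the basal plane.
    """
    masks = {}
    for name, ids in node_sets.items():
        inset = np.zeros(n_nodes, dtype=bool)
        inset[ids] = True
        masks[name] = inset
    out: dict[str, list] = {name: [] for name in node_sets}
    unlabelled = 0
    for f in faces:
        for name in node_sets:
            if masks[name][f].all():
                out[name].append(f)
                break
        else:
            unlabelled += 1
    if unlabelled:
        raise RuntimeError(f"{unlabelled} boundary faces could not be labelled")
    return {k: np.array(v, dtype=np.int64) for k, v in out.items() if v}


# ---------------------------------------------------------------------------
# ventricle generator
# ---------------------------------------------------------------------------


def _endo_point(axes, theta, phi):
    a, b, c = axes
    return np.array(
        [
            a * np.sin(phi) * np.cos(theta),
            b * np.sin(phi) * np.sin(theta),
            -c * np.cos(phi),
        ]
    )


def _endo_normal(axes, p):
    n = p / np.asarray(axes) ** 2
    return n / np.linalg.norm(n)


def _shell_point(axes, thickness, theta, phi, u):
    s = _endo_point(axes, theta, phi)
    return s + u * thickness * _endo_normal(axes, s)


def _phi_at_base(axes, thickness, theta, u, z_base):
    """Solve shell z(phi) = z_base by bisection (z increases with phi)."""
    lo, hi = 1e-9, np.pi - 1e-9
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _shell_point(axes, thickness, theta, mid, u)[2] < z_base:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _grid_resolution(target: int, n_phi_cells: bool, closed: bool):
    """Pick (n_phi, n_theta, n_r) so tet count lands near ``target``."""
    best = None
    for nr in (2, 3):
        for nphi in range(3, 40):
            for ntheta in range(6, 96, 2):
                if closed:
                    n_hex = (nphi - 2) * ntheta * nr
                    n_wed = 2 * ntheta * nr
                else:
                    n_hex = (nphi - 1) * ntheta * nr
                    n_wed = ntheta * nr
                ntet = 12 * n_hex + 8 * n_wed
                # keep in-plane cells near-isotropic (circumference is
                # roughly 2.3x the meridional arc of a cropped ellipsoid)
                aspect = abs(np.log(ntheta / (2.3 * nphi)))
                score = abs(ntet - target) / target + 0.4 * aspect + 0.05 * (nr - 2)
                if best is None or score < best[0]:
                    best = (score, (nphi, ntheta, nr))
    return best[1]


def ventricle_shell_mesh(
    semi_axes=(0.72, 0.72, 1.0),
    wall_thickness: float = 0.18,
    base_crop_fraction: float = 0.3,
    target_element_count: int = 3000,
    order: int = 2,
    fiber_mode: str = "circumferential",
    seed: int = 0,
) -> FEMesh:
    """Thick-walled truncated-ellipsoid ventricle mesh.

    ``base_crop_fraction`` is the fraction of the long-axis extent (2c)
    removed at the base; ``0`` builds a closed shell (useful for analytic
    volume checks).  Lengths in mm.
    """
    axes = np.asarray(semi_axes, dtype=float)
    a, b, c = axes
    t = float(wall_thickness)
    if np.any(axes <= 0):
        raise ValueError("semi_axes must be positive")
    if not 0 < t < axes.min():
        raise ValueError("wall_thickness must be in (0, min(semi_axes))")
    if not 0 <= base_crop_fraction < 1:
        raise ValueError("base_crop_fraction must be in [0, 1)")
    closed = base_crop_fraction == 0
    z_base = c * (1.0 - 2.0 * base_crop_fraction)

    n_phi, n_theta, n_r = _grid_resolution(target_element_count, True, closed)
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta

    nodes: list[np.ndarray] = []
    # node ids: nid[ir][iphi] -> int (pole) or array of ints (ring)
    nid: list[list] = []
    endo_ids, epi_ids, base_ids = [], [], []
    for ir in range(n_r + 1):
        u = ir / n_r
        layer = []
        # apex pole
        pid = len(nodes)
        nodes.append(_shell_point(axes, t, 0.0, 0.0, u))
        layer.append(pid)
        if ir == 0:
            endo_ids.append(pid)
        if ir == n_r:
            epi_ids.append(pid)
        n_rings = n_phi - 1 if closed else n_phi
        phi_max = (
            np.full(n_theta, np.pi)
            if closed
            else np.array([_phi_at_base(axes, t, th, u, z_base) for th in thetas])
        )
        for i in range(1, n_rings + 1):
            frac = i / n_phi
            ring = []
            for j, th in enumerate(thetas):
                pid = len(nodes)
                p = _shell_point(axes, t, th, frac * phi_max[j], u)
                if (not closed) and i == n_rings:
                    p[2] = z_base  # exact planarity of the basal cut
                nodes.append(p)
                ring.append(pid)
                if ir == 0:
                    endo_ids.append(pid)
                if ir == n_r:
                    epi_ids.append(pid)
                if (not closed) and i == n_rings:
                    base_ids.append(pid)
            layer.append(np.array(ring))
        if closed:
            pid = len(nodes)
            nodes.append(_shell_point(axes, t, 0.0, np.pi, u))
            layer.append(pid)
            if ir == 0:
                endo_ids.append(pid)
            if ir == n_r:
                epi_ids.append(pid)
        nid.append(layer)

    hexes, wedges = [], []
    n_levels = len(nid[0])  # pole + rings (+ pole)
    for ir in range(n_r):
        lo, hi = nid[ir], nid[ir + 1]
        for i in range(n_levels - 1):
            level_lo_is_pole = i == 0
            level_hi_is_pole = closed and (i + 1 == n_levels - 1)
            for j in range(n_theta):
                jn = (j + 1) % n_theta
                if level_lo_is_pole:
                    wedges.append(
                        (lo[0], lo[1][j], lo[1][jn], hi[0], hi[1][j], hi[1][jn])
                    )
                elif level_hi_is_pole:
                    wedges.append(
                        (
                            lo[i][jn],
                            lo[i][j],
                            lo[-1],
                            hi[i][jn],
                            hi[i][j],
                            hi[-1],
                        )
                    )
                else:
                    hexes.append(
                        (
                            lo[i][j],
                            lo[i][jn],
                            lo[i + 1][jn],
                            lo[i + 1][j],
                            hi[i][j],
                            hi[i][jn],
                            hi[i + 1][jn],
                            hi[i + 1][j],
                        )
                    )

    tets = _split_cells(hexes, wedges, nodes)
    node_arr = np.array(nodes)
    tets = _orient_positive(node_arr, tets)
    faces = _boundary_faces(tets)
    sets = {}
    if base_ids:
        sets["base"] = np.array(base_ids)
    sets["endo"] = np.array(endo_ids)
    sets["epi"] = np.array(epi_ids)
    surfaces = _classify_faces(faces, sets, len(node_arr))

    mesh = FEMesh(
        nodes=node_arr,
        elems=tets,
        surfaces=surfaces,
        endo_axes=axes,
        wall_thickness=t,
        base_z=None if closed else z_base,
        cavity_point=np.array([0.0, 0.0, 0.0 if closed else z_base]),
    )
    _attach_fibers(mesh, fiber_mode, seed)
    if order == 2:
        mesh = to_quadratic(mesh)
    n = mesh.n_elems
    if abs(n - target_element_count) > 0.25 * target_element_count:
        warnings.warn(
            f"element count {n} misses target {target_element_count} by >25%"
        )
    return mesh


def _attach_fibers(mesh: FEMesh, mode: str, seed: int) -> None:
    """Unit active-direction field, constant across the wall thickness."""
    X = mesh.nodes
    axis = mesh.long_axis
    r = X - np.outer(X @ axis, axis)
    rn = np.linalg.norm(r, axis=1)
    circ = np.cross(np.tile(axis, (len(X), 1)), r)
    cn = np.linalg.norm(circ, axis=1)
    ok = cn > 1e-12
    circ[ok] /= cn[ok, None]
    circ[~ok] = [1.0, 0.0, 0.0]  # apex pole fallback
    if mode == "circumferential":
        fib = circ
    elif mode == "random-tangent":
        rng = np.random.default_rng(seed)
        if mesh.endo_axes is not None:
            n = X / mesh.endo_axes**2
            nn = np.linalg.norm(n, axis=1)
            n[nn > 1e-12] /= nn[nn > 1e-12, None]
            n[nn <= 1e-12] = [0.0, 0.0, 1.0]
        else:
            n = np.tile([0.0, 0.0, 1.0], (len(X), 1))
        # smooth random in-plane angle: low-order Fourier series in the
        # azimuth/height so the field is spatially coherent
        th = np.arctan2(X[:, 1], X[:, 0])
        h = X[:, 2] / (np.abs(X[:, 2]).max() + 1e-12)
        psi = np.zeros(len(X))
        for k in range(1, 4):
            ak, bk, ck, dk = rng.normal(size=4)
            psi += ak * np.cos(k * th) + bk * np.sin(k * th) + ck * np.cos(
                k * np.pi * h + dk
            )
        psi *= 2.0
        lon = np.cross(n, circ)
        fib = np.cos(psi)[:, None] * circ + np.sin(psi)[:, None] * lon
    else:
        raise ValueError(f"unknown fiber_mode {mode!r}")
    fib /= np.linalg.norm(fib, axis=1, keepdims=True)
    mesh.fiber = fib


# ---------------------------------------------------------------------------
# cylindrical disc (MPA slab)
# ---------------------------------------------------------------------------


def cylinder_disc_mesh(
    radius: float,
    thickness: float,
    n_rad: int = 6,
    n_theta: int = 12,
    n_z: int = 3,
    grade: float = 2.0,
    grade_z: float = 1.0,
    order: int = 2,
    radii: np.ndarray | None = None,
) -> FEMesh:
    """Cylindrical tissue disc, top surface at z=0, bottom at z=-thickness.

    Radial node spacing is graded toward the axis by ``grade`` (>1 refines
    the centre, where the aspiration pipette acts), or prescribed directly
    via ``radii`` (ascending, starting at 0).  ``grade_z`` > 1 refines the
    layers near the top surface.  Surface labels: ``top``, ``bottom``,
    ``side``.
    """
    if radii is not None:
        rs = np.asarray(radii, dtype=float)
        n_rad = len(rs) - 1
    else:
        rs = radius * np.linspace(0, 1, n_rad + 1) ** grade
    zs = -thickness * (np.arange(n_z + 1) / n_z) ** grade_z
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta

    nodes: list[np.ndarray] = []
    nid: list[list] = []
    top_ids, bot_ids, side_ids = [], [], []
    for iz, z in enumerate(zs):
        layer = []
        pid = len(nodes)
        nodes.append(np.array([0.0, 0.0, z]))
        layer.append(pid)
        if iz == 0:
            top_ids.append(pid)
        if iz == n_z:
            bot_ids.append(pid)
        for i in range(1, n_rad + 1):
            ring = []
            for th in thetas:
                pid = len(nodes)
                nodes.append(np.array([rs[i] * np.cos(th), rs[i] * np.sin(th), z]))
                ring.append(pid)
                if iz == 0:
                    top_ids.append(pid)
                if iz == n_z:
                    bot_ids.append(pid)
                if i == n_rad:
                    side_ids.append(pid)
            layer.append(np.array(ring))
        nid.append(layer)

    hexes, wedges = [], []
    for iz in range(n_z):
        lo, hi = nid[iz], nid[iz + 1]
        for i in range(n_rad):
            for j in range(n_theta):
                jn = (j + 1) % n_theta
                if i == 0:
                    wedges.append(
                        (lo[0], lo[1][j], lo[1][jn], hi[0], hi[1][j], hi[1][jn])
                    )
                else:
                    hexes.append(
                        (
                            lo[i][j],
                            lo[i][jn],
                            lo[i + 1][jn],
                            lo[i + 1][j],
                            hi[i][j],
                            hi[i][jn],
                            hi[i + 1][jn],
                            hi[i + 1][j],
                        )
                    )
    tets = _split_cells(hexes, wedges, nodes)
    node_arr = np.array(nodes)
    tets = _orient_positive(node_arr, tets)
    faces = _boundary_faces(tets)
    surfaces = _classify_faces(
        faces,
        {
            "side": np.array(side_ids),
            "top": np.array(top_ids),
            "bottom": np.array(bot_ids),
        },
        len(node_arr),
    )
    mesh = FEMesh(nodes=node_arr, elems=tets, surfaces=surfaces)
    mesh.fiber = np.tile([1.0, 0.0, 0.0], (mesh.n_nodes, 1))  # in-plane fibers
    if order == 2:
        mesh = to_quadratic(mesh)
    return mesh


# ---------------------------------------------------------------------------
# quadratic conversion / refinement
# ---------------------------------------------------------------------------


def _project_endo(axes, p):
    rho = np.linalg.norm(p / axes)
    return p / rho


def _project_epi(axes, thickness, p):
    foot = _project_endo(axes, p)
    for _ in range(3):
        foot = _project_endo(axes, p - thickness * _endo_normal(axes, foot))
    return foot + thickness * _endo_normal(axes, foot)


def to_quadratic(mesh: FEMesh) -> FEMesh:
    """Insert midside nodes (VTK tet-10 ordering).

    Midside nodes on the endocardial/epicardial boundary are projected onto
    the analytic surfaces when the mesh carries ellipsoid metadata; edges
    touching the basal plane are left straight so the cut stays planar.
    """
    if mesh.order == 2:
        return mesh
    nodes = [p for p in mesh.nodes]
    in_set = {}
    for name in ("endo", "epi", "base"):
        s = np.zeros(mesh.n_nodes, dtype=bool)
        if name in mesh.surfaces:
            s[np.unique(mesh.surfaces[name])] = True
        in_set[name] = s
    axes, t = mesh.endo_axes, mesh.wall_thickness
    edge_mid: dict[tuple[int, int], int] = {}

    def midnode(i, j):
        key = (i, j) if i < j else (j, i)
        if key in edge_mid:
            return edge_mid[key]
        p = 0.5 * (mesh.nodes[i] + mesh.nodes[j])
        if axes is not None:
            on_base = in_set["base"][i] or in_set["base"][j]
            if not on_base:
                if in_set["endo"][i] and in_set["endo"][j]:
                    p = _project_endo(axes, p)
                elif in_set["epi"][i] and in_set["epi"][j]:
                    p = _project_epi(axes, t, p)
        pid = len(nodes)
        nodes.append(p)
        edge_mid[key] = pid
        return pid

    elems = np.empty((mesh.n_elems, 10), dtype=np.int64)
    elems[:, :4] = mesh.elems
    for e, tet in enumerate(mesh.elems):
        for k, (i, j) in enumerate(_TET_EDGES):
            elems[e, 4 + k] = midnode(int(tet[i]), int(tet[j]))

    surfaces = {}
    for name, tris in mesh.surfaces.items():
        out = np.empty((len(tris), 6), dtype=np.int64)
        out[:, :3] = tris
        for f, tri in enumerate(tris):
            out[f, 3] = edge_mid[tuple(sorted((tri[0], tri[1])))]
            out[f, 4] = edge_mid[tuple(sorted((tri[1], tri[2])))]
            out[f, 5] = edge_mid[tuple(sorted((tri[0], tri[2])))]
        surfaces[name] = out

    node_arr = np.array(nodes)
    # curved midside projection can invert coarse elements near the apex;
    # blend offending midside nodes back toward the straight midpoint
    straight = np.array(
        [
            0.5 * (mesh.nodes[i] + mesh.nodes[j])
            for (i, j) in sorted(edge_mid, key=edge_mid.get)
        ]
    )
    mid_ids = np.array(sorted(edge_mid.values()))
    from .fem import _TET10_QP, tet_shape  # local import to avoid a cycle

    # validate positivity at the parent quadrature points AND at the
    # quadrature points of all eight uniform-refinement children, so a
    # valid mesh stays valid under isoparametric refinement
    qp = _TET10_QP[0]
    lam_qp = np.column_stack([1 - qp.sum(axis=1), qp])  # (4, 4) barycentric
    check_pts = [qp]
    for ch in _BEY_CHILDREN:
        corners = np.array(ch, dtype=float) / 2.0  # (4, 4) barycentric
        lam_child = lam_qp @ corners  # (4, 4) in parent barycentric
        check_pts.append(lam_child[:, 1:])
    check_pts = np.vstack(check_pts)
    _, dN10 = tet_shape(2, check_pts)
    for _ in range(10):
        xe = node_arr[elems]
        detJ = np.linalg.det(np.einsum("eai,qaj->eqij", xe, dN10))
        bad = np.where((detJ <= 0).any(axis=1))[0]
        if len(bad) == 0:
            break
        bad_mids = np.unique(elems[bad][:, 4:])
        sel = np.isin(mid_ids, bad_mids)
        node_arr[mid_ids[sel]] = 0.5 * (
            node_arr[mid_ids[sel]] + straight[sel]
        )
    else:
        raise RuntimeError("could not untangle curved quadratic elements")
    fiber = None
    if mesh.fiber is not None:
        fiber = np.empty((len(node_arr), 3))
        fiber[: mesh.n_nodes] = mesh.fiber
        for (i, j), m in edge_mid.items():
            v = mesh.fiber[i] + mesh.fiber[j]
            n = np.linalg.norm(v)
            fiber[m] = v / n if n > 1e-12 else mesh.fiber[i]
    out_mesh = replace(mesh, nodes=node_arr, elems=elems, surfaces=surfaces)
    out_mesh.fiber = fiber
    return out_mesh


def _linear_refine(nodes, tets):
    """Split each linear tet into 8; returns (nodes, tets)."""
    pts = [np.asarray(p) for p in nodes]
    edge_mid: dict[tuple[int, int], int] = {}

    def midnode(i, j):
        key = (i, j) if i < j else (j, i)
        if key not in edge_mid:
            edge_mid[key] = len(pts)
            pts.append(0.5 * (pts[i] + pts[j]))
        return edge_mid[key]

    out = []
    for tet in tets:
        n0, n1, n2, n3 = (int(x) for x in tet)
        m01 = midnode(n0, n1)
        m12 = midnode(n1, n2)
        m02 = midnode(n0, n2)
        m03 = midnode(n0, n3)
        m13 = midnode(n1, n3)
        m23 = midnode(n2, n3)
        out += [
            (n0, m01, m02, m03),
            (n1, m12, m01, m13),
            (n2, m02, m12, m23),
            (n3, m03, m13, m23),
            # octahedron core, split through the m02-m13 diagonal
            (m02, m13, m01, m12),
            (m02, m13, m12, m23),
            (m02, m13, m23, m03),
            (m02, m13, m03, m01),
        ]
    return np.asarray(pts), np.asarray(out, dtype=np.int64)


# 8-subtet (Bey) refinement in reference barycentric coordinates
# (denominator 2); all children positively oriented.
_BEY_CHILDREN = (
    ((2, 0, 0, 0), (1, 1, 0, 0), (1, 0, 1, 0), (1, 0, 0, 1)),
    ((0, 2, 0, 0), (0, 1, 1, 0), (1, 1, 0, 0), (0, 1, 0, 1)),
    ((0, 0, 2, 0), (1, 0, 1, 0), (0, 1, 1, 0), (0, 0, 1, 1)),
    ((0, 0, 0, 2), (0, 1, 0, 1), (1, 0, 0, 1), (0, 0, 1, 1)),
    ((1, 0, 1, 0), (0, 1, 0, 1), (1, 1, 0, 0), (0, 1, 1, 0)),
    ((1, 0, 1, 0), (0, 1, 0, 1), (0, 1, 1, 0), (0, 0, 1, 1)),
    ((1, 0, 1, 0), (0, 1, 0, 1), (0, 0, 1, 1), (1, 0, 0, 1)),
    ((1, 0, 1, 0), (0, 1, 0, 1), (1, 0, 0, 1), (1, 1, 0, 0)),
)


def _refine_quadratic_isoparametric(mesh: FEMesh) -> FEMesh:
    """Geometry-preserving refinement of a curved quadratic mesh.

    Every child node is placed through the parent's isoparametric map, so
    the refined mesh reproduces the parent geometry exactly (children of a
    quadratic map are the same quadratic map restricted to sub-tets) and
    inherits positive Jacobians.
    """
    from .fem import tet_shape

    # child tet-10 nodes in parent barycentric (denominator 4)
    child_nodes_bary = []
    for ch in _BEY_CHILDREN:
        corners = [np.array(c) * 2 for c in ch]  # denominator 4
        mids = [
            (corners[i] + corners[j]) // 2
            for (i, j) in ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
        ]
        child_nodes_bary.append(corners + mids)

    # shape functions at every distinct barycentric lattice point used
    all_bary = sorted({tuple(b) for ch in child_nodes_bary for b in ch})
    bary_index = {b: k for k, b in enumerate(all_bary)}
    pts = np.array([[b[1] / 4.0, b[2] / 4.0, b[3] / 4.0] for b in all_bary])
    N, _ = tet_shape(2, pts)  # (n_lattice, 10)

    node_key_to_id: dict = {}
    new_nodes: list = []
    new_fiber: list = []
    prol_rows: list = []
    prol_cols: list = []
    prol_vals: list = []
    elems_out = np.empty((mesh.n_elems * 8, 10), dtype=np.int64)
    for e, tet in enumerate(mesh.elems):
        corners = tet[:4]
        # positions of all lattice points of this parent
        xloc = N @ mesh.nodes[tet]  # (n_lattice, 3)
        floc = None
        if mesh.fiber is not None:
            floc = N @ mesh.fiber[tet]
        ids = np.empty(len(all_bary), dtype=np.int64)
        for k, b in enumerate(all_bary):
            key = tuple(
                sorted((int(corners[i]), int(b[i])) for i in range(4) if b[i])
            )
            nid = node_key_to_id.get(key)
            if nid is None:
                nid = len(new_nodes)
                node_key_to_id[key] = nid
                new_nodes.append(xloc[k])
                if floc is not None:
                    new_fiber.append(floc[k])
                # prolongation: interpolate parent nodal fields here
                prol_rows.extend([nid] * 10)
                prol_cols.extend(int(t) for t in tet)
                prol_vals.extend(N[k])
            ids[k] = nid
        for c, ch in enumerate(child_nodes_bary):
            elems_out[8 * e + c] = [ids[bary_index[tuple(b)]] for b in ch]

    nodes = np.asarray(new_nodes)
    # surface node sets by barycentric support on parent surface facets
    surf_sets = {}
    for name, facets in mesh.surfaces.items():
        members = set(int(i) for i in np.unique(facets))
        surf_sets[name] = members
    node_sets = {name: [] for name in surf_sets}
    for key, nid in node_key_to_id.items():
        support = [c for c, _ in key]
        for name, members in surf_sets.items():
            if all(c in members for c in support):
                node_sets[name].append(nid)

    faces = _boundary_faces(elems_out[:, :4])
    order_names = [
        n for n in ("base", "side", "top", "bottom", "endo", "epi") if n in node_sets
    ]
    sets = {n: np.asarray(node_sets[n], dtype=np.int64) for n in order_names}
    surfaces3 = _classify_faces(faces, sets, len(nodes))
    # attach midside nodes to the 3-corner facets
    edge_map = {}
    for tet in elems_out:
        for k, (i, j) in enumerate(_TET_EDGES):
            a, b = int(tet[i]), int(tet[j])
            edge_map[(a, b) if a < b else (b, a)] = int(tet[4 + k])
    surfaces = {}
    for name, tris in surfaces3.items():
        out = np.empty((len(tris), 6), dtype=np.int64)
        out[:, :3] = tris
        for f, tri in enumerate(tris):
            out[f, 3] = edge_map[tuple(sorted((tri[0], tri[1])))]
            out[f, 4] = edge_map[tuple(sorted((tri[1], tri[2])))]
            out[f, 5] = edge_map[tuple(sorted((tri[0], tri[2])))]
        surfaces[name] = out

    out_mesh = replace(mesh, nodes=nodes, elems=elems_out, surfaces=surfaces)
    if mesh.fiber is not None:
        fib = np.asarray(new_fiber)
        fib /= np.maximum(np.linalg.norm(fib, axis=1, keepdims=True), 1e-30)
        out_mesh.fiber = fib
    else:
        out_mesh.fiber = None
    import scipy.sparse as _sp

    out_mesh.prolongation = _sp.csr_matrix(
        (prol_vals, (prol_rows, prol_cols)), shape=(len(nodes), mesh.n_nodes)
    )
    return out_mesh


def refine_uniform(mesh: FEMesh) -> FEMesh:
    """Uniformly refine (8 children per tet), preserving labels and order."""
    order = mesh.order
    if order == 2:
        return _refine_quadratic_isoparametric(mesh)
    else:
        nodes, tets = _linear_refine(mesh.nodes, mesh.elems)
        tets = _orient_positive(nodes, tets)
        surface_nodes = {}
        for name, f in mesh.surfaces.items():
            ids = set(int(i) for i in np.unique(f))
            extra = []
            # midpoints of surface edges belong to the surface
            for tri in f:
                for i, j in ((0, 1), (1, 2), (0, 2)):
                    a, b = int(tri[i]), int(tri[j])
                    extra.append((min(a, b), max(a, b)))
            surface_nodes[name] = (name, ids, extra)
        # resolve edge midpoint ids: rebuild the midnode map
        edge_map = {}
        base_n = mesh.n_nodes
        # _linear_refine assigned midnodes in deterministic order; recompute
        count = base_n
        seen = {}
        for tet in mesh.elems:
            for i, j in _TET_EDGES:
                a, b = int(tet[i]), int(tet[j])
                key = (a, b) if a < b else (b, a)
                if key not in seen:
                    seen[key] = count
                    count += 1
        edge_map = seen
        resolved = {}
        for name, (nm, ids, extra) in surface_nodes.items():
            mids = {edge_map[e] for e in extra if e in edge_map}
            resolved[name] = np.array(sorted(ids | mids), dtype=np.int64)
        surface_nodes = resolved

    faces = _boundary_faces(tets)
    order_names = [n for n in ("base", "side", "top", "bottom", "endo", "epi") if n in surface_nodes]
    sets = {n: np.asarray(surface_nodes[n]) for n in order_names}
    surfaces = _classify_faces(faces, sets, len(nodes))
    out = replace(mesh, nodes=nodes, elems=tets, surfaces=surfaces)
    if mesh.fiber is not None:
        fib = np.empty((len(nodes), 3))
        fib[: mesh.n_nodes] = mesh.fiber[: mesh.n_nodes]
        for (a, b), m in edge_map.items():
            v = mesh.fiber[a] + mesh.fiber[b]
            nn = np.linalg.norm(v)
            fib[m] = v / nn if nn > 1e-12 else mesh.fiber[a]
        out.fiber = fib
    else:
        out.fiber = None
    return out


# ---------------------------------------------------------------------------
# surface helpers
# ---------------------------------------------------------------------------


def surface_corner_triangles(mesh: FEMesh, name: str) -> np.ndarray:
    """Flat triangle decomposition of a labelled surface.

    Quadratic 6-node facets are split into 4 sub-triangles through their
    midside nodes; linear facets pass through unchanged.  Orientation
    (solid-outward) is preserved.
    """
    f = mesh.surfaces[name]
    if f.shape[1] == 3:
        return f
    subs = [
        f[:, [0, 3, 5]],
        f[:, [3, 1, 4]],
        f[:, [5, 4, 2]],
        f[:, [3, 4, 5]],
    ]
    return np.concatenate(subs, axis=0)


def surface_vertex_normals(mesh: FEMesh, name: str):
    """(vertex ids, area-weighted outward unit normals) of a surface."""
    tris = surface_corner_triangles(mesh, name)
    p = mesh.nodes[tris]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2*area*normal
    ids = np.unique(tris)
    idx = {int(v): k for k, v in enumerate(ids)}
    normals = np.zeros((len(ids), 3))
    for f, tri in enumerate(tris):
        for v in tri:
            normals[idx[int(v)]] += fn[f]
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals /= np.maximum(norms, 1e-30)
    return ids, normals
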