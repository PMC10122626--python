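"""Quasi-static nonlinear finite elements for the embryonic ventricle.

Total-Lagrangian displacement formulation on linear or quadratic
tetrahedra.  Passive stress is the Fung law plus a volumetric penalty
U(J) = kappa/2 (ln J)^2 enforcing near-incompressibility; active stress is
the Guccione rank-one Cauchy stress pulled back to a second Piola-Kirchhoff
contribution S_a = J sigma / (e_f0 . C e_f0) e_f0 (x) e_f0.

Cavity pressure is applied through the enclosed-volume potential: with the
endocardial surface closed by a fan to a fixed point in the basal plane,
the cavity volume V(u) is a cubic polynomial in the nodal positions, the
consistent follower nodal force is p dV/du and the (symmetric) load
stiffness is p d2V/du2 -- pressure loading of a closed cavity is
conservative.  Volume-constrained steps treat the pressure as a Lagrange
multiplier and solve the bordered Newton system by block elimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import constitutive as cm
from .constitutive import ActiveParams, FungParams, MMHG_TO_PA
from .geometry import FEMesh, surface_corner_triangles

__all__ = [
    "SolverConfig",
    "CavityState",
    "FEProblem",
    "cavity_volume",
    "solve_pressure_step",
    "solve_volume_step",
    "mpa_forward",
    "mpa_slab_problem",
    "mesh_volume",
    "ventricle_problem",
]


# ---------------------------------------------------------------------------
# quadrature / shape functions
# ---------------------------------------------------------------------------

_TET4_QP = (np.array([[0.25, 0.25, 0.25]]), np.array([1.0 / 6.0]))
_A, _B = 0.5854101966249685, 0.1381966011250105
_TET10_QP = (
    np.array([[_B, _B, _B], [_A, _B, _B], [_B, _A, _B], [_B, _B, _A]]),
    np.full(4, 1.0 / 24.0),
)
# degree-3 rule used for volume integrals of curved elements
_TET_QP5 = (
    np.array(
        [
            [0.25, 0.25, 0.25],
            [0.5, 1 / 6, 1 / 6],
            [1 / 6, 0.5, 1 / 6],
            [1 / 6, 1 / 6, 0.5],
            [1 / 6, 1 / 6, 1 / 6],
        ]
    ),
    np.array([-4.0 / 30.0, 0.075, 0.075, 0.075, 0.075]),
)


def tet_shape(order: int, pts: np.ndarray):
    """Shape functions and reference gradients at barycentric-style points.

    ``pts`` holds (xi, eta, zeta); lambda = (1 - xi - eta - zeta, xi, eta,
    zeta).  Returns N (Q, nen) and dN (Q, nen, 3) in VTK node ordering.
    """
    pts = np.asarray(pts, dtype=float)
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    lam = np.stack([1 - xi - eta - zeta, xi, eta, zeta], axis=1)  # (Q,4)
    dlam = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )  # (4,3)
    if order == 1:
        N = lam
        dN = np.broadcast_to(dlam, (len(pts), 4, 3)).copy()
        return N, dN
    Q = len(pts)
    N = np.empty((Q, 10))
    dN = np.empty((Q, 10, 3))
    for i in range(4):
        N[:, i] = lam[:, i] * (2 * lam[:, i] - 1)
        dN[:, i] = (4 * lam[:, i] - 1)[:, None] * dlam[i]
    edges = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
    for k, (i, j) in enumerate(edges):
        N[:, 4 + k] = 4 * lam[:, i] * lam[:, j]
        dN[:, 4 + k] = 4 * (
            lam[:, i][:, None] * dlam[j] + lam[:, j][:, None] * dlam[i]
        )
    return N, dN


def mesh_volume(mesh: FEMesh, u: np.ndarray | None = None) -> float:
    """Solid volume (deformed if ``u`` given), via a degree-3 rule."""
    pts, w = _TET_QP5 if mesh.order == 2 else _TET4_QP
    _, dN = tet_shape(mesh.order, pts)
    x = mesh.nodes if u is None else mesh.nodes + u
    xe = x[mesh.elems]  # (M, nen, 3)
    J = np.einsum("eai,qaj->eqij", xe, dN)
    return float(np.einsum("eq,q->", np.linalg.det(J), w))


# ---------------------------------------------------------------------------
# enclosed-volume pressure surface
# ---------------------------------------------------------------------------


def _cross_mat(v: np.ndarray) -> np.ndarray:
    """Matrix X(v) with X @ w = v x w; batched over leading dims."""
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


class PressureSurface:
    """Signed enclosed volume of a triangulated surface closed by a fan.

    An open surface (e.g. the endocardium cut at the base) is closed by a
    fan from the centroid of its boundary ring to the ring itself; since
    the fan point follows the ring, the volume is exact whenever the ring
    is planar and invariant under rigid translations.  A closed surface
    needs no fan (the formula is then independent of the reference point).
    The sign is fixed at construction so the reference volume is
    non-negative.  The volume Hessian omits the (planarity-vanishing)
    fan-point coupling terms; with the basal out-of-plane constraint the
    ring stays planar and the omission is exact.
    """

    def __init__(self, tris: np.ndarray, q: np.ndarray, ref_nodes: np.ndarray):
        self.tris = np.asarray(tris, dtype=np.int64)
        # boundary ring: edges used by exactly one triangle
        edges = np.concatenate(
            [self.tris[:, [0, 1]], self.tris[:, [1, 2]], self.tris[:, [2, 0]]]
        )
        key = np.sort(edges, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        ring_edges = edges[counts[inv] == 1]
        self.ring = np.unique(ring_edges)
        self._q_fallback = np.asarray(q, dtype=float)
        self.sign = 1.0
        v = self._raw_volume(ref_nodes)
        self.sign = 1.0 if v >= 0 else -1.0

    def _q(self, x: np.ndarray) -> np.ndarray:
        if len(self.ring):
            return x[self.ring].mean(axis=0)
        return self._q_fallback

    def _raw_volume(self, x: np.ndarray) -> float:
        p = x[self.tris] - self._q(x)
        return float(
            np.einsum("ti,ti->t", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0
        )

    def volume(self, x: np.ndarray) -> float:
        return self.sign * self._raw_volume(x)

    def grad(self, x: np.ndarray, n_nodes: int) -> np.ndarray:
        """dV/dx as an (n_nodes, 3) array (fan-point chain rule included)."""
        p = x[self.tris] - self._q(x)
        g = np.empty_like(p)
        g[:, 0] = np.cross(p[:, 1], p[:, 2])
        g[:, 1] = np.cross(p[:, 2], p[:, 0])
        g[:, 2] = np.cross(p[:, 0], p[:, 1])
        g *= self.sign / 6.0
        out = np.zeros((n_nodes, 3))
        np.add.at(out, self.tris.ravel(), g.reshape(-1, 3))
        if len(self.ring):
            dV_dq = -g.sum(axis=(0, 1))
            out[self.ring] += dV_dq / len(self.ring)
        return out

    def hess_blocks(self, x: np.ndarray):
        """Nonzero Hessian blocks as (rows, cols, 3x3 values) triplets.

        d2V/da db = s/6 * (-X(c)), d2V/da dc = s/6 * X(b),
        d2V/db dc = s/6 * (-X(a)); diagonal blocks vanish.  Fan-point
        coupling terms are omitted (see class docstring).
        """
        p = x[self.tris] - self._q(x)
        a, b, c = p[:, 0], p[:, 1], p[:, 2]
        s = self.sign / 6.0
        pairs = []
        for (i, j, blk) in (
            (0, 1, -_cross_mat(c)),
            (0, 2, _cross_mat(b)),
            (1, 2, -_cross_mat(a)),
        ):
            blk = s * blk
            pairs.append((self.tris[:, i], self.tris[:, j], blk))
            pairs.append((self.tris[:, j], self.tris[:, i], np.swapaxes(blk, -1, -2)))
        return pairs


def cavity_volume(mesh: FEMesh, u: np.ndarray | None = None) -> float:
    """Volume enclosed by the (deformed) endocardial surface and the basal
    plane, by the divergence theorem."""
    surf = PressureSurface(
        surface_corner_triangles(mesh, "endo"), mesh.cavity_point, mesh.nodes
    )
    x = mesh.nodes if u is None else mesh.nodes + u
    return surf.volume(x)


# ---------------------------------------------------------------------------
# solver configuration / state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    bulk_modulus: float = 2.0e5  # Pa
    newton_tol: float = 1.0e-6  # relative residual
    max_newton_iter: int = 25
    load_steps: int = 4
    volume_tol: float = 1.0e-4  # relative cavity-volume mismatch
    max_halvings: int = 8

    def __post_init__(self):
        if min(self.bulk_modulus, self.newton_tol, self.volume_tol) <= 0:
            raise ValueError("tolerances and bulk modulus must be positive")


@dataclass
class CavityState:
    """Converged equilibrium: cavity pressure (Pa), volume (mm^3), nodal
    displacements (mm), and the solve bookkeeping."""

    pressure: float
    volume: float
    displacement: np.ndarray
    t_active: float = 0.0
    activation: float = 0.0
    newton_iters: int = 0
    predictor: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.volume is not None and self.volume <= 0:
            raise ValueError("cavity volume must be positive")


class NewtonDivergence(RuntimeError):
    def __init__(self, msg, halvings=0):
        super().__init__(msg)
        self.halvings = halvings


class _Factor:
    """Sparse LU with symmetric-mode ordering and iterative refinement.

    SuperLU's symmetric mode with a relaxed pivot threshold is an order of
    magnitude faster on these symmetric-pattern stiffness matrices than the
    default column ordering; one refinement step recovers the accuracy lost
    to the relaxed pivoting.  Falls back to the default factorization if
    the relaxed one breaks down.
    """

    def __init__(self, K: sp.csr_matrix):
        self.A = K.tocsc()
        try:
            self.lu = spla.splu(
                self.A,
                permc_spec="MMD_AT_PLUS_A",
                diag_pivot_thresh=1e-3,
                options=dict(SymmetricMode=True),
            )
        except RuntimeError:
            self.lu = spla.splu(self.A)

    def solve(self, b: np.ndarray) -> np.ndarray:
        x = self.lu.solve(b)
        x += self.lu.solve(b - self.A @ x)
        return x


# ---------------------------------------------------------------------------
# sparse pattern
# ---------------------------------------------------------------------------


class _Pattern:
    """Fixed sparsity pattern with fast repeated accumulation.

    Entries are (row, col) dof pairs in the reduced (free-dof) numbering;
    repeated values are summed with add.reduceat over a precomputed
    permutation.
    """

    def __init__(self, rows: np.ndarray, cols: np.ndarray, n: int):
        key = rows.astype(np.int64) * n + cols
        order = np.argsort(key, kind="stable")
        sk = key[order]
        uniq, starts = np.unique(sk, return_index=True)
        self.order = order
        self.starts = starts
        self.n = n
        self.rows_u = (uniq // n).astype(np.int32)
        self.cols_u = (uniq % n).astype(np.int32)
        csr = sp.csr_matrix(
            (np.zeros(len(uniq)), (self.rows_u, self.cols_u)), shape=(n, n)
        )
        csr.sort_indices()
        self.indptr = csr.indptr
        self.indices = csr.indices
        # position of each unique entry in the csr data array
        lookup = sp.csr_matrix(
            (np.arange(len(uniq), dtype=np.int64), (self.rows_u, self.cols_u)),
            shape=(n, n),
        )
        lookup.sort_indices()
        inv = np.empty(len(uniq), dtype=np.int64)
        inv[lookup.data] = np.arange(len(uniq))
        self.csr_pos = inv

    def build(self, values: np.ndarray) -> sp.csr_matrix:
        acc = np.add.reduceat(values[self.order], self.starts)
        data = np.empty_like(acc)
        data[self.csr_pos] = acc
        return sp.csr_matrix((data, self.indices, self.indptr), shape=(self.n, self.n))


# ---------------------------------------------------------------------------
# the assembled problem
# ---------------------------------------------------------------------------


class FEProblem:
    """Precomputed FE operator for one mesh + boundary-condition set.

    ``fixed`` is an (N, 3) boolean mask of Dirichlet (zero) dofs.
    ``pressure_surface`` receives the consistent enclosed-volume load.
    Material parameters are attributes so inverse loops can update them
    without re-precomputing geometry.
    """

    def __init__(
        self,
        mesh: FEMesh,
        fung: FungParams,
        active: ActiveParams | None = None,
        config: SolverConfig = SolverConfig(),
        fixed: np.ndarray | None = None,
        pressure_surface: PressureSurface | None = None,
        active_formulation: str = "cauchy",
    ):
        self.mesh = mesh
        self.fung = fung
        self.active = active or ActiveParams()
        self.config = config
        self.active_formulation = active_formulation
        if fixed is None:
            fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
        self.fixed = fixed
        self.surf = pressure_surface
        self._precompute()

    # -- geometry precomputation -------------------------------------------
    def _precompute(self):
        mesh = self.mesh
        pts, w = _TET10_QP if mesh.order == 2 else _TET4_QP
        N, dN = tet_shape(mesh.order, pts)
        self.qp_N = N
        xe = mesh.nodes[mesh.elems]  # (M, nen, 3)
        J = np.einsum("eai,qaj->eqij", xe, dN)  # dX/dxi
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise RuntimeError("non-positive Jacobian in reference mesh")
        invJ = np.linalg.inv(J)
        # gradN[e,q,a,i] = dN_a/dX_i
        self.gradN = np.einsum("qaj,eqji->eqai", dN, invJ)
        self.wdetJ = detJ * w[None, :]
        fib = mesh.fiber[mesh.elems]  # (M, nen, 3)
        f0 = np.einsum("qa,eai->eqi", N, fib)
        f0 /= np.linalg.norm(f0, axis=-1, keepdims=True)
        self.f0 = f0
        # complete orthonormal frames (batched)
        helper = np.where(
            (np.abs(f0[..., 2]) > 0.9)[..., None],
            np.array([1.0, 0.0, 0.0]),
            np.array([0.0, 0.0, 1.0]),
        )
        s = np.cross(helper, f0)
        s /= np.linalg.norm(s, axis=-1, keepdims=True)
        n = np.cross(f0, s)
        self.R = np.stack([f0, s, n], axis=-1)  # (M,Q,3,3) columns f,s,n
        self.M0 = np.einsum("eqi,eqj->eqij", f0, f0)

        # reduced dof numbering
        free = ~self.fixed.ravel()
        self.free = free
        self.n_free = int(free.sum())
        dofmap = -np.ones(mesh.n_nodes * 3, dtype=np.int64)
        dofmap[free] = np.arange(self.n_free)
        self.dofmap = dofmap

        # sparsity pattern: element blocks + pressure-surface blocks
        nen = mesh.elems.shape[1]
        edofs = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(
            mesh.n_elems, 3 * nen
        )
        er = np.repeat(edofs, 3 * nen, axis=1).ravel()
        ec = np.tile(edofs, (1, 3 * nen)).ravel()
        rows = [er]
        cols = [ec]
        self._elem_entry_mask = None
        if self.surf is not None:
            tris = self.surf.tris
            # order must mirror PressureSurface.hess_blocks
            for i, j in ((0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)):
                di = 3 * tris[:, i, None] + np.arange(3)
                dj = 3 * tris[:, j, None] + np.arange(3)
                rows.append(np.repeat(di, 3, axis=1).ravel())
                cols.append(np.tile(dj, (1, 3)).ravel())
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        rr = dofmap[rows]
        cc = dofmap[cols]
        keep = (rr >= 0) & (cc >= 0)
        self._keep = keep
        self._n_elem_entries = er.size
        self.pattern = _Pattern(rr[keep], cc[keep], self.n_free)

    # -- material evaluation ----------------------------------------------
    def _active_g(self, lam2, t):
        """g = sigma/lam2 and its derivative wrt lam2 (finite difference)."""
        p = self.active

        def g_of(l2):
            l = np.sqrt(l2) * p.l_r
            return cm.active_tension(t, l, p) / l2

        g = g_of(lam2)
        h = 1e-6
        gp = (g_of(lam2 + h) - g_of(lam2 - h)) / (2 * h)
        return g, gp

    def _stress_and_tangent(self, u, t_active, act_scale, want_tangent=True):
        mesh = self.mesh
        ue = u[mesh.elems]
        F = np.einsum("eai,eqaj->eqij", ue, self.gradN)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F[..., 2, 2] += 1.0
        C = np.einsum("eqki,eqkj->eqij", F, F, optimize=True)
        E = 0.5 * (C - np.eye(3))
        R = self.R
        Ef = np.einsum("eqji,eqjk,eqkl->eqil", R, E, R, optimize=True)
        Q, M = cm._q_and_m(Ef, self.fung)
        if np.any(Q > cm._Q_MAX):
            raise NewtonDivergence("Fung exponent overflow (element inverted?)")
        eQ = np.exp(Q)
        Sf = 2.0 * self.fung.C * eQ[..., None, None] * M
        S = np.einsum("eqij,eqjk,eqlk->eqil", R, Sf, R, optimize=True)

        kappa = self.config.bulk_modulus
        detC = np.linalg.det(C)
        if np.any(detC <= 0):
            raise NewtonDivergence("negative volume ratio at quadrature point")
        lnJ = 0.5 * np.log(detC)
        Cinv = np.linalg.inv(C)
        S_vol = kappa * lnJ[..., None, None] * Cinv
        S = S + S_vol

        S_act = 0.0
        g = gp = lam2 = None
        if act_scale != 0.0:
            lam2 = np.einsum("eqi,eqij,eqj->eq", self.f0, C, self.f0, optimize=True)
            g, gp = self._active_g(lam2, t_active)
            g = g * act_scale
            gp = gp * act_scale
            Jdet = np.sqrt(detC)
            S_act = (Jdet * g)[..., None, None] * self.M0
            S = S + S_act

        out = {"F": F, "S": S, "lnJ": lnJ, "detC": detC, "Cinv": Cinv,
               "S_act": S_act, "Ef": Ef, "eQ": eQ, "M": M}
        if not want_tangent:
            return out

        A = self.fung.exponent_matrix()
        I3 = np.eye(3)
        Isym = 0.5 * (
            np.einsum("ik,jl->ijkl", I3, I3) + np.einsum("il,jk->ijkl", I3, I3)
        )
        CC_f = 4.0 * self.fung.C * eQ[..., None, None, None, None] * np.einsum("eqij,eqkl->eqijkl", M, M, optimize=True)
        CC_f += (
            2.0
            * self.fung.C
            * eQ[..., None, None, None, None]
            * np.einsum("ij,ijkl->ijkl", A, Isym)
        )
        CC = np.einsum(
            "eqia,eqjb,eqkc,eqld,eqabcd->eqijkl", R, R, R, R, CC_f, optimize=True
        )
        # volumetric tangent
        CC += kappa * np.einsum("eqij,eqkl->eqijkl", Cinv, Cinv, optimize=True)
        CiCi = 0.5 * (
            np.einsum("eqik,eqjl->eqijkl", Cinv, Cinv, optimize=True)
            + np.einsum("eqil,eqjk->eqijkl", Cinv, Cinv, optimize=True)
        )
        CC += (-2.0 * kappa) * lnJ[..., None, None, None, None] * CiCi
        if act_scale != 0.0:
            Jdet = np.sqrt(detC)
            CC += np.einsum("eqij,eqkl->eqijkl", self.M0, (Jdet * g)[..., None, None] * Cinv, optimize=True)
            CC += 2.0 * np.einsum("eqij,eqkl->eqijkl", self.M0, (Jdet * gp)[..., None, None] * self.M0, optimize=True)
        out["CC"] = CC
        return out

    # -- assembly -----------------------------------------------------------
    def internal_force(self, u, t_active=0.0, act_scale=0.0, parts=False):
        d = self._stress_and_tangent(u, t_active, act_scale, want_tangent=False)
        P = np.einsum("eqij,eqjk->eqik", d["F"], d["S"])
        fe = np.einsum("eqik,eqak,eq->eai", P, self.gradN, self.wdetJ, optimize=True)
        f = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(f, self.mesh.elems.ravel(), fe.reshape(-1, 3))
        if not parts:
            return f
        f_act = np.zeros((self.mesh.n_nodes, 3))
        if act_scale != 0.0:
            Pa = np.einsum("eqij,eqjk->eqik", d["F"], np.asarray(d["S_act"]), optimize=True)
            fa = np.einsum("eqik,eqak,eq->eai", Pa, self.gradN, self.wdetJ, optimize=True)
            np.add.at(f_act, self.mesh.elems.ravel(), fa.reshape(-1, 3))
        return f, f_act

    def assemble(self, u, p, t_active=0.0, act_scale=0.0, tangent=True):
        """Reduced residual (and tangent): R = f_int - p dV/du."""
        d = self._stress_and_tangent(u, t_active, act_scale, want_tangent=tangent)
        mesh = self.mesh
        F, S = d["F"], d["S"]
        P = np.einsum("eqij,eqjk->eqik", F, S, optimize=True)
        fe = np.einsum("eqik,eqak,eq->eai", P, self.gradN, self.wdetJ, optimize=True)
        f = np.zeros((mesh.n_nodes, 3))
        np.add.at(f, mesh.elems.ravel(), fe.reshape(-1, 3))

        V = None
        gfull = np.zeros((mesh.n_nodes, 3))
        if self.surf is not None:
            x = mesh.nodes + u
            V = self.surf.volume(x)
            gfull = self.surf.grad(x, mesh.n_nodes)
        r = (f - p * gfull).ravel()[self.free]
        g_red = gfull.ravel()[self.free]
        if not tangent:
            return r, None, g_red, V

        CC = d["CC"]
        # first elasticity tensor A_iJkL = delta_ik S_JL + F_iM C_MJNL F_kN
        D = np.einsum("eqim,eqmjnl,eqkn->eqijkl", F, CC, F, optimize=True)
        # contract with both shape-gradient arrays through batched matmuls
        # (an order of magnitude faster than the equivalent einsum)
        E_, Q_ = D.shape[:2]
        nen = self.mesh.elems.shape[1]
        Dw = D * self.wdetJ[..., None, None, None, None]
        T1 = np.matmul(
            Dw.reshape(E_ * Q_, 27, 3),
            np.swapaxes(self.gradN, -1, -2).reshape(E_ * Q_, 3, nen),
        )  # (EQ, (i,j,k), b)
        T1 = (
            T1.reshape(E_ * Q_, 3, 3, 3, nen)
            .transpose(0, 2, 1, 3, 4)
            .reshape(E_ * Q_, 3, 9 * nen)
        )  # (EQ, j, (i,k,b))
        T2 = np.matmul(self.gradN.reshape(E_ * Q_, nen, 3), T1)  # (EQ, a, (i,k,b))
        Ke = (
            T2.reshape(E_, Q_, -1)
            .sum(axis=1)
            .reshape(E_, nen, 3, 3, nen)
            .transpose(0, 1, 2, 4, 3)
        )  # (e, a, i, b, k)
        Ke = np.ascontiguousarray(Ke)
        geo = np.einsum("eqaj,eqjl,eqbl,eq->eab", self.gradN, S, self.gradN, self.wdetJ, optimize=True)
        Ke += np.einsum("eab,ik->eaibk", geo, np.eye(3), optimize=True)
        nen = mesh.elems.shape[1]
        vals = [Ke.reshape(mesh.n_elems, -1).ravel()]
        if self.surf is not None:
            x = mesh.nodes + u
            for rows_t, cols_t, blk in self.surf.hess_blocks(x):
                vals.append((-p) * blk.reshape(len(rows_t), 9).ravel())
        values = np.concatenate(vals)[self._keep]
        K = self.pattern.build(values)
        return r, K, g_red, V

    # -- Newton ------------------------------------------------------------
    def _newton(
        self,
        u0,
        p0,
        *,
        pressure=None,
        volume=None,
        t_active=0.0,
        act_scale=0.0,
    ):
        cfg = self.config
        u = u0.copy()
        p = float(pressure) if pressure is not None else float(p0)
        bad = 0
        lu = None
        rebuild = True
        free_idx = np.where(self.free)[0]
        max_total = 3 * cfg.max_newton_iter
        builds = 0
        merit_prev = None
        for it in range(max_total):
            r, K, g, V = self.assemble(u, p, t_active, act_scale, tangent=rebuild)
            if rebuild:
                if builds >= cfg.max_newton_iter:
                    raise NewtonDivergence("Newton did not converge (tangent budget)")
                lu = _Factor(K)
                builds += 1
            gnorm = np.linalg.norm(g)
            # external-load reference for the relative residual
            if act_scale != 0.0:
                _, f_act = self.internal_force(u, t_active, act_scale, parts=True)
                act_ref = np.linalg.norm(f_act.ravel()[self.free])
            else:
                act_ref = 0.0
            ref = max(abs(p) * gnorm, act_ref, 1e-9)
            rnorm = np.linalg.norm(r)
            vol_ok = True
            if volume is not None:
                vol_ok = abs(V - volume) <= cfg.volume_tol * volume
            if getattr(self, "verbose", False):
                print(
                    f"    it {it} rnorm {rnorm:.3e} ref {ref:.3e} "
                    f"V {V} p {p:.4g} rebuild {rebuild}"
                )
            if rnorm <= cfg.newton_tol * ref and vol_ok:
                # du/dp at the solution, for the caller's step predictor
                w2 = lu.solve(g) if gnorm > 0 else np.zeros_like(g)
                return u, p, V, it, (w2, g)
            if volume is not None:
                w1 = lu.solve(r)
                w2 = lu.solve(g)
                denom = g @ w2
                if abs(denom) < 1e-300:
                    raise NewtonDivergence("singular volume-pressure coupling")
                dp = (g @ w1 - (V - volume)) / denom
                du = -w1 + dp * w2
            else:
                dp = 0.0
                du = -lu.solve(r)
            if not np.all(np.isfinite(du)):
                raise NewtonDivergence("non-finite Newton update")
            # backtracking line search on the merit ||r|| (+ volume mismatch)
            merit0 = rnorm + (abs(V - volume) / volume * ref if volume is not None else 0)
            best = None
            for alpha in (1.0, 0.5, 0.25):
                u_try = u.copy()
                u_try.reshape(-1)[free_idx] = u.reshape(-1)[self.free] + alpha * du
                p_try = p + alpha * dp
                try:
                    r_t, _, g_t, V_t = self.assemble(
                        u_try, p_try, t_active, act_scale, tangent=False
                    )
                except NewtonDivergence:
                    continue
                merit = np.linalg.norm(r_t) + (
                    abs(V_t - volume) / volume * ref if volume is not None else 0
                )
                if best is None or merit < best[0]:
                    best = (merit, alpha, u_try, p_try)
                if merit < 0.5 * merit0:
                    break  # good enough, stop probing
            if best is None:
                if not rebuild:
                    rebuild = True  # stale tangent: refresh and retry
                    bad = 0
                    continue
                raise NewtonDivergence("no admissible Newton step")
            merit, alpha, u, p = best
            bad = bad + 1 if merit > merit0 else 0
            if bad >= 3:
                raise NewtonDivergence("Newton residual diverging")
            # reuse the factorization while convergence is fast enough
            rebuild = merit > 0.25 * merit0 or (alpha < 1.0)
        raise NewtonDivergence("Newton did not converge")

    def solve(
        self,
        start: CavityState | None = None,
        *,
        pressure=None,
        volume=None,
        t_active=None,
        act_scale=None,
        n_steps=None,
    ) -> CavityState:
        """Continuation-driven solve to target pressure OR cavity volume.

        The load parameters (pressure/volume target, activation time and
        scale) are ramped linearly from the starting state; increments are
        halved adaptively on Newton divergence.
        """
        if (pressure is None) == (volume is None):
            raise ValueError("specify exactly one of pressure or volume")
        cfg = self.config
        if start is None:
            u = np.zeros((self.mesh.n_nodes, 3))
            p_prev = 0.0
            t_prev = 0.0
            a_prev = 0.0
            V_prev = (
                self.surf.volume(self.mesh.nodes) if self.surf is not None else None
            )
            start_predictor = None
        else:
            u = start.displacement.copy()
            p_prev = start.pressure
            t_prev = start.t_active
            a_prev = start.activation
            V_prev = start.volume
            start_predictor = start.predictor
        t_tgt = t_prev if t_active is None else float(t_active)
        a_tgt = a_prev if act_scale is None else float(act_scale)

        s = 0.0
        ds = 1.0 / (n_steps or cfg.load_steps)
        halved = 0
        iters_total = 0
        p_cur = p_prev
        V_cur = V_prev
        predictor = start_predictor  # (w2, g) from the last converged solve
        free_idx = np.where(self.free)[0]
        while s < 1.0 - 1e-12:
            s_try = min(1.0, s + ds)
            kw = dict(
                t_active=t_prev + s_try * (t_tgt - t_prev),
                act_scale=a_prev + s_try * (a_tgt - a_prev),
            )
            if pressure is not None:
                kw["pressure"] = p_prev + s_try * (pressure - p_prev)
            else:
                kw["volume"] = V_prev + s_try * (volume - V_prev)
            # tangent predictor: extrapolate along du/dp from the last
            # converged state
            u_init, p_init = u, p_cur
            if predictor is not None:
                w2, gvec = predictor
                if pressure is not None:
                    dp_pred = kw["pressure"] - p_cur
                else:
                    gw = gvec @ w2
                    dp_pred = (kw["volume"] - V_cur) / gw if abs(gw) > 1e-300 else 0.0
                u_init = u.copy()
                u_init.reshape(-1)[free_idx] = u.reshape(-1)[self.free] + dp_pred * w2
                p_init = p_cur + dp_pred
            try:
                u_new, p_new, V_new, its, predictor_new = self._newton(
                    u_init, p_init, **kw
                )
            except NewtonDivergence:
                halved += 1
                if halved > cfg.max_halvings:
                    raise NewtonDivergence(
                        f"load step failed after {halved} halvings", halvings=halved
                    )
                ds *= 0.5
                continue
            u, p_cur, V_cur = u_new, p_new, V_new
            predictor = predictor_new
            s = s_try
            iters_total += its + 1
            if its <= 4:
                ds = min(ds * 1.7, max(1.0 - s, 1e-6))
        return CavityState(
            pressure=p_cur,
            volume=V_new if self.surf is not None else mesh_volume(self.mesh, u),
            displacement=u,
            t_active=t_tgt,
            activation=a_tgt,
            newton_iters=iters_total,
            predictor=predictor,
        )

    def strain_energy_total(self, u) -> float:
        """Stored energy (Fung + volumetric penalty) of a displacement field."""
        d = self._stress_and_tangent(u, 0.0, 0.0, want_tangent=False)
        W, _ = cm.strain_energy(d["Ef"], self.fung)
        W_vol = 0.5 * self.config.bulk_modulus * d["lnJ"] ** 2
        return float(np.einsum("eq,eq->", W + W_vol, self.wdetJ))

    def cauchy_stress(self, u, t_active=0.0, act_scale=0.0):
        """Per-quadrature-point Cauchy stress (total), averaged per element."""
        d = self._stress_and_tangent(u, t_active, act_scale, want_tangent=False)
        F, S = d["F"], d["S"]
        J = np.sqrt(d["detC"])
        sig = np.einsum("eqij,eqjk,eqlk->eqil", F, S, F, optimize=True) / J[..., None, None]
        w = self.wdetJ / self.wdetJ.sum(axis=1, keepdims=True)
        return np.einsum("eqij,eq->eij", sig, w)

    def jacobian_range(self, u):
        d = self._stress_and_tangent(u, 0.0, 0.0, want_tangent=False)
        J = np.sqrt(d["detC"])
        return float(J.min()), float(J.max())


# ---------------------------------------------------------------------------
# canned problems
# ---------------------------------------------------------------------------


def ventricle_problem(
    mesh: FEMesh,
    fung: FungParams,
    active: ActiveParams | None = None,
    config: SolverConfig = SolverConfig(),
) -> FEProblem:
    """Ventricle with basal out-of-plane constraint and cavity pressure.

    Basal nodes are fixed along the long axis only (in-plane motion free);
    two basal nodes are additionally pinned in-plane to remove the
    remaining rigid modes.
    """
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    base_nodes = np.unique(mesh.surfaces["base"])
    fixed[base_nodes, 2] = True
    xy = mesh.nodes[base_nodes, :2]
    a_node = base_nodes[int(np.argmax(xy[:, 0]))]
    b_node = base_nodes[int(np.argmin(xy[:, 0]))]
    fixed[a_node, 0] = True
    fixed[a_node, 1] = True
    fixed[b_node, 1] = True
    surf = PressureSurface(
        surface_corner_triangles(mesh, "endo"), mesh.cavity_point, mesh.nodes
    )
    return FEProblem(mesh, fung, active, config, fixed, surf)


def solve_pressure_step(
    problem: FEProblem,
    pressure: float,
    t_active: float = 0.0,
    act_scale: float = 0.0,
    start: CavityState | None = None,
    n_steps: int | None = None,
) -> CavityState:
    """Equilibrium at a prescribed cavity pressure (Pa)."""
    return problem.solve(
        start, pressure=pressure, t_active=t_active, act_scale=act_scale,
        n_steps=n_steps,
    )


def solve_volume_step(
    problem: FEProblem,
    target_volume: float,
    t_active: float = 0.0,
    act_scale: float = 0.0,
    start: CavityState | None = None,
    n_steps: int | None = None,
) -> CavityState:
    """Equilibrium at a prescribed cavity volume; pressure is the output."""
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    return problem.solve(
        start, volume=target_volume, t_active=t_active, act_scale=act_scale,
        n_steps=n_steps,
    )


# ---------------------------------------------------------------------------
# micropipette aspiration forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MPAGeometry:
    """Tissue-slab idealization of the aspiration experiment.

    The pipette lumen (radius ``pipette_radius``) is a suction-loaded disc
    on the top surface; the annular pipette rim blocks vertical motion; the
    lateral and bottom boundaries (several pipette radii away) are fixed.
    Lengths in mm.
    """

    pipette_radius: float = 0.060
    rim_width: float = 0.030
    slab_radius_factor: float = 6.0
    thickness: float = 0.24
    n_theta: int = 6
    n_z: int = 3
    order: int = 2


def _mpa_radii(geom: MPAGeometry) -> np.ndarray:
    rp, w = geom.pipette_radius, geom.rim_width
    r_out = geom.slab_radius_factor * rp
    inner = list(np.linspace(0.0, rp, 4))
    rim = [rp + w]
    rest = list(np.geomspace(rp + 2.5 * w, r_out, 4))
    return np.array(inner + rim + rest)


def mpa_slab_problem(
    fung: FungParams,
    geom: MPAGeometry = MPAGeometry(),
    config: SolverConfig | None = None,
) -> FEProblem:
    """FE problem for the aspiration slab (suction on the lumen disc)."""
    from .geometry import cylinder_disc_mesh

    rp = geom.pipette_radius
    r_out = geom.slab_radius_factor * rp
    mesh = cylinder_disc_mesh(
        radius=r_out,
        thickness=geom.thickness,
        n_theta=geom.n_theta,
        n_z=geom.n_z,
        grade_z=1.6,
        order=geom.order,
        radii=_mpa_radii(geom),
    )
    if config is None:
        config = SolverConfig(bulk_modulus=5e4, load_steps=6)
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    for name in ("side", "bottom"):
        fixed[np.unique(mesh.surfaces[name])] = True
    r = np.linalg.norm(mesh.nodes[:, :2], axis=1)
    top_nodes = np.unique(mesh.surfaces["top"])
    on_rim = (r[top_nodes] >= rp - 1e-9) & (r[top_nodes] <= rp + geom.rim_width + 1e-9)
    fixed[top_nodes[on_rim], 2] = True
    # lumen surface: top sub-triangles fully inside the pipette radius
    tris = surface_corner_triangles(mesh, "top")
    inside = (r[tris] <= rp + 1e-9).all(axis=1)
    lumen = tris[inside]
    surf = PressureSurface(lumen, np.array([0.0, 0.0, 0.0]), mesh.nodes)
    # orient so suction (positive p below) increases aspirated volume upward
    prob = FEProblem(mesh, fung, None, config, fixed, surf)
    centre_candidates = top_nodes[r[top_nodes] < 1e-9]
    prob.centre_node = int(centre_candidates[0])
    return prob


def mpa_forward(
    fung: FungParams,
    pressures_mmhg: np.ndarray,
    geom: MPAGeometry = MPAGeometry(),
    config: SolverConfig | None = None,
    problem: FEProblem | None = None,
) -> np.ndarray:
    """Aspirated lengths (um) at each vacuum pressure (mmHg, <= 0).

    Pressure steps are solved sequentially, each warm-started from the
    previous converged state.
    """
    pressures_mmhg = np.asarray(pressures_mmhg, dtype=float)
    if np.any(pressures_mmhg > 1e-12):
        raise ValueError("aspiration pressures must be non-positive (vacuum)")
    if problem is None:
        problem = mpa_slab_problem(fung, geom, config)
    else:
        problem.fung = fung
    lengths = np.empty(len(pressures_mmhg))
    state = None
    for k, p_mmhg in enumerate(pressures_mmhg):
        suction = -p_mmhg * MMHG_TO_PA  # positive suction magnitude, Pa
        if suction == 0.0:
            lengths[k] = 0.0
            if state is None:
                state = CavityState(
                    pressure=0.0,
                    volume=max(problem.surf.volume(problem.mesh.nodes), 1e-12),
                    displacement=np.zeros((problem.mesh.n_nodes, 3)),
                )
            continue
        try:
            state = problem.solve(state, pressure=suction)
        except NewtonDivergence as err:
            raise RuntimeError(
                f"aspiration forward solve failed at step {k} "
                f"({p_mmhg} mmHg): {err}"
            ) from err
        lengths[k] = state.displacement[problem.centre_node, 2] * 1000.0  # mm -> um
    return lengths
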