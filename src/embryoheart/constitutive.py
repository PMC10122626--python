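"""Myocardial constitutive models of the HH25 chick ventricle.

Passive behaviour is a transversely isotropic Fung-type hyperelastic law,

    W = C (exp(Q) - 1),
    Q = b_ff E_ff^2 + b_xx (E_ss^2 + E_nn^2 + E_sn^2 + E_ns^2)
        + b_fx (E_fn^2 + E_nf^2 + E_fs^2 + E_sf^2),

with the Green-Lagrange strain E expressed in the local fiber/sheet/
sheet-normal frame.  Active contraction follows the Guccione model: a
rank-one Cauchy stress of magnitude

    sigma = T_max * Ca0^2 / (ECa50^2 + Ca0^2) * C_t

along the current fiber direction, where the calcium sensitivity
ECa50 = Ca0_max / sqrt(exp(B (l - l0)) - 1) depends on the sarcomere
length l = sqrt(e_f0 . C_V e_f0) * l_r, and the activation transient
C_t = (1 - cos w)/2 rises over [0, t0) and relaxes over [t0, t0 + t_r)
with a length-dependent relaxation time t_r = m l + b.

Units: stresses Pa, lengths of sarcomeres um, times ms, calcium uM.
All tensor functions are batched: leading array dimensions broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "FungParams",
    "ActiveParams",
    "FiberFrame",
    "KinematicState",
    "NORMAL_FUNG",
    "LAL_FUNG",
    "default_active_params",
    "strain_energy",
    "passive_stress",
    "passive_stress_fiber",
    "passive_tangent_fiber",
    "eca50",
    "sarcomere_length",
    "ct",
    "active_tension",
    "active_stress",
]

MMHG_TO_PA = 133.322

_Q_MAX = 80.0  # exp(Q) overflow guard; strains beyond this are unphysical

CYCLE_PERIOD_MS = 60000.0 / 164.0  # 164 bpm


@dataclass(frozen=True)
class FungParams:
    """Fung-law parameters: scaling stress C (Pa) and exponents."""

    C: float
    b_ff: float = 29.9
    b_xx: float = 13.3
    b_fx: float = 26.6

    def __post_init__(self):
        if self.C <= 0 or min(self.b_ff, self.b_xx, self.b_fx) <= 0:
            raise ValueError("Fung parameters must be positive")

    def exponent_matrix(self) -> np.ndarray:
        """Coefficient matrix A with Q = sum_ij A_ij E_ij^2 (fiber frame)."""
        b_ff, b_xx, b_fx = self.b_ff, self.b_xx, self.b_fx
        return np.array(
            [
                [b_ff, b_fx, b_fx],
                [b_fx, b_xx, b_xx],
                [b_fx, b_xx, b_xx],
            ]
        )


NORMAL_FUNG = FungParams(C=19.7)
LAL_FUNG = FungParams(C=27.6)


@dataclass(frozen=True)
class ActiveParams:
    """Guccione active-contraction parameters.

    ``m`` and ``b`` (relaxation-time law t_r = m l + b) default so that
    t_r at the relaxed sarcomere length spans 45% of the 164 bpm cycle --
    long enough that the transient covers systole and early relaxation
    and end-systolic pressures stay positive, as in the published
    pressure-volume loops -- with the same relative length sensitivity
    (d ln t_r / d ln l) as the canonical adult parameterization.
    """

    T_max: float = 7000.0  # Pa
    Ca0: float = 4.35  # uM
    Ca0_max: float = 4.35  # uM
    B: float = 4.75  # 1/um
    l0: float = 1.7  # um
    l_r: float = 2.2  # um
    t0: float = 110.0  # ms
    m: float = 194.6  # ms/um
    b: float = 0.45 * CYCLE_PERIOD_MS - 194.6 * 2.2  # ms

    def __post_init__(self):
        if min(self.Ca0, self.Ca0_max, self.B, self.l0, self.l_r, self.t0) <= 0:
            raise ValueError("active parameters must be positive")
        if self.l_r <= self.l0:
            raise ValueError("relaxed length l_r must exceed l0")
        if self.t_r(self.l0) <= 0:
            raise ValueError("relaxation time t_r must stay positive above l0")

    def t_r(self, l):
        return self.m * np.asarray(l) + self.b


def default_active_params(T_max: float = 7000.0) -> ActiveParams:
    return ActiveParams(T_max=T_max)


@dataclass(frozen=True)
class FiberFrame:
    """Right-handed orthonormal (fiber, sheet, sheet-normal) triad."""

    f: np.ndarray
    s: np.ndarray
    n: np.ndarray

    @classmethod
    def from_fiber(cls, f: np.ndarray) -> "FiberFrame":
        """Complete an orthonormal frame from the fiber direction alone."""
        f = np.asarray(f, dtype=float)
        f = f / np.linalg.norm(f)
        helper = np.array([0.0, 0.0, 1.0])
        if abs(f @ helper) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        s = np.cross(helper, f)
        s /= np.linalg.norm(s)
        n = np.cross(f, s)
        return cls(f=f, s=s, n=n)

    @property
    def rotation(self) -> np.ndarray:
        """Matrix R with columns (f, s, n): E_fiber = R^T E R."""
        return np.stack([self.f, self.s, self.n], axis=-1)


@dataclass
class KinematicState:
    """Deformation gradient plus the local fiber frame, with derived tensors."""

    F: np.ndarray
    frame: FiberFrame

    @property
    def C_V(self) -> np.ndarray:
        F = np.asarray(self.F)
        return np.swapaxes(F, -1, -2) @ F

    @property
    def J(self) -> np.ndarray:
        return np.linalg.det(self.F)

    @property
    def E(self) -> np.ndarray:
        return 0.5 * (self.C_V - np.eye(3))

    @property
    def E_fiber(self) -> np.ndarray:
        R = self.frame.rotation
        return np.swapaxes(R, -1, -2) @ self.E @ R

    @property
    def e_f(self) -> np.ndarray:
        v = np.asarray(self.F) @ self.frame.f
        return v / np.linalg.norm(v, axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# passive law
# ---------------------------------------------------------------------------


def _q_and_m(E_fiber: np.ndarray, p: FungParams):
    A = p.exponent_matrix()
    M = A * E_fiber  # Hadamard: dQ/dE = 2 M
    Q = np.einsum("...ij,...ij->...", A, E_fiber**2)
    return Q, M


def strain_energy(E_fiber: np.ndarray, p: FungParams):
    """(W, Q) of the Fung law for fiber-frame Green-Lagrange strain."""
    E_fiber = np.asarray(E_fiber, dtype=float)
    Q, _ = _q_and_m(E_fiber, p)
    if np.any(Q > _Q_MAX):
        raise OverflowError("Fung exponent Q exceeds overflow guard (unphysical strain)")
    return p.C * (np.exp(Q) - 1.0), Q


def passive_stress_fiber(E_fiber: np.ndarray, p: FungParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress in the fiber frame: S = 2 C e^Q (A o E)."""
    E_fiber = np.asarray(E_fiber, dtype=float)
    Q, M = _q_and_m(E_fiber, p)
    if np.any(Q > _Q_MAX):
        raise OverflowError("Fung exponent Q exceeds overflow guard (unphysical strain)")
    return 2.0 * p.C * np.exp(Q)[..., None, None] * M


def passive_tangent_fiber(E_fiber: np.ndarray, p: FungParams) -> np.ndarray:
    """dS/dE (fourth-order, fiber frame), symmetrized in the last two slots."""
    E_fiber = np.asarray(E_fiber, dtype=float)
    Q, M = _q_and_m(E_fiber, p)
    if np.any(Q > _Q_MAX):
        raise OverflowError("Fung exponent Q exceeds overflow guard (unphysical strain)")
    eQ = np.exp(Q)[..., None, None, None, None]
    A = p.exponent_matrix()
    I3 = np.eye(3)
    Isym = 0.5 * (
        np.einsum("ik,jl->ijkl", I3, I3) + np.einsum("il,jk->ijkl", I3, I3)
    )
    term1 = 4.0 * p.C * eQ * np.einsum("...ij,...kl->...ijkl", M, M)
    term2 = 2.0 * p.C * eQ * np.einsum("...ij,ijkl->...ijkl", A + 0 * M, Isym)
    return term1 + term2


def passive_stress(state: KinematicState, p: FungParams) -> np.ndarray:
    """Fung second Piola-Kirchhoff stress in the global frame."""
    R = state.frame.rotation
    S_f = passive_stress_fiber(state.E_fiber, p)
    return R @ S_f @ np.swapaxes(R, -1, -2)


# ---------------------------------------------------------------------------
# active law
# ---------------------------------------------------------------------------


def eca50(l, p: ActiveParams):
    """Length-dependent calcium sensitivity; +inf at or below l0 (no tension)."""
    l = np.asarray(l, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.exp(p.B * (l - p.l0)) - 1.0
        out = np.where(l > p.l0, p.Ca0_max / np.sqrt(np.maximum(arg, 0.0)), np.inf)
    return out if out.ndim else float(out)


def active_fraction(l, p: ActiveParams):
    """Ca0^2 / (ECa50^2 + Ca0^2): in (0, 1), increasing with length above l0."""
    l = np.asarray(l, dtype=float)
    e = np.exp(np.minimum(p.B * (l - p.l0), 700.0)) - 1.0
    # Ca0^2/(ECa50^2+Ca0^2) with ECa50^2 = Ca0_max^2 / e  (e > 0)
    frac = np.where(
        l > p.l0,
        p.Ca0**2 * np.maximum(e, 0.0) / (p.Ca0_max**2 + p.Ca0**2 * np.maximum(e, 0.0)),
        0.0,
    )
    return frac if frac.ndim else float(frac)


def sarcomere_length(state_or_C, p: ActiveParams, ef0: np.ndarray | None = None):
    """l = sqrt(e_f0 . C_V e_f0) * l_r (um)."""
    if isinstance(state_or_C, KinematicState):
        C_V = state_or_C.C_V
        ef0 = state_or_C.frame.f
    else:
        C_V = np.asarray(state_or_C, dtype=float)
        if ef0 is None:
            raise ValueError("ef0 required when passing C_V directly")
    lam2 = np.einsum("...i,...ij,...j->...", ef0, C_V, ef0)
    return np.sqrt(lam2) * p.l_r


def ct(t, l, p: ActiveParams):
    """Activation transient C_t(t; l) with the three-branch phase angle."""
    t = np.asarray(t, dtype=float)
    l = np.asarray(l, dtype=float)
    t_r = p.t_r(l)
    if np.any((t_r <= 0) & (l > p.l0)):
        raise ValueError("relaxation duration t_r = m*l + b is non-positive")
    # below l0 no tension develops at all; clamp t_r so the transient is
    # well-defined there (the active fraction is zero regardless)
    t_r = np.maximum(t_r, 1e-9)
    omega = np.where(
        t < p.t0,
        np.pi * t / p.t0,
        np.where(t < p.t0 + t_r, np.pi * (t - p.t0 + t_r) / t_r, 0.0),
    )
    omega = np.where(t < 0, 0.0, omega)
    out = 0.5 * (1.0 - np.cos(omega))
    return out if out.ndim else float(out)


def active_tension(t, l, p: ActiveParams):
    """Scalar active fiber stress sigma(t, l) in Pa."""
    return p.T_max * active_fraction(l, p) * ct(t, l, p)


def active_stress(
    state: KinematicState,
    t,
    p: ActiveParams,
    formulation: str = "cauchy",
) -> np.ndarray:
    """Active stress tensor.

    ``formulation="cauchy"`` (default): sigma * e_f (x) e_f with e_f the
    current (pushed-forward, normalized) fiber direction -- the standard
    reading of the Guccione rank-one stress.  ``"second-piola"`` returns
    sigma * e_f0 (x) e_f0 in the reference configuration instead.
    """
    l = sarcomere_length(state, p)
    sigma = np.asarray(active_tension(t, l, p))
    if formulation == "cauchy":
        ef = state.e_f
        return sigma[..., None, None] * np.einsum("...i,...j->...ij", ef, ef)
    if formulation == "second-piola":
        ef0 = state.frame.f
        return sigma[..., None, None] * np.einsum("...i,...j->...ij", ef0, ef0)
    raise ValueError(f"unknown formulation {formulation!r}")
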