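"""Fung strain-energy law and Guccione active-tension model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryoheart import constitutive as cm
from embryoheart.constitutive import (
    LAL_FUNG,
    NORMAL_FUNG,
    ActiveParams,
    FiberFrame,
    FungParams,
    KinematicState,
)

FRAME = FiberFrame(
    f=np.array([1.0, 0.0, 0.0]),
    s=np.array([0.0, 1.0, 0.0]),
    n=np.array([0.0, 0.0, 1.0]),
)


def _E(**kw):
    E = np.zeros((3, 3))
    ix = {"ff": (0, 0), "ss": (1, 1), "nn": (2, 2), "fs": (0, 1), "fn": (0, 2), "sn": (1, 2)}
    for k, v in kw.items():
        i, j = ix[k]
        E[i, j] = E[j, i] = v
    return E


class TestStrainEnergy:
    def test_zero_strain(self):
        W, Q = cm.strain_energy(np.zeros((3, 3)), NORMAL_FUNG)
        assert W == 0.0 and Q == 0.0

    def test_pure_fiber_stretch_value(self):
        # Q = b_ff * E_ff^2 with the published exponents
        W, Q = cm.strain_energy(_E(ff=0.1), NORMAL_FUNG)
        assert Q == pytest.approx(29.9 * 0.01)
        assert W == pytest.approx(19.7 * (np.exp(0.299) - 1.0))

    def test_transverse_isotropy_sn_swap(self):
        E1 = _E(ss=0.05, nn=-0.02, fs=0.03, fn=0.01, sn=0.02)
        E2 = _E(ss=-0.02, nn=0.05, fs=0.01, fn=0.03, sn=0.02)  # s <-> n
        W1, _ = cm.strain_energy(E1, NORMAL_FUNG)
        W2, _ = cm.strain_energy(E2, NORMAL_FUNG)
        assert W1 == pytest.approx(W2, rel=1e-12)

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            cm.strain_energy(_E(ff=3.0), NORMAL_FUNG)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-0.25, 0.25), min_size=6, max_size=6))
    def test_energy_nonnegative(self, comps):
        E = _E(ff=comps[0], ss=comps[1], nn=comps[2], fs=comps[3], fn=comps[4], sn=comps[5])
        W, _ = cm.strain_energy(E, LAL_FUNG)
        assert W >= 0.0
        if np.allclose(E, 0):
            assert W == 0.0
        elif np.abs(E).max() > 1e-12:
            assert W > 0.0


class TestPassiveStress:
    def test_zero_strain_zero_stress(self):
        state = KinematicState(F=np.eye(3), frame=FRAME)
        assert np.allclose(cm.passive_stress(state, NORMAL_FUNG), 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_energy_gradient(self, seed):
        # S must be the strain derivative of W (central finite differences)
        rng = np.random.default_rng(seed)
        A = 0.05 * rng.standard_normal((3, 3))
        E = 0.5 * (A + A.T)
        S = cm.passive_stress_fiber(E, NORMAL_FUNG)
        h = 1e-7
        for i in range(3):
            for j in range(3):
                dE = np.zeros((3, 3))
                dE[i, j] += 0.5 * h
                dE[j, i] += 0.5 * h
                if i == j:
                    dE[i, j] = h
                Wp, _ = cm.strain_energy(E + dE, NORMAL_FUNG)
                Wm, _ = cm.strain_energy(E - dE, NORMAL_FUNG)
                fd = (Wp - Wm) / (2 * h)
                # symmetric differentiation: off-diagonals pick up S_ij+S_ji
                ref = S[i, j] if i == j else S[i, j]
                assert fd == pytest.approx(ref, rel=1e-5, abs=1e-8)

    def test_fiber_stiffer_than_cross(self):
        lam = 1.1
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        state = KinematicState(F=F, frame=FRAME)
        S = cm.passive_stress(state, NORMAL_FUNG)
        F2 = np.diag([1 / np.sqrt(lam), lam, 1 / np.sqrt(lam)])
        S2 = cm.passive_stress(KinematicState(F=F2, frame=FRAME), NORMAL_FUNG)
        assert S[0, 0] > S2[1, 1]  # b_ff > b_xx


class TestCalciumSensitivity:
    def test_diverges_at_l0(self):
        p = ActiveParams()
        assert cm.eca50(p.l0, p) == np.inf
        assert cm.eca50(p.l0 - 0.1, p) == np.inf
        assert cm.eca50(p.l0 + 1e-9, p) > 1e3

    def test_value_at_relaxed_length(self):
        # direct evaluation of Ca0_max / sqrt(exp(B (l - l0)) - 1)
        p = ActiveParams()
        expected = 4.35 / np.sqrt(np.exp(4.75 * (2.2 - 1.7)) - 1.0)
        assert cm.eca50(2.2, p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing(self):
        p = ActiveParams()
        ls = np.linspace(p.l0 + 0.01, 3.0, 50)
        vals = cm.eca50(ls, p)
        assert np.all(np.diff(vals) < 0)

    def test_active_fraction_bounds_and_monotone(self):
        p = ActiveParams()
        ls = np.linspace(p.l0 + 1e-4, 3.0, 100)
        frac = cm.active_fraction(ls, p)
        assert np.all((frac > 0) & (frac < 1))
        assert np.all(np.diff(frac) > 0)
        assert cm.active_fraction(p.l0 - 0.2, p) == 0.0


class TestSarcomereLength:
    def test_identity(self):
        state = KinematicState(F=np.eye(3), frame=FRAME)
        assert cm.sarcomere_length(state, ActiveParams()) == pytest.approx(2.2)

    def test_uniaxial(self):
        F = np.diag([1.2, 1.0, 1.0])
        state = KinematicState(F=F, frame=FRAME)
        assert cm.sarcomere_length(state, ActiveParams()) == pytest.approx(1.2 * 2.2)

    def test_rotation_objectivity(self):
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        state = KinematicState(F=R, frame=FRAME)
        assert cm.sarcomere_length(state, ActiveParams()) == pytest.approx(2.2)


class TestActivationTransient:
    def test_endpoints(self):
        p = ActiveParams()
        l = p.l_r
        assert cm.ct(0.0, l, p) == pytest.approx(0.0)
        assert cm.ct(p.t0, l, p) == pytest.approx(1.0)
        assert cm.ct(p.t0 / 2, l, p) == pytest.approx(0.5)

    def test_relaxation_end(self):
        p = ActiveParams()
        l = p.l_r
        tr = p.t_r(l)
        assert cm.ct(p.t0 + tr, l, p) == pytest.approx(0.0, abs=1e-12)
        assert cm.ct(p.t0 + tr + 50.0, l, p) == 0.0

    def test_bad_relaxation_parameters(self):
        with pytest.raises(ValueError):
            ActiveParams(m=10.0, b=-200.0)  # t_r < 0 above l0


class TestActiveStress:
    def test_zero_after_transient(self):
        p = ActiveParams()
        state = KinematicState(F=np.eye(3), frame=FRAME)
        t_end = p.t0 + p.t_r(2.2) + 1.0
        assert np.allclose(cm.active_stress(state, t_end, p), 0.0)

    def test_zero_below_slack_length(self):
        p = ActiveParams()
        F = np.diag([0.7, 1.2, 1.2])  # fiber l = 0.7*2.2 = 1.54 < 1.7
        state = KinematicState(F=F, frame=FRAME)
        assert np.allclose(cm.active_stress(state, p.t0, p), 0.0)

    def test_peak_magnitude_direct_evaluation(self):
        # sigma = T_max Ca0^2/(ECa50^2+Ca0^2) at C_t = 1, F = I
        p = ActiveParams(T_max=7000.0)
        state = KinematicState(F=np.eye(3), frame=FRAME)
        sig = cm.active_stress(state, p.t0, p)
        eca = 4.35 / np.sqrt(np.exp(4.75 * 0.5) - 1.0)
        expect = 7000.0 * 4.35**2 / (eca**2 + 4.35**2)
        assert sig[0, 0] == pytest.approx(expect, rel=1e-10)
        assert np.allclose(sig - np.diag([sig[0, 0], 0, 0]), 0.0)

    def test_second_piola_variant(self):
        p = ActiveParams()
        F = np.diag([1.1, 1.0, 0.95])
        state = KinematicState(F=F, frame=FRAME)
        s_cauchy = cm.active_stress(state, p.t0, p, formulation="cauchy")
        s_pk2 = cm.active_stress(state, p.t0, p, formulation="second-piola")
        assert s_cauchy.shape == s_pk2.shape == (3, 3)
        assert not np.allclose(s_cauchy, 0.0)

    def test_objectivity(self):
        # rotating the deformation rotates the Cauchy stress accordingly
        p = ActiveParams()
        rng = np.random.default_rng(4)
        A = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        th = 0.9
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        s1 = cm.active_stress(KinematicState(F=A, frame=FRAME), p.t0, p)
        s2 = cm.active_stress(KinematicState(F=R @ A, frame=FRAME), p.t0, p)
        assert np.allclose(R @ s1 @ R.T, s2, atol=1e-10)


def test_parameter_validation():
    with pytest.raises(ValueError):
        FungParams(C=-1.0)
    with pytest.raises(ValueError):
        ActiveParams(l_r=1.6)  # below l0
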