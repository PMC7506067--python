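"""Holzapfel-Ogden passive law: invariants, energies, analytic stress
against a finite-difference oracle, and frame-indifference properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from stenosim.materials.passive import (DeformationState, FiberFrame,
                                        HOParameters, InvalidDeformationError,
                                        deviatoric_energy, fiber_passive_stress,
                                        isochoric_invariants,
                                        passive_cauchy_stress, total_energy,
                                        volumetric_energy)

FRAME = FiberFrame(f0=np.array([1.0, 0.0, 0.0]), s0=np.array([0.0, 1.0, 0.0]))


def fd_cauchy_stress(F, frame, params, h=1e-6):
    """Independent oracle: sigma = (1/J) dW/dF F^T by central differences
    of the total strain energy."""
    dWdF = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            dWdF[i, j] = (total_energy(DeformationState(F=Fp), frame, params)
                          - total_energy(DeformationState(F=Fm), frame, params)
                          ) / (2.0 * h)
    return dWdF @ F.T / np.linalg.det(F)


def random_admissible_F(rng, amplitude=0.08):
    while True:
        F = np.eye(3) + amplitude * rng.standard_normal((3, 3))
        if 0.95 <= np.linalg.det(F) <= 1.05:
            return F


class TestInvariants:
    def test_identity(self):
        inv = isochoric_invariants(DeformationState(F=np.eye(3)), FRAME)
        assert inv.I1bar == pytest.approx(3.0)
        assert inv.I4f == pytest.approx(1.0)
        assert inv.I4s == pytest.approx(1.0)
        assert inv.I8fs == pytest.approx(0.0)

    def test_pure_rotation_equals_identity(self, rng):
        R = Rotation.random(random_state=7).as_matrix()
        inv = isochoric_invariants(DeformationState(F=R), FRAME)
        assert inv.I1bar == pytest.approx(3.0, abs=1e-12)
        assert inv.I4f == pytest.approx(1.0, abs=1e-12)

    def test_uniaxial_fiber_stretch(self):
        lam = 1.2
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        inv = isochoric_invariants(DeformationState(F=F), FRAME)
        assert inv.I4f == pytest.approx(1.44)
        assert inv.I4s == pytest.approx(1 / 1.2)
        assert inv.I8fs == pytest.approx(0.0, abs=1e-14)
        assert inv.I1bar == pytest.approx(1.44 + 2 / 1.2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        F = random_admissible_F(rng)
        R = Rotation.random(random_state=seed).as_matrix()
        a = isochoric_invariants(DeformationState(F=F), FRAME)
        b = isochoric_invariants(DeformationState(F=R @ F), FRAME)
        for name in ("I1bar", "I4f", "I4s", "I8fs"):
            assert getattr(a, name) == pytest.approx(getattr(b, name),
                                                     rel=1e-10, abs=1e-10)

    def test_invalid_deformation(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState(F=-np.eye(3))


class TestEnergies:
    def test_reference_energy_is_zero(self):
        p = HOParameters()
        inv = isochoric_invariants(DeformationState(F=np.eye(3)), FRAME)
        assert deviatoric_energy(inv, p) == pytest.approx(0.0, abs=1e-14)

    def test_fiber_compression_contributes_nothing(self):
        p = HOParameters()
        from stenosim.materials.passive import InvariantSet
        base = InvariantSet(I1bar=3.0, I4f=1.0, I4s=1.0, I8fs=0.0)
        comp = InvariantSet(I1bar=3.0, I4f=0.9, I4s=1.0, I8fs=0.0)
        assert deviatoric_energy(comp, p) == deviatoric_energy(base, p)

    def test_deviatoric_energy_scalar_oracle(self):
        p = HOParameters()
        from stenosim.materials.passive import InvariantSet
        inv = InvariantSet(I1bar=3.2, I4f=1.21, I4s=1.0, I8fs=0.0)
        # independent hand evaluation of the strain-energy expression
        expected = (p.a / (2 * p.b) * (np.exp(p.b * 0.2) - 1.0)
                    + p.a_f / (2 * p.b_f) * (np.exp(p.b_f * 0.21 ** 2) - 1.0))
        assert deviatoric_energy(inv, p) == pytest.approx(expected, rel=1e-12)

    def test_volumetric_identity(self):
        assert volumetric_energy(1.0, 0.002) == 0.0

    def test_volumetric_stress_free_at_unit_volume(self):
        h = 1e-6
        d = (volumetric_energy(1 + h, 0.002)
             - volumetric_energy(1 - h, 0.002)) / (2 * h)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_volumetric_scalar_oracle(self):
        J, D = 1.05, 0.002
        expected = (1 / D) * ((J ** 2 - 1) / 2 - np.log(J))
        assert volumetric_energy(J, D) == pytest.approx(expected, rel=1e-12)

    def test_volumetric_rejects_nonpositive_J(self):
        with pytest.raises(InvalidDeformationError):
            volumetric_energy(-0.1, 0.002)

    def test_energy_nonnegative_near_identity(self, rng):
        p = HOParameters()
        for _ in range(50):
            F = random_admissible_F(rng, amplitude=0.05)
            F = F / np.linalg.det(F) ** (1 / 3)  # J = 1
            assert total_energy(DeformationState(F=F), FRAME, p) >= -1e-10

    def test_energy_monotone_in_fiber_stretch(self):
        p = HOParameters()
        energies = []
        for lam in np.linspace(1.01, 1.3, 12):
            F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
            inv = isochoric_invariants(DeformationState(F=F), FRAME)
            energies.append(deviatoric_energy(inv, p))
        assert np.all(np.diff(energies) > 0)


class TestCauchyStress:
    def test_zero_at_identity(self):
        sig = passive_cauchy_stress(DeformationState(F=np.eye(3)), FRAME,
                                    HOParameters())
        assert np.allclose(sig, 0.0, atol=1e-12)

    def test_matches_finite_difference_oracle(self, rng):
        """Analytic stress vs numerical differentiation of the energy on
        >= 100 random admissible deformations (rel. err < 1e-4)."""
        p = HOParameters()
        checked = 0
        while checked < 100:
            F = random_admissible_F(rng)
            st_ = DeformationState(F=F)
            sig = passive_cauchy_stress(st_, FRAME, p)
            ref = fd_cauchy_stress(F, FRAME, p)
            scale = max(np.abs(ref).max(), 1e-6)
            assert np.abs(sig - ref).max() / scale < 1e-4
            checked += 1

    def test_matches_oracle_with_all_terms_active(self, rng):
        p = HOParameters(a_s=1.1, b_s=2.0, a_fs=0.7, b_fs=1.5)
        for _ in range(25):
            F = random_admissible_F(rng)
            sig = passive_cauchy_stress(DeformationState(F=F), FRAME, p)
            ref = fd_cauchy_stress(F, FRAME, p)
            assert np.abs(sig - ref).max() / max(np.abs(ref).max(), 1e-6) < 1e-4

    def test_symmetry(self, rng):
        p = HOParameters()
        F = random_admissible_F(rng)
        sig = passive_cauchy_stress(DeformationState(F=F), FRAME, p)
        assert np.allclose(sig, sig.T, atol=1e-10)

    def test_objectivity(self, rng):
        """sigma(R F) = R sigma(F) R^T for random rotations."""
        p = HOParameters()
        for seed in range(10):
            F = random_admissible_F(rng)
            R = Rotation.random(random_state=seed).as_matrix()
            a = passive_cauchy_stress(DeformationState(F=R @ F), FRAME, p)
            b = passive_cauchy_stress(DeformationState(F=F), FRAME, p)
            assert np.allclose(a, R @ b @ R.T, rtol=1e-9, atol=1e-9)

    def test_fiber_component(self, rng):
        """f . sigma . f along the deformed fibre: positive in uniaxial
        fibre tension and consistent with the tensor oracle."""
        p = HOParameters()
        lam = 1.1
        F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
        val = fiber_passive_stress(DeformationState(F=F), FRAME, p)
        assert val > 0
        ref = fd_cauchy_stress(F, FRAME, p)
        f = F @ FRAME.f0
        f = f / np.linalg.norm(f)
        assert val == pytest.approx(float(f @ ref @ f), rel=1e-4)
        assert fiber_passive_stress(DeformationState(F=np.eye(3)), FRAME, p) \
            == pytest.approx(0.0, abs=1e-12)


class TestFrameValidation:
    def test_rejects_non_orthogonal(self):
        with pytest.raises(ValueError):
            FiberFrame(f0=np.array([1.0, 0, 0]),
                       s0=np.array([1.0, 1.0, 0]) / np.sqrt(2) * 1.0 + 0)

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError):
            FiberFrame(f0=np.array([2.0, 0, 0]), s0=np.array([0, 1.0, 0]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HOParameters(a=-1.0)
        with pytest.raises(ValueError):
            HOParameters(D=0.0)
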