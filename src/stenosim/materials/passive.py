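"""Passive myocardium: Holzapfel–Ogden orthotropic hyperelasticity.

The passive response of ventricular muscle is modelled with the
Holzapfel–Ogden strain-energy density built from isochoric invariants of
the right Cauchy–Green tensor,

    Psi_dev = a/(2b) * exp[b(I1bar - 3)]
            + sum_{i=f,s} a_i/(2 b_i) * {exp[b_i (I4ibar - 1)^2] - 1}
            + a_fs/(2 b_fs) * {exp[b_fs I8fsbar^2] - 1}

with a nearly-incompressible volumetric penalty

    Psi_vol = (1/D) * ((J^2 - 1)/2 - ln J),   D = 2/K.

The fibre/sheet terms are tension-only: they contribute only when the
corresponding squared stretch invariant exceeds one (muscle fibres do not
support compression).  The Cauchy stress is the analytic push-forward
sigma = (2/J) F dPsi/dC F^T with the exact isochoric (deviatoric)
projection; a finite-difference oracle verifies it in the test suite.

Units: stresses and energy densities in kPa, D in 1/kPa, lengths
dimensionless (stretches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HOParameters",
    "FiberFrame",
    "DeformationState",
    "InvariantSet",
    "InvalidDeformationError",
    "isochoric_invariants",
    "deviatoric_energy",
    "volumetric_energy",
    "total_energy",
    "passive_cauchy_stress",
    "fiber_passive_stress",
]


class InvalidDeformationError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


@dataclass(frozen=True)
class HOParameters:
    """Constitutive constants of the Holzapfel–Ogden law.

    Defaults are the transversely-isotropic reduction used for the
    simulations: only the isotropic and fibre terms are active
    (``a_s = b_s = a_fs = b_fs = 0``).
    """

    a: float = 3.354      # kPa
    b: float = 7.08       # -
    a_f: float = 2.501    # kPa
    b_f: float = 5.34     # -
    a_s: float = 0.0      # kPa
    b_s: float = 0.0      # -
    a_fs: float = 0.0     # kPa
    b_fs: float = 0.0     # -
    D: float = 0.002      # 1/kPa, = 2/K with bulk modulus K = 1000 kPa

    def __post_init__(self) -> None:
        for name in ("a", "a_f", "a_s", "a_fs", "b", "b_f", "b_s", "b_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"HO parameter {name} must be >= 0")
        if self.D <= 0:
            raise ValueError("volumetric parameter D must be > 0")


@dataclass(frozen=True)
class FiberFrame:
    """Orthonormal material frame: fibre f0, sheet s0, normal n0 = f0 x s0."""

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        f0 = np.asarray(self.f0, dtype=float)
        s0 = np.asarray(self.s0, dtype=float)
        if not (np.isclose(np.linalg.norm(f0), 1.0, atol=1e-8)
                and np.isclose(np.linalg.norm(s0), 1.0, atol=1e-8)):
            raise ValueError("f0 and s0 must be unit vectors")
        if abs(float(f0 @ s0)) > 1e-8:
            raise ValueError("f0 and s0 must be orthogonal")
        object.__setattr__(self, "f0", f0)
        object.__setattr__(self, "s0", s0)
        n0 = np.cross(f0, s0) if self.n0 is None else np.asarray(self.n0, float)
        if not np.allclose(n0, np.cross(f0, s0), atol=1e-8):
            raise ValueError("frame must be right-handed: n0 = f0 x s0")
        object.__setattr__(self, "n0", n0)


@dataclass(frozen=True)
class DeformationState:
    """Deformation gradient F and its determinant J = det F (recomputed)."""

    F: np.ndarray

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise ValueError("F must be a 3x3 matrix")
        object.__setattr__(self, "F", F)
        if self.J <= 0:
            raise InvalidDeformationError(f"det(F) = {self.J} must be > 0")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))


@dataclass(frozen=True)
class InvariantSet:
    """Isochoric strain invariants (I1bar, I4f, I4s, I8fs)."""

    I1bar: float
    I4f: float
    I4s: float
    I8fs: float

    def __post_init__(self) -> None:
        if self.I4f <= 0 or self.I4s <= 0:
            raise ValueError("squared stretch invariants I4f, I4s must be > 0")


def isochoric_invariants(state: DeformationState, frame: FiberFrame) -> InvariantSet:
    """Invariants of Cbar = J^(-2/3) F^T F projected on the fibre frame."""
    F = state.F
    J = state.J
    Cbar = J ** (-2.0 / 3.0) * (F.T @ F)
    f0, s0 = frame.f0, frame.s0
    return InvariantSet(
        I1bar=float(np.trace(Cbar)),
        I4f=float(f0 @ Cbar @ f0),
        I4s=float(s0 @ Cbar @ s0),
        I8fs=float(f0 @ Cbar @ s0),
    )


def deviatoric_energy(inv: InvariantSet, p: HOParameters) -> float:
    """Deviatoric strain energy (kPa), measured relative to the reference
    state so that the undeformed configuration maps to zero.

    The anisotropic I4 terms are tension-only (contribute for I4 > 1)."""
    w = p.a / (2.0 * p.b) * (np.exp(p.b * (inv.I1bar - 3.0)) - 1.0)
    for a_i, b_i, I4 in ((p.a_f, p.b_f, inv.I4f), (p.a_s, p.b_s, inv.I4s)):
        if a_i > 0.0 and I4 > 1.0:
            e = (I4 - 1.0) ** 2
            if b_i > 0.0:
                w += a_i / (2.0 * b_i) * (np.exp(b_i * e) - 1.0)
            else:
                w += 0.5 * a_i * e
    if p.a_fs > 0.0:
        e = inv.I8fs ** 2
        if p.b_fs > 0.0:
            w += p.a_fs / (2.0 * p.b_fs) * (np.exp(p.b_fs * e) - 1.0)
        else:
            w += 0.5 * p.a_fs * e
    return float(w)


def volumetric_energy(J: float, D: float) -> float:
    """Volumetric penalty energy (kPa): (1/D)((J^2-1)/2 - ln J)."""
    if J <= 0:
        raise InvalidDeformationError(f"J = {J} must be > 0")
    if D <= 0:
        raise ValueError("D must be > 0")
    return float((1.0 / D) * (0.5 * (J * J - 1.0) - np.log(J)))


def total_energy(state: DeformationState, frame: FiberFrame, p: HOParameters) -> float:
    """Deviatoric + volumetric energy relative to the reference state."""
    inv = isochoric_invariants(state, frame)
    return deviatoric_energy(inv, p) + volumetric_energy(state.J, p.D)


def _psi1(I1bar: float, p: HOParameters) -> float:
    return 0.5 * p.a * np.exp(p.b * (I1bar - 3.0))


def _psi4(I4: float, a_i: float, b_i: float) -> float:
    # tension-only switch
    if a_i <= 0.0 or I4 <= 1.0:
        return 0.0
    return a_i * (I4 - 1.0) * np.exp(b_i * (I4 - 1.0) ** 2)


def _psi8(I8: float, p: HOParameters) -> float:
    if p.a_fs <= 0.0:
        return 0.0
    return p.a_fs * I8 * np.exp(p.b_fs * I8 ** 2)


def passive_cauchy_stress(
    state: DeformationState, frame: FiberFrame, p: HOParameters
) -> np.ndarray:
    """Analytic passive Cauchy stress tensor (kPa), symmetric 3x3.

    sigma = (2/J) F dPsi/dC F^T.  Each isochoric term pushes forward to a
    traceless contribution; the volumetric term contributes the pressure
    dPsi_vol/dJ = (1/D)(J - 1/J) times the identity.
    """
    F = state.F
    J = state.J
    inv = isochoric_invariants(state, frame)
    I = np.eye(3)

    Bbar = J ** (-2.0 / 3.0) * (F @ F.T)          # isochoric left CG tensor
    sig = (2.0 * _psi1(inv.I1bar, p) / J) * (Bbar - inv.I1bar / 3.0 * I)

    for vec, a_i, b_i, I4 in (
        (frame.f0, p.a_f, p.b_f, inv.I4f),
        (frame.s0, p.a_s, p.b_s, inv.I4s),
    ):
        psi = _psi4(I4, a_i, b_i)
        if psi != 0.0:
            v = J ** (-1.0 / 3.0) * (F @ vec)     # isochoric push-forward
            sig += (2.0 * psi / J) * (np.outer(v, v) - I4 / 3.0 * I)

    psi8 = _psi8(inv.I8fs, p)
    if psi8 != 0.0:
        vf = J ** (-1.0 / 3.0) * (F @ frame.f0)
        vs = J ** (-1.0 / 3.0) * (F @ frame.s0)
        sym = 0.5 * (np.outer(vf, vs) + np.outer(vs, vf))
        sig += (2.0 * psi8 / J) * (sym - inv.I8fs / 3.0 * I)

    p_vol = (1.0 / p.D) * (J - 1.0 / J)
    sig += p_vol * I
    return sig


def fiber_passive_stress(
    state: DeformationState, frame: FiberFrame, p: HOParameters
) -> float:
    """Fibre-direction component f . sigma . f of the passive Cauchy stress,
    with f the deformed, renormalised fibre direction F f0 / |F f0|."""
    sig = passive_cauchy_stress(state, frame, p)
    f = state.F @ frame.f0
    f = f / np.linalg.norm(f)
    return float(f @ sig @ f)
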