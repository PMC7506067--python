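"""Idealized left-ventricular chamber.

The ventricle is a truncated thick-walled prolate ellipsoid defined
directly in its unloaded (zero-stress) configuration.  The wall is a
stack of confocal-like shells obtained by linear interpolation between
the endocardial and epicardial ellipsoids, truncated by a fixed basal
plane.  Material points carry a rule-based fibre field (+60 deg at the
endocardium to -60 deg at the epicardium, measured from the
circumferential direction), a linearly varying unloaded sarcomere length
(1.78 um endo to 1.91 um epi) and an AHA-17 segment label.

Kinematics are axisymmetric and exactly incompressible: each shell
conserves its wall volume, the in-surface stretch is isotropic,
lambda = (V_enclosed / V_enclosed_ref)^(1/3), and the transmural stretch
is 1/lambda^2, so det F = 1 at every point.  Fibre Green strain is
Eff = (lambda_f^2 - 1)/2 with lambda_f = lambda (fibres lie in-surface).

The cavity pressure follows from radial equilibrium of the shell stack
(the layer-wise generalization of the one-fibre relation
P = (sigma/3) ln(1 + Vw/V)):

    P = sum_i  g_i / 3 * ln( (V + v_{i+1}) / (V + v_i) )

where v_i are cumulative wall volumes at shell boundaries and g_i is the
in-plane generating stress of shell i,

    g = 3 (sigma_p,ff + sigma_p,ss) + (1 + n_cross) * sigma_af .

The same integration yields the transmural hydrostatic (radial) stress
profile, sigma_rr from -P at the endocardium to 0 at the epicardium; the
reported myofiber stress is the fibre-direction Cauchy component
including that hydrostatic part.

Units: mm, mm^3, kPa, s, um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .materials.active import ActiveParameters, active_fiber_stress
from .materials.passive import HOParameters

__all__ = [
    "LVGeometryParams",
    "LVModel",
    "WallState",
    "truncated_ellipsoid_volume",
    "build_geometry",
    "aha_segment",
    "kinematics",
    "lv_pressure_and_stress",
    "cavity_pressure",
    "cavity_pressure_from_fiber_tension",
]

ENDO_FIBER_ANGLE = 60.0    # deg, at the endocardium
EPI_FIBER_ANGLE = -60.0    # deg, at the epicardium
LR_ENDO, LR_EPI = 1.78, 1.91  # um, unloaded sarcomere lengths


class GeometryError(ValueError):
    """Degenerate chamber geometry (non-positive thickness, bad truncation)."""


class InvalidVolumeError(ValueError):
    """Cavity volume outside the admissible range of the shell kinematics."""


def truncated_ellipsoid_volume(a: float, c: float, h: float) -> float:
    """Volume of an ellipsoid (semi-axes a, a, c) truncated at z = h.

    The apex sits at z = -c; the retained region is z in [-c, h].
    For h = c this is the full ellipsoid 4*pi*a^2*c/3; for h = 0
    (truncation at the equator) exactly half of it.
    """
    if not (-c < h <= c):
        raise GeometryError("truncation plane must satisfy -c < h <= c")
    return float(np.pi * a * a * (h - h ** 3 / (3.0 * c * c) + 2.0 * c / 3.0))


@dataclass(frozen=True)
class LVGeometryParams:
    """Unloaded geometry of the idealized LV.

    Defaults give an unloaded cavity of ~104 ml and a wall volume of
    ~172 ml (LV mass ~180 g); together with the diastolic-anchor
    stiffness scale this puts the passively loaded chamber at the
    136-138 ml end-diastolic volume near the ~4 mmHg diastolic LV
    pressure of the initialization targets.
    """

    a_endo: float = 24.0        # mm, endocardial short semi-axis
    c_endo: float = 60.0        # mm, endocardial long semi-axis
    wall_thickness: float = 13.0  # mm, lateral wall thickness
    apex_thickness: float = 10.0  # mm, apical wall thickness
    h_base: float = 18.0        # mm, truncation (base) plane height
    n_transmural: int = 12
    n_longitudinal: int = 16
    n_circumferential: int = 12
    apex_cap_fraction: float = 0.12  # long-axis fraction labelled segment 17

    def __post_init__(self) -> None:
        if min(self.a_endo, self.c_endo) <= 0:
            raise GeometryError("semi-axes must be positive")
        if self.wall_thickness <= 0 or self.apex_thickness <= 0:
            raise GeometryError("wall thickness must be positive")
        if not (-self.c_endo < self.h_base < self.c_endo):
            raise GeometryError("base plane must cut the endocardial ellipsoid")
        if (self.n_transmural < 2 or self.n_longitudinal < 8
                or self.n_circumferential < 8):
            raise GeometryError("discretization counts must be >= 2/8/8")

    def surfaces(self, d):
        """Semi-axes (a, c) of the shell at transmural depth d in [0, 1]."""
        d = np.asarray(d, dtype=float)
        return (self.a_endo + d * self.wall_thickness,
                self.c_endo + d * self.apex_thickness)

    def enclosed_volume(self, d):
        """Volume inside the shell surface at depth d (truncated)."""
        a, c = self.surfaces(d)
        h = self.h_base
        return np.pi * a * a * (h - h ** 3 / (3.0 * c * c) + 2.0 * c / 3.0)


@dataclass
class LVModel:
    """Discretized idealized ventricle (structure-of-arrays).

    Per-point arrays (length N): reference position, transmural depth,
    volume weight, fibre frame vectors f0/s0/n0, unloaded sarcomere
    length lr and AHA segment label.  Per-layer arrays (length
    n_transmural) drive the fast chamber solver.
    """

    params: LVGeometryParams
    seed: int
    position: np.ndarray          # (N, 3) mm
    depth: np.ndarray             # (N,) in [0, 1]
    weight: np.ndarray            # (N,) mm^3
    f0: np.ndarray                # (N, 3)
    s0: np.ndarray                # (N, 3)
    n0: np.ndarray                # (N, 3)
    lr: np.ndarray                # (N,) um
    segment: np.ndarray           # (N,) int in 1..17
    layer_index: np.ndarray       # (N,) int, transmural layer of each point
    vw_edges: np.ndarray          # (n_t+1,) cumulative wall volume at edges
    vw_mid: np.ndarray            # (n_t,) cumulative wall volume at centers
    lr_layer: np.ndarray          # (n_t,) um
    cavity_volume: float          # mm^3, unloaded V0
    wall_volume: float            # mm^3

    @property
    def n_points(self) -> int:
        return len(self.depth)

    @property
    def n_layers(self) -> int:
        return len(self.vw_mid)

    def as_dataframe(self) -> pd.DataFrame:
        """Column-oriented table of the material points."""
        df = pd.DataFrame({
            "x": self.position[:, 0], "y": self.position[:, 1],
            "z": self.position[:, 2],
            "depth": self.depth, "weight": self.weight,
            "f0x": self.f0[:, 0], "f0y": self.f0[:, 1], "f0z": self.f0[:, 2],
            "lr": self.lr, "segment": self.segment,
        })
        df.index.name = "point_id"
        return df


@dataclass
class WallState:
    """Snapshot of the wall: per-point deformation and stress at one
    (volume, time) pair, plus the cavity pressure it equilibrates."""

    volume: float                     # mm^3
    pressure: float                   # kPa
    F: np.ndarray                     # (N, 3, 3)
    Eff: np.ndarray                   # (N,) fibre Green strain
    sigma_f: np.ndarray               # (N,) kPa, total fibre Cauchy stress
    sigma_active: np.ndarray          # (N,) kPa, active part
    sigma_rr: np.ndarray              # (N,) kPa, radial (hydrostatic) part
    time: Optional[float] = None      # s within the cycle, None = passive


def aha_segment(position, params: LVGeometryParams):
    """AHA 17-segment label of reference position(s).

    Basal/mid/apical thirds by normalized long-axis height (6/6/4
    circumferential sectors) plus the apical cap (17).  Sector angles
    follow the standard convention with the anterior wall at 90 deg.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    z_apex = -(params.c_endo + params.apex_thickness)
    s = (pos[:, 2] - z_apex) / (params.h_base - z_apex)
    phi = np.degrees(np.arctan2(pos[:, 1], pos[:, 0])) % 360.0

    sector6 = (np.floor(((phi - 60.0) % 360.0) / 60.0)).astype(int)   # 0..5
    sector4 = (np.floor(((phi - 45.0) % 360.0) / 90.0)).astype(int)   # 0..3

    label = np.empty(len(pos), dtype=int)
    basal = s >= 2.0 / 3.0
    mid = (s >= 1.0 / 3.0) & ~basal
    cap = s < params.apex_cap_fraction
    apical = ~basal & ~mid & ~cap
    label[basal] = 1 + sector6[basal]
    label[mid] = 7 + sector6[mid]
    label[apical] = 13 + sector4[apical]
    label[cap] = 17
    if np.asarray(position).ndim == 1:
        return int(label[0])
    return label


def build_geometry(params: Optional[LVGeometryParams] = None, seed: int = 0) -> LVModel:
    """Generate the discretized unloaded ventricle.

    Deterministic for a given (params, seed); the seed only jitters the
    azimuthal offset of each point ring to decorrelate the lattice from
    the AHA sector boundaries.
    """
    if params is None:
        params = LVGeometryParams()
    rng = np.random.default_rng(seed)
    n_t, n_u, n_p = (params.n_transmural, params.n_longitudinal,
                     params.n_circumferential)

    d_edges = np.linspace(0.0, 1.0, n_t + 1)
    venc_edges = params.enclosed_volume(d_edges)
    vw_edges = venc_edges - venc_edges[0]
    layer_vol = np.diff(vw_edges)
    d_mid = 0.5 * (d_edges[:-1] + d_edges[1:])
    vw_mid = 0.5 * (vw_edges[:-1] + vw_edges[1:])

    positions, depths, weights = [], [], []
    f0s, s0s, n0s, lrs, layers = [], [], [], [], []

    for i, d in enumerate(d_mid):
        a, c = params.surfaces(d)
        u_base = params.h_base / c
        u_edges = np.linspace(-1.0 + 1e-6, u_base, n_u + 1)
        u_mid = 0.5 * (u_edges[:-1] + u_edges[1:])
        # surface area element dA = a * sqrt(a^2 u^2 + c^2 (1-u^2)) du dphi
        area = a * np.sqrt(a * a * u_mid ** 2 + c * c * (1.0 - u_mid ** 2))
        area_w = area * np.diff(u_edges)
        area_w = area_w / area_w.sum()

        angle = np.radians(ENDO_FIBER_ANGLE
                           + d * (EPI_FIBER_ANGLE - ENDO_FIBER_ANGLE))
        for j, u in enumerate(u_mid):
            offset = rng.uniform(0.0, 2.0 * np.pi / n_p)
            phis = offset + np.arange(n_p) * 2.0 * np.pi / n_p
            rho = np.sqrt(max(1.0 - u * u, 0.0))
            x = a * rho * np.cos(phis)
            y = a * rho * np.sin(phis)
            z = np.full(n_p, c * u)
            pts = np.column_stack([x, y, z])

            # local basis: e_r outward normal, e_c circumferential,
            # e_l = e_r x e_c meridional
            nvec = np.column_stack([x / a ** 2, y / a ** 2, z / c ** 2])
            e_r = nvec / np.linalg.norm(nvec, axis=1, keepdims=True)
            e_c = np.column_stack([-np.sin(phis), np.cos(phis),
                                   np.zeros(n_p)])
            e_l = np.cross(e_r, e_c)
            e_l /= np.linalg.norm(e_l, axis=1, keepdims=True)
            # re-orthogonalize e_c against e_r (exact on the surface)
            e_c = np.cross(e_l, e_r)

            f0 = np.cos(angle) * e_c + np.sin(angle) * e_l
            s0 = -np.sin(angle) * e_c + np.cos(angle) * e_l

            positions.append(pts)
            depths.append(np.full(n_p, d))
            weights.append(np.full(n_p, layer_vol[i] * area_w[j] / n_p))
            f0s.append(f0)
            s0s.append(s0)
            n0s.append(e_r)
            lrs.append(np.full(n_p, LR_ENDO + (LR_EPI - LR_ENDO) * d))
            layers.append(np.full(n_p, i, dtype=int))

    position = np.concatenate(positions)
    model = LVModel(
        params=params, seed=seed,
        position=position,
        depth=np.concatenate(depths),
        weight=np.concatenate(weights),
        f0=np.concatenate(f0s), s0=np.concatenate(s0s),
        n0=np.concatenate(n0s),
        lr=np.concatenate(lrs),
        segment=aha_segment(position, params),
        layer_index=np.concatenate(layers),
        vw_edges=vw_edges, vw_mid=vw_mid,
        lr_layer=LR_ENDO + (LR_EPI - LR_ENDO) * d_mid,
        cavity_volume=float(venc_edges[0]),
        wall_volume=float(vw_edges[-1]),
    )
    missing = set(range(1, 18)) - set(np.unique(model.segment))
    if missing:
        raise GeometryError(f"AHA segments {sorted(missing)} received no points; "
                            "increase the discretization counts")
    return model


def _layer_stretch(model: LVModel, V: float) -> np.ndarray:
    """In-surface stretch lambda per transmural layer at cavity volume V."""
    if V <= 0:
        raise InvalidVolumeError("cavity volume must be positive")
    venc_ref = model.cavity_volume + model.vw_mid
    return ((V + model.vw_mid) / venc_ref) ** (1.0 / 3.0)


def kinematics(model: LVModel, V: float) -> WallState:
    """Per-point deformation state for cavity volume V (no stresses).

    Each shell conserves its wall volume; F is assembled in the local
    surface frame as diag(lambda, lambda, lambda^-2), so det F = 1
    exactly at every point.
    """
    lam_layer = _layer_stretch(model, V)
    lam = lam_layer[model.layer_index]
    N = model.n_points
    # F = lam * I + (lam^-2 - lam) * e_r (x) e_r  in global coordinates
    F = lam[:, None, None] * np.eye(3)[None, :, :]
    er = model.n0
    F += (lam ** -2 - lam)[:, None, None] * er[:, :, None] * er[:, None, :]
    Eff = 0.5 * (lam ** 2 - 1.0)
    z = np.zeros(N)
    return WallState(volume=float(V), pressure=0.0, F=F, Eff=Eff,
                     sigma_f=z.copy(), sigma_active=z.copy(),
                     sigma_rr=z.copy(), time=None)


def _inplane_passive(lam: np.ndarray, p: HOParameters):
    """Passive Cauchy stress components for F = diag(lam, lam, lam^-2)
    in the local frame (J = 1), vectorized over layers.

    Returns (sigma_ff, sigma_ss, sigma_nn); the fibre lies in-surface so
    its stretch is lam regardless of the helix angle.
    """
    lam2 = lam ** 2
    I1 = 2.0 * lam2 + lam ** -4
    psi1 = 0.5 * p.a * np.exp(p.b * (I1 - 3.0))
    s_ff = 2.0 * psi1 * (lam2 - I1 / 3.0)
    s_nn = 2.0 * psi1 * (lam ** -4 - I1 / 3.0)
    s_ss = s_ff.copy()

    I4 = lam2  # fibre and sheet both in-surface
    tens = I4 > 1.0
    if np.any(tens):
        e = I4 - 1.0
        psi4f = np.where(tens, p.a_f * e * np.exp(p.b_f * e ** 2), 0.0)
        psi4s = np.where(tens, p.a_s * e * np.exp(p.b_s * e ** 2), 0.0)
        s_ff = s_ff + 2.0 * psi4f * I4 * (2.0 / 3.0) - 2.0 * psi4s * I4 / 3.0
        s_ss = s_ss + 2.0 * psi4s * I4 * (2.0 / 3.0) - 2.0 * psi4f * I4 / 3.0
        s_nn = s_nn - 2.0 * (psi4f + psi4s) * I4 / 3.0
    return s_ff, s_ss, s_nn


def cavity_pressure_from_fiber_tension(tension, V: float, vw_edges) -> float:
    """Layer-wise one-fibre force balance.

    P = sum_i T_i/3 * ln((V + v_{i+1}) / (V + v_i)); exact for
    piecewise-constant tension, reducing to P = (T/3) ln(1 + Vw/V) for a
    uniform profile.
    """
    tension = np.asarray(tension, dtype=float)
    vw_edges = np.asarray(vw_edges, dtype=float)
    if V <= 0:
        raise InvalidVolumeError("cavity volume must be positive")
    log_terms = np.log((V + vw_edges[1:]) / (V + vw_edges[:-1]))
    return float(np.sum(tension * log_terms) / 3.0)


def _layer_generating_stress(model: LVModel, V: float, t: Optional[float],
                             passive: HOParameters, active: ActiveParameters,
                             off_mask: Optional[np.ndarray] = None):
    """Per-layer in-plane generating stress g, active stress and passive
    components at (V, t).  t=None means fully passive; ``off_mask`` marks
    layers whose relaxation has completed this cycle (tension latched to
    zero so that late-diastolic refilling cannot rewind the phase)."""
    lam = _layer_stretch(model, V)
    Eff = 0.5 * (lam ** 2 - 1.0)
    s_ff, s_ss, s_nn = _inplane_passive(lam, passive)
    if t is None:
        sig_a = np.zeros_like(lam)
    else:
        sig_a = np.asarray(
            active_fiber_stress(t, Eff, model.lr_layer, active), dtype=float
        )
        if off_mask is not None:
            sig_a = np.where(off_mask, 0.0, sig_a)
    g = 3.0 * (s_ff + s_ss) + (1.0 + active.n_cross) * sig_a
    return g, sig_a, s_ff, s_ss, s_nn, Eff, lam


def cavity_pressure(model: LVModel, V: float, t: Optional[float],
                    passive: HOParameters, active: ActiveParameters,
                    off_mask: Optional[np.ndarray] = None) -> float:
    """Cavity pressure (kPa) at volume V and cycle time t (None = passive)."""
    g, *_ = _layer_generating_stress(model, V, t, passive, active, off_mask)
    return cavity_pressure_from_fiber_tension(g, V, model.vw_edges)


def lv_pressure_and_stress(model: LVModel, V: float, t: Optional[float],
                           passive: HOParameters, active: ActiveParameters,
                           off_mask: Optional[np.ndarray] = None) -> WallState:
    """Full wall state: per-point deformation, total fibre Cauchy stress
    (including the equilibrium hydrostatic profile) and cavity pressure."""
    g, sig_a, s_ff, s_ss, s_nn, Eff_l, lam = _layer_generating_stress(
        model, V, t, passive, active, off_mask)
    edges = model.vw_edges
    log_full = np.log((V + edges[1:]) / (V + edges[:-1]))
    P = float(np.sum(g * log_full) / 3.0)

    # radial stress at layer midpoints: integrate from the endocardium
    log_half = np.log((V + model.vw_mid) / (V + edges[:-1]))
    cum_before = np.concatenate([[0.0], np.cumsum(g * log_full)[:-1]])
    sigma_rr_l = -P + (cum_before + g * log_half) / 3.0

    # total fibre component: sigma_ff = s_ff + sigma_af + q, with the
    # hydrostatic q fixed by the radial equilibrium profile
    sigma_f_l = s_ff + sig_a + (sigma_rr_l - s_nn)

    state = kinematics(model, V)
    idx = model.layer_index
    state.pressure = P
    state.time = t
    state.sigma_f = sigma_f_l[idx]
    state.sigma_active = sig_a[idx]
    state.sigma_rr = sigma_rr_l[idx]
    return state


def passive_volume_at_pressure(model: LVModel, P_kpa: float,
                               passive: HOParameters,
                               active: ActiveParameters) -> float:
    """Invert the passive pressure-volume curve (used by the ramp)."""
    from scipy.optimize import brentq

    if P_kpa <= 0.0:
        return model.cavity_volume
    f = lambda V: cavity_pressure(model, V, None, passive, active) - P_kpa
    lo, hi = model.cavity_volume, model.cavity_volume * 3.0
    while f(hi) < 0.0 and hi < model.cavity_volume * 10.0:
        hi *= 1.5
    return float(brentq(f, lo, hi, xtol=1e-6))
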