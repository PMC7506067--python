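"""Active myocardium: time-varying elastance contraction law.

Developed fibre tension follows a prescribed time course scaled by a
length-dependent calcium sensitivity (the classic Guccione-style
elastance law):

    sigma_af(t, Eff) = Tmax/2 * Ca0^2 / (Ca0^2 + ECa50(l)^2) * (1 - cos w(t, l))

    ECa50(l) = Ca0max / sqrt(exp(B (l - l0)) - 1)        (l > l0)
    l(Eff)   = lr * sqrt(2 Eff + 1)                      (sarcomere length)
    w        = pi t / t0                      0 <= t < t0
             = pi (t - t0 + tr) / tr          t0 <= t <= t0 + tr
             = 0                              t > t0 + tr
    tr(l)    = m l + b_relax                  (relaxation duration)

For sarcomere lengths at or below the zero-tension length ``l0`` the
active stress is clamped to zero (the continuous limit ECa50 -> inf).
Cross-fibre coupling: a fraction ``n_cross`` of the fibre tension also
acts in the sheet direction, sigma_s = sigma_ps + n_cross * sigma_af.

All functions accept scalars or numpy arrays (broadcasting) so the
chamber solver can evaluate whole transmural profiles at once.

Units: kPa, seconds, micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActiveParameters",
    "SarcomereState",
    "InvalidStrainError",
    "sarcomere_length",
    "eca50",
    "relaxation_duration",
    "activation_phase",
    "active_fiber_stress",
    "total_sheet_stress",
]


class InvalidStrainError(ValueError):
    """Fibre Green strain must satisfy 2 Eff + 1 > 0."""


@dataclass(frozen=True)
class ActiveParameters:
    Tmax: float = 135.7       # kPa, maximum active tension
    Ca0: float = 4.35         # umol/l, peak intracellular calcium
    Ca0max: float = 4.35      # umol/l, maximum peak calcium
    B: float = 4.750          # 1/um, length-sensitivity exponent
    l0: float = 1.58          # um, zero-active-tension sarcomere length
    m: float = 1.0489         # s/um, slope of relaxation duration vs length
    b_relax: float = -1.429   # s, intercept of relaxation duration
    t0: float = 0.15          # s, time to peak tension (calibrated)
    n_cross: float = 0.4      # -, cross-fibre (sheet) fraction of tension

    def __post_init__(self) -> None:
        if self.Tmax <= 0:
            raise ValueError("Tmax must be > 0")
        if self.l0 <= 0:
            raise ValueError("l0 must be > 0")
        if not 0.0 <= self.n_cross <= 1.0:
            raise ValueError("n_cross must lie in [0, 1]")
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")


@dataclass(frozen=True)
class SarcomereState:
    """Local sarcomere kinematics: unloaded length lr (um, 1.78 at the
    endocardium to 1.91 at the epicardium), fibre Green strain Eff and
    the resulting current length l."""

    lr: float
    Eff: float

    @property
    def l(self) -> float:
        return sarcomere_length(self.Eff, self.lr)


def sarcomere_length(Eff, lr):
    """Current sarcomere length l = lr * sqrt(2 Eff + 1)."""
    Eff = np.asarray(Eff, dtype=float)
    arg = 2.0 * Eff + 1.0
    if np.any(arg <= 0.0):
        raise InvalidStrainError("fibre strain must satisfy Eff > -0.5")
    out = np.asarray(lr, dtype=float) * np.sqrt(arg)
    return out if out.ndim else float(out)


def eca50(l, p: ActiveParameters):
    """Length-dependent calcium sensitivity ECa50 (umol/l).

    Returns +inf for l <= l0; downstream active stress is then zero."""
    l = np.asarray(l, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        denom = np.expm1(p.B * (l - p.l0))
        out = np.where(denom > 0.0, p.Ca0max / np.sqrt(np.abs(denom) + 1e-300), np.inf)
    return out if out.ndim else float(out)


def relaxation_duration(l, p: ActiveParameters):
    """tr(l) = m l + b_relax (s); must be positive for valid configurations."""
    tr = p.m * np.asarray(l, dtype=float) + p.b_relax
    if np.any(tr <= 0.0):
        raise ValueError(
            "relaxation duration tr = m*l + b_relax must be positive; "
            "sarcomere length too short for the configured timing"
        )
    return tr if tr.ndim else float(tr)


def activation_phase(t, l, p: ActiveParameters):
    """Contraction phase angle w(t, l) in radians.

    Rises linearly to pi at t0 (peak tension), returns to 2*pi at
    t0 + tr(l) and is identically zero afterwards (no tension)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be >= 0")
    tr = np.asarray(relaxation_duration(l, p))
    rise = np.pi * t / p.t0
    fall = np.pi * (t - p.t0 + tr) / tr
    w = np.where(t < p.t0, rise, np.where(t <= p.t0 + tr, fall, 0.0))
    return w if w.ndim else float(w)


def active_fiber_stress(t, Eff, lr, p: ActiveParameters):
    """Active fibre tension sigma_af(t, Eff) in kPa; 0 <= sigma_af <= Tmax."""
    l = np.asarray(sarcomere_length(Eff, lr))
    # Below the zero-tension length the stress is clamped to zero, so the
    # phase is evaluated at l0 there merely to keep tr(l) > 0 well defined.
    w = np.asarray(activation_phase(t, np.maximum(l, p.l0), p))
    e = np.asarray(eca50(l, p))
    with np.errstate(invalid="ignore"):
        ca_frac = np.where(
            np.isfinite(e), p.Ca0 ** 2 / (p.Ca0 ** 2 + e ** 2), 0.0
        )
    sig = 0.5 * p.Tmax * ca_frac * (1.0 - np.cos(w))
    return sig if sig.ndim else float(sig)


def total_sheet_stress(sigma_ps, sigma_af, n_cross: float = 0.4):
    """Total scalar sheet-direction stress sigma_s = sigma_ps + n * sigma_af."""
    out = np.asarray(sigma_ps, dtype=float) + n_cross * np.asarray(sigma_af, dtype=float)
    return out if out.ndim else float(out)
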