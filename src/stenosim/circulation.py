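"""Closed-loop lumped-parameter circulation.

Network (systemic + pulmonary) with diode-resistor valves and linear
compliances, coupled to the LV chamber:

    LA -[R_mitral]-> LV -[R_aorta]-> ART -[R_system]-> VEN
    VEN -[R_venous]-> RA -[R_tricuspid]-> RV -[R_pulmonary]-> PUL
    PUL -[R_pulmonary_system]-> LA

ART (aorta/systemic arterial), VEN and PUL are linear compliances; LA,
RA and RV are simple time-varying elastance chambers; the LV pressure is
supplied by the chamber model (any object exposing ``pressure(V, t)`` in
MPa, or a plain callable).  Valves are ideal diodes in series with a
linear resistance, Q = max(dP, 0)/R.

Integration is fixed-step and deterministic.  Flows between linear
compartments use a semi-implicit update that is unconditionally stable;
the two LV valve flows are refined each step by a scalar Newton solve so
that the recorded end-of-step pressures satisfy dP = R*Q across an open
valve essentially exactly.  Every flow is applied antisymmetrically to
its two compartments, so total blood volume is conserved to round-off.

The first cycle is preceded by a pressure ramp: every compartment is
ramped linearly from zero to the physiologic target pressures, reaching
them at 70% of the diastolic duration (diastole taken as the zero-
active-tension interval, cycle length minus the minimum mechanical
systole t0 + tr(l0)).

Units: MPa, mm^3, s.  1 mmHg = 133.322e-6 MPa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MMHG = 133.322e-6  # MPa per mmHg
MMHG_PER_ML = MMHG / 1000.0  # MPa/mm^3 per mmHg/ml

COMPARTMENTS = ("lv", "art", "ven", "ra", "rv", "pul", "la")
FLOWS = ("mitral", "aortic", "systemic", "venous",
         "tricuspid", "pulmonary_valve", "pulmonary_system")

# scenario aortic valve resistances, MPa*s/mm^3
R_AORTA_BASELINE = 1.0e-9
R_AORTA_MODERATE = 5.0e-9
R_AORTA_SEVERE = 1.0e-8


class IntegrationError(RuntimeError):
    """Time integration failed to converge."""


@dataclass(frozen=True)
class ElastanceParams:
    """Linear time-varying elastance chamber P = E(t) (V - V0)."""

    e_min: float              # MPa/mm^3
    e_max: float              # MPa/mm^3
    v0: float                 # mm^3, unstressed volume
    t_on: float               # s, activation onset within the cycle
    duration: float           # s, activation duration

    def elastance(self, t_cycle: float, cycle_length: float) -> float:
        tt = (t_cycle - self.t_on) % cycle_length
        if tt < self.duration:
            act = math.sin(math.pi * tt / self.duration) ** 2
        else:
            act = 0.0
        return self.e_min + (self.e_max - self.e_min) * act


@dataclass(frozen=True)
class CircuitParameters:
    """Resistances (MPa*s/mm^3), compliances (mm^3/MPa), unstressed
    volumes (mm^3) and elastance stand-ins for LA/RA/RV.

    The three aortic valve resistances are the values used to grade
    stenosis (1.0e-9 baseline, 5.0e-9 moderate, 1.0e-8 severe); the
    remaining values are physiologic defaults refined by calibration.
    """

    R_mitral: float = 6.0e-10
    R_aorta: float = R_AORTA_BASELINE
    R_system: float = 8.1e-8
    R_venous: float = 2.3e-9
    R_tricuspid: float = 5.0e-10
    R_pulmonary: float = 1.0e-9
    R_pulmonary_system: float = 8.0e-9

    C_arterial: float = 7.1e6
    C_venous: float = 7.5e8
    C_pulmonary: float = 3.0e7

    V0_arterial: float = 5.0e5
    V0_venous: float = 2.5e6
    V0_pulmonary: float = 1.0e4

    la: ElastanceParams = field(default_factory=lambda: ElastanceParams(
        e_min=0.03 * MMHG_PER_ML, e_max=0.09 * MMHG_PER_ML, v0=1.0e4,
        t_on=0.55, duration=0.12))
    ra: ElastanceParams = field(default_factory=lambda: ElastanceParams(
        e_min=0.04 * MMHG_PER_ML, e_max=0.08 * MMHG_PER_ML, v0=1.0e4,
        t_on=0.55, duration=0.12))
    rv: ElastanceParams = field(default_factory=lambda: ElastanceParams(
        e_min=0.02 * MMHG_PER_ML, e_max=1.0 * MMHG_PER_ML, v0=1.0e4,
        t_on=0.0, duration=0.40))

    cycle_length: float = 0.7     # s
    dt: float = 5.0e-4            # s
    blood_volume_delta: float = 0.0  # mm^3 added to the venous pool (calibrated)

    # initialization ramp targets, mmHg (aorta and systemic arterial
    # chamber share the single ART node)
    ramp_targets_mmhg: Dict[str, float] = field(default_factory=lambda: {
        "ra": 2.0, "rv": 2.0, "pul": 8.0, "la": 4.0, "lv": 4.0,
        "art": 80.0, "ven": 2.0})

    def __post_init__(self) -> None:
        for name in ("R_mitral", "R_aorta", "R_system", "R_venous",
                     "R_tricuspid", "R_pulmonary", "R_pulmonary_system"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("C_arterial", "C_venous", "C_pulmonary"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.dt <= 0 or self.dt > 1e-3:
            raise ValueError("dt must satisfy 0 < dt <= 1e-3 s")


@dataclass
class CircuitState:
    """Pressures (MPa), volumes (mm^3) and valve flows (mm^3/s) at one instant."""

    time: float
    pressures: Dict[str, float]
    volumes: Dict[str, float]
    flows: Dict[str, float]

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))


@dataclass
class CycleRecord:
    """Uniformly sampled time series for one cardiac cycle."""

    cycle: int
    t: np.ndarray                       # s, time within the cycle
    pressures: Dict[str, np.ndarray]    # MPa
    volumes: Dict[str, np.ndarray]      # mm^3
    flows: Dict[str, np.ndarray]        # mm^3/s

    def as_dataframe(self) -> pd.DataFrame:
        data = {"t": self.t}
        data.update({f"P_{k}": v for k, v in self.pressures.items()})
        data.update({f"V_{k}": v for k, v in self.volumes.items()})
        data.update({f"Q_{k}": v for k, v in self.flows.items()})
        return pd.DataFrame(data)

    def peak_pressures(self) -> Dict[str, float]:
        return {k: float(np.max(v)) for k, v in self.pressures.items()}


def valve_flow(p_up: float, p_down: float, R: float) -> float:
    """Ideal diode + linear resistance: Q = max(p_up - p_down, 0)/R."""
    if R <= 0:
        raise ValueError("valve resistance must be > 0")
    dp = p_up - p_down
    return dp / R if dp > 0.0 else 0.0


class _CallableLV:
    """Adapter giving a plain P(V, t) callable the chamber interface."""

    def __init__(self, fn: Callable[[float, Optional[float]], float]):
        self._fn = fn

    def pressure(self, V: float, t: Optional[float]) -> float:
        return self._fn(V, t)

    def dPdV(self, V: float, t: Optional[float], delta: float = 10.0) -> float:
        return (self._fn(V + delta, t) - self._fn(V - delta, t)) / (2 * delta)

    def end_step(self, V: float, t: float) -> None:
        pass

    def reset_cycle(self) -> None:
        pass

    def passive_volume(self, P: float) -> float:
        from scipy.optimize import brentq
        f = lambda V: self._fn(V, None) - P
        lo, hi = 1.0, 1.0e6
        return float(brentq(f, lo, hi, xtol=1e-6))


def _as_chamber(lv_pressure_fn):
    if callable(lv_pressure_fn) and not hasattr(lv_pressure_fn, "pressure"):
        return _CallableLV(lv_pressure_fn)
    return lv_pressure_fn


class CirculationSimulator:
    """Fixed-step integrator for the closed loop."""

    def __init__(self, params: CircuitParameters, lv_pressure_fn):
        self.params = params
        self.lv = _as_chamber(lv_pressure_fn)
        self.volumes: Dict[str, float] = {}

    # -- pressures ---------------------------------------------------------

    def _pressures(self, vols: Dict[str, float], t_cycle: Optional[float]
                   ) -> Dict[str, float]:
        p = self.params
        T = p.cycle_length
        tc = 0.0 if t_cycle is None else t_cycle
        return {
            "lv": self.lv.pressure(vols["lv"], t_cycle),
            "art": (vols["art"] - p.V0_arterial) / p.C_arterial,
            "ven": (vols["ven"] - p.V0_venous) / p.C_venous,
            "ra": p.ra.elastance(tc, T) * (vols["ra"] - p.ra.v0),
            "rv": p.rv.elastance(tc, T) * (vols["rv"] - p.rv.v0),
            "pul": (vols["pul"] - p.V0_pulmonary) / p.C_pulmonary,
            "la": p.la.elastance(tc, T) * (vols["la"] - p.la.v0),
        }

    # -- initialization ramp ----------------------------------------------

    def diastole_duration(self, t0: float, tr_min: float) -> float:
        """Zero-active-tension interval: cycle length minus the minimum
        mechanical systole t0 + tr(l0)."""
        return max(self.params.cycle_length - (t0 + tr_min),
                   0.05 * self.params.cycle_length)

    def initialize_ramp(self, t0: float = 0.15, tr_min: float = 0.2283,
                        n_steps: int = 50) -> List[CircuitState]:
        """Linear pressure ramp from zero reaching the physiologic targets
        at 70% of the diastolic duration; returns the ramp trace, leaving
        the simulator's volumes at the ramp endpoint."""
        p = self.params
        D = self.diastole_duration(t0, tr_min)
        t_ramp = 0.7 * D
        targets = {k: v * MMHG for k, v in p.ramp_targets_mmhg.items()}
        trace: List[CircuitState] = []
        for i in range(n_steps + 1):
            frac = min((i / n_steps) * D / t_ramp, 1.0) if t_ramp > 0 else 1.0
            pr = {k: frac * v for k, v in targets.items()}
            T = p.cycle_length
            vols = {
                "lv": self.lv.passive_volume(pr["lv"]),
                "art": p.V0_arterial + p.C_arterial * pr["art"],
                "ven": p.V0_venous + p.C_venous * pr["ven"],
                "ra": p.ra.v0 + pr["ra"] / p.ra.elastance(0.99 * T, T),
                "rv": p.rv.v0 + pr["rv"] / p.rv.elastance(0.99 * T, T),
                "pul": p.V0_pulmonary + p.C_pulmonary * pr["pul"],
                "la": p.la.v0 + pr["la"] / p.la.elastance(0.99 * T, T),
            }
            trace.append(CircuitState(
                time=(i / n_steps) * D, pressures=pr, volumes=vols,
                flows={k: 0.0 for k in FLOWS}))
        self.volumes = dict(trace[-1].volumes)
        self.volumes["ven"] += p.blood_volume_delta
        return trace

    # -- stepping ----------------------------------------------------------

    def _refine_valve(self, which: str, q0: float, vols, lv_slope: float,
                      q_other: float, q_out: float, dt: float,
                      t1: float) -> float:
        """Newton solve for an LV valve flow so end-of-step pressures obey
        dP = R*Q exactly.  ``which`` is 'aortic' or 'mitral'."""
        p = self.params
        if which == "aortic":
            R = p.R_aorta

            def residual(q):
                v_lv = vols["lv"] + dt * (q_other - q)
                p_lv = self.lv.pressure(v_lv, t1)
                p_art = ((vols["art"] + dt * (q - q_out) - p.V0_arterial)
                         / p.C_arterial)
                return p_lv - p_art - R * q
        else:
            R = p.R_mitral
            T = p.cycle_length
            e_la = p.la.elastance(t1 % T, T)

            def residual(q):
                v_lv = vols["lv"] + dt * (q - q_other)
                p_lv = self.lv.pressure(v_lv, t1)
                p_la = e_la * (vols["la"] + dt * (q_out - q) - p.la.v0)
                return p_la - p_lv - R * q

        r = residual(q0)
        slope = -(dt * lv_slope
                  + dt * (1.0 / p.C_arterial if which == "aortic"
                          else p.la.elastance(t1 % p.cycle_length,
                                              p.cycle_length))
                  + R)
        q = q0
        for _ in range(60):
            if abs(r) < 1e-12:
                break
            step = -r / slope
            q_new = q + step
            r_new = residual(q_new)
            if abs(q_new - q) > 1e-30 and r_new != r:
                slope = (r_new - r) / (q_new - q)  # secant refresh
            q, r = q_new, r_new
        else:
            raise IntegrationError(
                f"{which} valve flow solve did not converge (residual {r:.3e})")
        return max(q, 0.0)

    def step(self, t_cycle: float) -> CircuitState:
        """Advance one time step from t_cycle to t_cycle + dt."""
        p = self.params
        dt = p.dt
        T = p.cycle_length
        t1 = t_cycle + dt
        vols = self.volumes
        pres = self._pressures(vols, min(t1, T))

        e_ra = p.ra.elastance(t1 % T, T)
        e_rv = p.rv.elastance(t1 % T, T)
        e_la = p.la.elastance(t1 % T, T)
        lv_slope = abs(self.lv.dPdV(vols["lv"], min(t1, T)))
        caps = {
            "art": p.C_arterial, "ven": p.C_venous, "pul": p.C_pulmonary,
            "ra": 1.0 / max(e_ra, 1e-16), "rv": 1.0 / max(e_rv, 1e-16),
            "la": 1.0 / max(e_la, 1e-16),
            "lv": 1.0 / max(lv_slope, 1e-16),
        }

        def semi_implicit(p_up, p_down, R, c_up, c_down, diode):
            dp = p_up - p_down
            if diode and dp <= 0.0:
                return 0.0
            return dp / (R + dt * (1.0 / c_up + 1.0 / c_down))

        q = {
            "systemic": semi_implicit(pres["art"], pres["ven"], p.R_system,
                                      caps["art"], caps["ven"], False),
            "venous": semi_implicit(pres["ven"], pres["ra"], p.R_venous,
                                    caps["ven"], caps["ra"], False),
            "tricuspid": semi_implicit(pres["ra"], pres["rv"], p.R_tricuspid,
                                       caps["ra"], caps["rv"], True),
            "pulmonary_valve": semi_implicit(pres["rv"], pres["pul"],
                                             p.R_pulmonary, caps["rv"],
                                             caps["pul"], True),
            "pulmonary_system": semi_implicit(pres["pul"], pres["la"],
                                              p.R_pulmonary_system,
                                              caps["pul"], caps["la"], False),
            "mitral": semi_implicit(pres["la"], pres["lv"], p.R_mitral,
                                    caps["la"], caps["lv"], True),
            "aortic": semi_implicit(pres["lv"], pres["art"], p.R_aorta,
                                    caps["lv"], caps["art"], True),
        }

        # Newton refinement of the LV valve flows (exact diode law on the
        # recorded end-of-step pressures)
        # attempt the implicit solve within a small reverse-bias margin:
        # compartment pressures move within the step (arterial run-off,
        # tension decay), so a valve may need to open even when the
        # start-of-step difference is slightly negative
        margin = 1.0e-4  # MPa
        t1c = min(t1, T)
        if q["aortic"] > 0.0 or pres["lv"] > pres["art"] - margin:
            q["aortic"] = self._refine_valve(
                "aortic", q["aortic"], vols, lv_slope,
                q_other=q["mitral"], q_out=q["systemic"], dt=dt, t1=t1c)
        if q["mitral"] > 0.0 or pres["la"] > pres["lv"] - margin:
            q["mitral"] = self._refine_valve(
                "mitral", q["mitral"], vols, lv_slope,
                q_other=q["aortic"], q_out=q["pulmonary_system"], dt=dt, t1=t1c)
            if q["mitral"] > 0.0 and q["aortic"] > 0.0:
                q["aortic"] = self._refine_valve(
                    "aortic", q["aortic"], vols, lv_slope,
                    q_other=q["mitral"], q_out=q["systemic"], dt=dt, t1=t1c)

        # antisymmetric volume update: exact conservation
        vols["lv"] += dt * (q["mitral"] - q["aortic"])
        vols["art"] += dt * (q["aortic"] - q["systemic"])
        vols["ven"] += dt * (q["systemic"] - q["venous"])
        vols["ra"] += dt * (q["venous"] - q["tricuspid"])
        vols["rv"] += dt * (q["tricuspid"] - q["pulmonary_valve"])
        vols["pul"] += dt * (q["pulmonary_valve"] - q["pulmonary_system"])
        vols["la"] += dt * (q["pulmonary_system"] - q["mitral"])

        if min(vols.values()) < 0.0:
            raise IntegrationError("negative compartment volume; reduce dt")

        new_pres = self._pressures(vols, t1c)
        self.lv.end_step(vols["lv"], t1c)
        return CircuitState(time=t1, pressures=new_pres, volumes=dict(vols),
                            flows=dict(q))

    def run_cycle(self, cycle_index: int) -> CycleRecord:
        """Integrate one full cardiac cycle, recording every step."""
        p = self.params
        n = int(round(p.cycle_length / p.dt))
        self.lv.reset_cycle()
        times = np.empty(n)
        P = {k: np.empty(n) for k in COMPARTMENTS}
        V = {k: np.empty(n) for k in COMPARTMENTS}
        Q = {k: np.empty(n) for k in FLOWS}
        for i in range(n):
            st = self.step(i * p.dt)
            times[i] = st.time
            for k in COMPARTMENTS:
                P[k][i] = st.pressures[k]
                V[k][i] = st.volumes[k]
            for k in FLOWS:
                Q[k][i] = st.flows[k]
        return CycleRecord(cycle=cycle_index, t=times, pressures=P,
                           volumes=V, flows=Q)


def run_to_steady_state(params: CircuitParameters, lv_pressure_fn,
                        n_cycles: int = 3, t0: float = 0.15,
                        tr_min: float = 0.2283,
                        max_extra_cycles: int = 0) -> List[CycleRecord]:
    """Ramp-initialize and integrate ``n_cycles`` consecutive cycles.

    Steady state is assessed from the per-compartment peak-pressure
    relative change between the last two cycles; a change above 5%
    raises a warning (not an error)."""
    sim = CirculationSimulator(params, lv_pressure_fn)
    sim.initialize_ramp(t0=t0, tr_min=tr_min)
    records = [sim.run_cycle(i + 1) for i in range(max(n_cycles, 2))]
    for _ in range(max_extra_cycles):
        change = _peak_pressure_change(records[-2], records[-1])
        if change < 0.05:
            break
        records.append(sim.run_cycle(len(records) + 1))
    change = _peak_pressure_change(records[-2], records[-1])
    if change >= 0.05:
        logger.warning("steady state not reached: peak-pressure change "
                       "%.1f%% between last two cycles", 100 * change)
    return records


def _peak_pressure_change(prev: CycleRecord, last: CycleRecord) -> float:
    """Maximum relative change in any compartment's peak pressure."""
    pa, pb = prev.peak_pressures(), last.peak_pressures()
    return max(abs(pb[k] - pa[k]) / max(abs(pa[k]), 1e-12) for k in pa)
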