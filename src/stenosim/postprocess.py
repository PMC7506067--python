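"""Reported metrics: transvalvular gradient, PV-loop quantities, global
and AHA-17-segment myofiber stress/strain statistics (volume-weighted
mean +/- SD), Welch t-tests between scenarios, and tabular/figure output.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .chamber import WallState
from .circulation import MMHG, CycleRecord
from .simulation import (ScenarioResult, cycle_metrics, find_end_diastole,
                         find_peak_systole)

logger = logging.getLogger(__name__)

__all__ = [
    "mean_systolic_gradient",
    "pv_metrics",
    "field_statistics",
    "welch_t_test",
    "stress_frames",
    "scenario_summary",
    "report",
]


def mean_systolic_gradient(lv_p: np.ndarray, ao_p: np.ndarray) -> float:
    """Mean systolic LV-aorta gradient (same units as the inputs).

    The difference is averaged over the timesteps where LV pressure
    exceeds aortic pressure; if it never does, returns 0 with a warning.
    """
    lv_p = np.asarray(lv_p, dtype=float)
    ao_p = np.asarray(ao_p, dtype=float)
    if lv_p.shape != ao_p.shape or lv_p.ndim != 1:
        raise ValueError("LV and aortic traces must be equal-length 1-D arrays")
    mask = lv_p > ao_p
    if not np.any(mask):
        warnings.warn("LV pressure never exceeds aortic pressure; gradient 0")
        return 0.0
    return float(np.mean(lv_p[mask] - ao_p[mask]))


def pv_metrics(record: CycleRecord) -> Dict[str, float]:
    """PV-loop metrics of one cycle: EDV/ESV/SV (ml), EF (%), stroke work.

    Stroke work is the signed loop area -closed-integral P dV, positive
    for an ejecting loop; reported in mmHg*ml and joules.
    """
    v = np.asarray(record.volumes["lv"], dtype=float)
    p = np.asarray(record.pressures["lv"], dtype=float)
    if len(v) < 8:
        raise ValueError("record too short to form a cycle")
    edv, esv = float(np.max(v)), float(np.min(v))
    if abs(v[-1] - v[0]) > 0.25 * max(edv - esv, 1.0):
        raise ValueError("record is not cyclic: LV volume does not return "
                         "to its starting value")
    # shoelace around the closed loop
    v_next = np.roll(v, -1)
    p_mid = 0.5 * (p + np.roll(p, -1))
    work_mpa_mm3 = -float(np.sum(p_mid * (v_next - v)))
    return {
        "edv_ml": edv / 1e3,
        "esv_ml": esv / 1e3,
        "sv_ml": (edv - esv) / 1e3,
        "ef_pct": 100.0 * (edv - esv) / edv,
        "stroke_work_mmhg_ml": work_mpa_mm3 / MMHG / 1e3,
        "stroke_work_j": work_mpa_mm3 * 1e-3,  # MPa*mm^3 = mJ
    }


def field_statistics(values: np.ndarray, weights: np.ndarray,
                     segments: Optional[np.ndarray] = None
                     ) -> Dict[str, object]:
    """Volume-weighted mean and population SD of a per-point field.

    With ``segments`` given, also returns a per-segment table (segments
    1..17); empty segments are excluded with a warning.  Segment means
    recombine exactly to the global mean under segment-volume weighting.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights must have identical shape")
    w = weights / weights.sum()
    mean = float(np.sum(w * values))
    sd = float(np.sqrt(np.sum(w * (values - mean) ** 2)))
    out: Dict[str, object] = {"mean": mean, "sd": sd,
                              "volume": float(weights.sum())}
    if segments is not None:
        rows = []
        for s in range(1, 18):
            sel = segments == s
            if not np.any(sel):
                warnings.warn(f"AHA segment {s} is empty; excluded")
                continue
            ws = weights[sel] / weights[sel].sum()
            m = float(np.sum(ws * values[sel]))
            rows.append({
                "segment": s, "mean": m,
                "sd": float(np.sqrt(np.sum(ws * (values[sel] - m) ** 2))),
                "volume": float(weights[sel].sum()),
                "n_points": int(sel.sum()),
            })
        out["by_segment"] = pd.DataFrame(rows)
    return out


def welch_t_test(sample_a, sample_b) -> Dict[str, float]:
    """Welch unequal-variance two-sided t-test.

    Returns the t statistic, Welch-Satterthwaite degrees of freedom and
    the two-sided p-value.  Two identical-mean zero-variance samples give
    t = 0, p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0.0:
        return {"t": 0.0 if diff == 0.0 else math.copysign(math.inf, diff),
                "df": float(na + nb - 2), "p": 1.0 if diff == 0.0 else 0.0}
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as t_dist
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return {"t": float(t), "df": float(df), "p": p}


def stress_frames(result: ScenarioResult) -> Tuple[WallState, WallState]:
    """Wall states at end-diastole and peak systole of the analysis cycle.

    End-diastole is the frame of maximal LV volume before ejection and is
    evaluated in the zero-active-tension state: physiological end-diastole
    precedes the onset of contraction, whereas in the lumped timing
    convention activation starts exactly at the cycle origin, a few
    milliseconds before the mitral valve finishes closing."""
    rec = result.analysis_cycle
    i_ed = find_end_diastole(rec)
    i_ps = find_peak_systole(rec)
    ed = result.lv.wall_state(float(rec.volumes["lv"][i_ed]), None)
    ps = result.lv.wall_state(float(rec.volumes["lv"][i_ps]),
                              float(rec.t[i_ps]))
    return ed, ps


def scenario_summary(result: ScenarioResult) -> Dict[str, object]:
    """All reported metrics of one scenario (analysis = third cycle)."""
    rec = result.analysis_cycle
    model = result.lv.model
    ed, ps = stress_frames(result)
    w, seg = model.weight, model.segment
    stats_ps = field_statistics(ps.sigma_f, w, seg)
    stats_ed = field_statistics(ed.sigma_f, w)
    strain_ps = field_statistics(100.0 * ps.Eff, w)
    strain_ed = field_statistics(100.0 * ed.Eff, w)
    gradient = mean_systolic_gradient(rec.pressures["lv"] / MMHG,
                                      rec.pressures["art"] / MMHG)
    out = {
        "scenario": result.scenario.name,
        "R_aorta": result.scenario.R_aorta,
        "tmax_scale": result.tmax_scale,
        "mean_systolic_gradient_mmhg": gradient,
        **cycle_metrics(rec),
        "stroke_work_mmhg_ml": pv_metrics(rec)["stroke_work_mmhg_ml"],
        "stress_ps_mean_kpa": stats_ps["mean"],
        "stress_ps_sd_kpa": stats_ps["sd"],
        "stress_ed_mean_kpa": stats_ed["mean"],
        "stress_ed_sd_kpa": stats_ed["sd"],
        "strain_ps_mean_pct": strain_ps["mean"],
        "strain_ps_sd_pct": strain_ps["sd"],
        "strain_ed_mean_pct": strain_ed["mean"],
        "strain_ed_sd_pct": strain_ed["sd"],
        "t_end_diastole_s": float(rec.t[find_end_diastole(rec)]),
        "t_peak_systole_s": float(rec.t[find_peak_systole(rec)]),
    }
    return out


def report(results: Dict[str, ScenarioResult], out_dir) -> Dict[str, object]:
    """Aggregate the three scenarios: Table-1 twin CSV, per-segment CSV,
    PV-loop and pressure-trace figures, JSON summary.

    Missing scenarios produce a partial report with a warning."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = [n for n in ("baseline", "moderate", "severe") if n in results]
    missing = {"baseline", "moderate", "severe"} - set(results)
    if missing:
        warnings.warn(f"missing scenarios {sorted(missing)}; partial report")

    summaries = {n: scenario_summary(results[n]) for n in order}

    table1 = pd.DataFrame([{
        "condition": n,
        "stress_ed_kpa": s["stress_ed_mean_kpa"],
        "stress_ed_sd_kpa": s["stress_ed_sd_kpa"],
        "stress_ps_kpa": s["stress_ps_mean_kpa"],
        "stress_ps_sd_kpa": s["stress_ps_sd_kpa"],
        "strain_ed_pct": s["strain_ed_mean_pct"],
        "strain_ed_sd_pct": s["strain_ed_sd_pct"],
        "strain_ps_pct": s["strain_ps_mean_pct"],
        "strain_ps_sd_pct": s["strain_ps_sd_pct"],
    } for n, s in summaries.items()])
    table1.to_csv(out_dir / "table1_global_stress_strain.csv", index=False)

    seg_frames = []
    for n in order:
        _, ps = stress_frames(results[n])
        model = results[n].lv.model
        st = field_statistics(ps.sigma_f, model.weight, model.segment)
        df = st["by_segment"].copy()
        df.insert(0, "condition", n)
        seg_frames.append(df)
    segments = pd.concat(seg_frames, ignore_index=True)
    segments.to_csv(out_dir / "segment_systolic_stress.csv", index=False)

    _plot(results, order, out_dir)

    summary: Dict[str, object] = {"scenarios": summaries}
    if "baseline" in summaries:
        base_ps = summaries["baseline"]["stress_ps_mean_kpa"]
        for n in order:
            if n != "baseline":
                summary[f"stress_ratio_{n}_over_baseline"] = (
                    summaries[n]["stress_ps_mean_kpa"] / base_ps)
        for a, b in (("moderate", "baseline"), ("severe", "baseline"),
                     ("severe", "moderate")):
            if a in results and b in results:
                _, ps_a = stress_frames(results[a])
                _, ps_b = stress_frames(results[b])
                tt = welch_t_test(ps_a.sigma_f, ps_b.sigma_f)
                summary[f"ttest_{a}_vs_{b}"] = {
                    **tt, "n_a": len(ps_a.sigma_f), "n_b": len(ps_b.sigma_f)}
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _plot(results, order, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for n in order:
        rec = results[n].analysis_cycle
        ax.plot(rec.volumes["lv"] / 1e3, rec.pressures["lv"] / MMHG, label=n)
    ax.set_xlabel("LV volume (ml)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "pv_loops.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(order), figsize=(4 * len(order), 3.2),
                             sharey=True, squeeze=False)
    for ax, n in zip(axes[0], order):
        rec = results[n].analysis_cycle
        ax.plot(rec.t, rec.pressures["lv"] / MMHG, label="LV")
        ax.plot(rec.t, rec.pressures["art"] / MMHG, label="aorta")
        ax.set_title(n)
        ax.set_xlabel("time (s)")
    axes[0][0].set_ylabel("pressure (mmHg)")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "pressure_traces.png", dpi=120)
    plt.close(fig)
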