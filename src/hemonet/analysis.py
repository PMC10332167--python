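"""Haemodynamic index battery and the local sensitivity driver.

Indexes are computed over the last complete cardiac cycle of a waveform
record: cycle averages (MAP, CO, CVP, MPAP, mean ICP), extrema (SBP/DBP,
pulse pressures), ventricular volumes (LVSV, LVEF), ventriculo-arterial
coupling (E_LV I, EaI, indexed by body surface area), transit-time pulse
wave velocity (foot located by the intersecting-tangent method on the
pressure upstroke) and simple ratios (PPA, ABI).

Local sensitivity: S(+/-) = 100 (M_hat(+/-) - M_bar)/M_bar for each
(variable, parameter) pair, where M_hat is obtained by rerunning the model
with the parameter increased/decreased by a fixed fraction (10% by default)
of its reference value; 2|P| + 1 runs in total, ranked by |S|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import WaveformRecord
from .mechanics import MMHG


@dataclass
class SiteSpec:
    """Monitor names used for the site-bound indexes."""
    aorta: str | None = None          # ascending-aorta monitor
    brachial: str | None = None       # brachial/upper-limb site
    femoral: str | None = None
    ankle: str | None = None
    carotid: str | None = None
    tibial: str | None = None
    pwv_pairs: dict = field(default_factory=dict)  # name -> (siteA, siteB, path cm)


def cycle_series(record: WaveformRecord, key: str, monitor: str | None = None):
    """(t, x) over the last complete cycle for a monitor or lumped series."""
    nc = record.n_complete_cycles()
    if nc < 1:
        raise ValueError("record holds no complete cycle")
    i0, i1 = record.cycle_indices(nc - 1)
    t = record.t[i0:i1 + 1] if i1 < len(record.t) else record.t[i0:]
    if monitor is not None:
        x = record.monitors[monitor][key]
    else:
        x = record.lumped[key]
    x = x[i0:i0 + len(t)]
    return t, x


def cycle_mean(t, x) -> float:
    if len(t) < 2:
        return float(x[0])
    return float(np.trapezoid(x, t) / (t[-1] - t[0]))


def waveform_foot(t, p) -> float:
    """Foot time by the intersecting-tangent method.

    The tangent at the steepest upstroke point is intersected with the
    horizontal line through the cycle minimum; the crossing time is the
    foot of the wave.
    """
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    i_min = int(np.argmin(p))
    dp = np.gradient(p, t)
    # steepest upstroke after the minimum (wrap not needed within a cycle
    # that starts near diastole; search the whole cycle otherwise)
    seg = slice(i_min, len(p)) if i_min < len(p) - 5 else slice(0, len(p))
    i_up = int(np.argmax(dp[seg])) + (seg.start or 0)
    slope = dp[i_up]
    if slope <= 0:
        raise ValueError("no rising edge found")
    return float(t[i_up] - (p[i_up] - p[i_min]) / slope)


def pulse_wave_velocity(t1, p1, t2, p2, path_length: float) -> float:
    """Foot-to-foot transit PWV over a path of known length (cm/s)."""
    dt = waveform_foot(t2, p2) - waveform_foot(t1, p1)
    if dt <= 0:
        raise ValueError("non-positive transit time")
    return path_length / dt


@dataclass
class IndexBattery:
    values: dict = field(default_factory=dict)   # name -> value (CGS or stated)

    def in_mmhg(self, name):
        return self.values[name] / MMHG

    def __getitem__(self, k):
        return self.values[k]


def compute_indexes(record: WaveformRecord, sites: SiteSpec | None = None,
                    bsa: float = 1.9) -> IndexBattery:
    """Index battery over the last complete cycle.

    Pressure indexes are in dyn/cm^2, flows in cm^3/s, PWV in cm/s; the
    ventriculo-arterial elastance indexes are reported in mmHg/mL * m^2
    (multiplied by the body surface area ``bsa``).
    """
    sites = sites or SiteSpec()
    out = {}
    sbp_dbp = {}
    for name in record.monitors:
        t, p = cycle_series(record, "p", name)
        sbp_dbp[name] = (float(np.max(p)), float(np.min(p)))
        out[f"mean_p:{name}"] = cycle_mean(t, p)
        tq, q = cycle_series(record, "q", name)
        out[f"mean_q:{name}"] = cycle_mean(tq, q)

    def site_pressures(site):
        t, p = cycle_series(record, "p", site)
        return t, p

    if sites.aorta:
        t, p = site_pressures(sites.aorta)
        out["MAP"] = cycle_mean(t, p)
        out["SBP"] = float(np.max(p))
        out["DBP"] = float(np.min(p))
        out["PP_A"] = out["SBP"] - out["DBP"]
        tq, q = cycle_series(record, "q", sites.aorta)
        out["CO"] = cycle_mean(tq, q)
    if sites.femoral:
        s, d = sbp_dbp[sites.femoral]
        out["PP_F"] = s - d
    if sites.brachial and sites.aorta:
        s, d = sbp_dbp[sites.brachial]
        out["PPA"] = (s - d) / out["PP_A"]
    if sites.ankle and sites.brachial:
        out["ABI"] = sbp_dbp[sites.ankle][0] / sbp_dbp[sites.brachial][0]
    for name, (sA, sB, L) in (sites.pwv_pairs or {}).items():
        tA, pA = site_pressures(sA)
        tB, pB = site_pressures(sB)
        out[name] = pulse_wave_velocity(tA, pA, tB, pB, L)

    if "p_RA" in record.lumped:
        t, p = cycle_series(record, "p_RA")
        out["CVP"] = cycle_mean(t, p)
    if "p_pua" in record.lumped:
        t, p = cycle_series(record, "p_pua")
        out["MPAP"] = cycle_mean(t, p)
    if "p_icp" in record.lumped:
        t, p = cycle_series(record, "p_icp")
        out["ICP"] = cycle_mean(t, p)
    if "V_LV" in record.lumped:
        t, V = cycle_series(record, "V_LV")
        V_ed, V_es = float(np.max(V)), float(np.min(V))
        out["LVSV"] = V_ed - V_es
        out["LVEF"] = (V_ed - V_es) / V_ed
        if "p_LV" in record.lumped:
            _, pLV = cycle_series(record, "p_LV")
            i_es = int(np.argmin(V))
            p_es = float(pLV[i_es])
            # end-systolic elastance and arterial elastance, BSA-indexed
            out["E_LV_I"] = p_es / max(V_es, 1e-9) / MMHG * bsa
            out["EaI"] = p_es / max(out["LVSV"], 1e-9) / MMHG * bsa
    return IndexBattery(values=out)


# ---------------------------------------------------------------------------
# Local sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivitySpec:
    parameters: list                  # parameter names (accessor keys)
    variables: list = field(default_factory=lambda: ["MAP", "PP_A", "CVP", "CO"])
    perturbation: float = 0.10        # fractional one-at-a-time perturbation


def sensitivity_index(M_hat: float, M_bar: float) -> float:
    """S = 100 (M_hat - M_bar)/M_bar."""
    return 100.0 * (M_hat - M_bar) / M_bar


def local_sensitivity(spec: SensitivitySpec, runner) -> pd.DataFrame:
    """One-at-a-time local sensitivity table.

    ``runner(overrides)`` runs the model with parameter multipliers
    ``overrides`` ({param name: factor}) and returns {variable: value};
    the baseline is runner({}). 2|P| + 1 runs. Failed perturbed runs are
    excluded and logged in the 'failed' column. The table is ranked by |S|
    within each variable.
    """
    base = runner({})
    rows = []
    for p in spec.parameters:
        for sign, tag in ((+1, "+"), (-1, "-")):
            factor = 1.0 + sign * spec.perturbation
            try:
                res = runner({p: factor})
                failed = False
            except Exception as exc:   # noqa: BLE001 - report and continue
                res = {}
                failed = str(exc)
            for M in spec.variables:
                rows.append({
                    "parameter": f"{p}{tag}", "variable": M,
                    "S": sensitivity_index(res[M], base[M]) if not failed else np.nan,
                    "failed": failed if failed else "",
                })
    df = pd.DataFrame(rows)
    df["absS"] = df["S"].abs()
    df["rank"] = df.groupby("variable")["absS"].rank(
        ascending=False, method="first")
    return df.drop(columns="absS").sort_values(
        ["variable", "rank"]).reset_index(drop=True)
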