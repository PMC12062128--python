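"""Quantitative batch-fermentation physiology.

Estimators for specific growth rates (log-linear OD regression), growth
phase detection (ammonium depletion or the dissolved-oxygen trace),
biomass-specific conversion rates, product/substrate yields on molar,
carbon-mole and mass bases, carbon-balance closure, the respiratory
quotient, and the media stoichiometry calculus (molar C/N ratios,
mM <-> g/L conversions, ammonium from ammonium sulfate, OD -> cell dry
weight).

Unit conventions: time in hours, concentrations in g/L except ammonium
(mM), biomass-specific rates q in mmol/gCDW/h with consumption negative
and production positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import (ATOMIC_MASSES, BIOMASS_COMPOSITION, cmol_mass,
                         formula_weight, parse_formula)

__all__ = [
    "TimeSeries",
    "PhaseAnnotation",
    "PhysiologySummary",
    "ANALYTE_FORMULAS",
    "MOLAR_MASSES",
    "CARBON_COUNTS",
    "read_timeseries",
    "write_timeseries",
    "fit_growth_rate",
    "detect_phases",
    "specific_rate",
    "molar_yield",
    "cmol_yield",
    "mass_yield",
    "regression_yield",
    "carbon_balance",
    "respiratory_quotient",
    "cn_ratio_molar",
    "ammonium_from_as",
    "mm_to_gl",
    "gl_to_mm",
    "od_to_cdw",
    "summarize",
]

#: Hill formulas of the quantified extracellular analytes
ANALYTE_FORMULAS: dict[str, dict[str, float]] = {
    "glucose": parse_formula("C6H12O6"),
    "xylose": parse_formula("C5H10O5"),
    "eg": parse_formula("C2H6O2"),
    "ga": parse_formula("C2H4O3"),       # glycolic acid, neutral
    "glycerol": parse_formula("C3H8O3"),
    "ammonium": parse_formula("NH4"),
}
MOLAR_MASSES = {k: formula_weight(f) for k, f in ANALYTE_FORMULAS.items()}
CARBON_COUNTS = {k: f.get("C", 0.0) for k, f in ANALYTE_FORMULAS.items()}
#: carbon mass fraction per analyte (g C per g compound)
CARBON_FRACTIONS = {k: CARBON_COUNTS[k] * ATOMIC_MASSES["C"] / MOLAR_MASSES[k]
                    for k in ANALYTE_FORMULAS}

AMMONIUM_SULFATE_MASS = formula_weight(parse_formula("N2H8SO4"))  # 132.14
_NH4_MASS = MOLAR_MASSES["ammonium"]

#: biomass carbon mass fraction from the default elemental composition
BIOMASS_CARBON_FRACTION = ATOMIC_MASSES["C"] / cmol_mass(BIOMASS_COMPOSITION)

CSV_COLUMNS = ["time_h", "od", "do_percent", "glc_g_l", "xyl_g_l", "eg_g_l",
               "ga_g_l", "gly_g_l", "nh4_mM", "co2_mmol_l_h", "o2_mmol_l_h"]
_COLUMN_TO_ANALYTE = {"glc_g_l": "glucose", "xyl_g_l": "xylose",
                      "eg_g_l": "eg", "ga_g_l": "ga", "gly_g_l": "glycerol"}


@dataclass
class TimeSeries:
    """Batch-culture observations on a strictly increasing time grid.

    ``concentrations`` holds g/L traces per analyte (glucose, xylose,
    eg, ga, glycerol); ammonium is carried separately in mM.  Off-gas
    CO2/O2 evolution rates (mmol/L/h) are optional.
    """

    time: np.ndarray
    od: np.ndarray
    do_percent: np.ndarray | None = None
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    ammonium_mM: np.ndarray | None = None
    co2_rate: np.ndarray | None = None
    o2_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        for name, arr in list(self.concentrations.items()):
            arr = np.asarray(arr, dtype=float)
            if np.nanmin(arr, initial=0.0) < -1e-9:
                raise ValueError(f"negative concentrations in {name!r}")
            self.concentrations[name] = arr

    @property
    def n(self) -> int:
        return len(self.time)

    def window_mask(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.time >= lo - 1e-9) & (self.time <= hi + 1e-9)


@dataclass
class PhaseAnnotation:
    """Exponential and nitrogen-limited phase intervals (hours)."""

    exponential: tuple[float, float]
    nlim: tuple[float, float] | None
    basis: str  # ammonium | do | manual

    def __post_init__(self) -> None:
        if self.nlim is not None and self.nlim[0] < self.exponential[1] - 1e-9:
            raise ValueError("phase intervals overlap")


@dataclass
class PhysiologySummary:
    """Growth rates, specific rates, yields, RQ and carbon closure."""

    mu_exp: float
    mu_exp_se: float
    mu_nlim: float | None
    mu_nlim_se: float | None
    phases: PhaseAnnotation
    q_exp: dict[str, float]
    q_nlim: dict[str, float]
    yields: dict[str, float]
    rq: float
    carbon_closure: float

    def as_dict(self) -> dict:
        return {
            "mu_exp_per_h": self.mu_exp, "mu_exp_se": self.mu_exp_se,
            "mu_nlim_per_h": self.mu_nlim, "mu_nlim_se": self.mu_nlim_se,
            "phases": {"exponential": list(self.phases.exponential),
                       "nlim": list(self.phases.nlim) if self.phases.nlim else None,
                       "basis": self.phases.basis},
            "q_exp_mmol_gcdw_h": self.q_exp,
            "q_nlim_mmol_gcdw_h": self.q_nlim,
            "yields": self.yields,
            "rq": self.rq,
            "carbon_closure": self.carbon_closure,
        }


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path) -> TimeSeries:
    """Read the time-series CSV (columns ``time_h, od, do_percent,
    glc_g_l, xyl_g_l, eg_g_l, ga_g_l, gly_g_l, nh4_mM, co2_mmol_l_h,
    o2_mmol_l_h``; missing values allowed)."""
    df = pd.read_csv(path)
    missing = [c for c in ("time_h", "od") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    conc = {analyte: df[col].to_numpy(float)
            for col, analyte in _COLUMN_TO_ANALYTE.items() if col in df.columns}
    opt = {c: df[c].to_numpy(float) if c in df.columns else None
           for c in ("do_percent", "nh4_mM", "co2_mmol_l_h", "o2_mmol_l_h")}
    return TimeSeries(df["time_h"].to_numpy(float), df["od"].to_numpy(float),
                      do_percent=opt["do_percent"], concentrations=conc,
                      ammonium_mM=opt["nh4_mM"], co2_rate=opt["co2_mmol_l_h"],
                      o2_rate=opt["o2_mmol_l_h"])


def write_timeseries(series: TimeSeries, path: str | Path) -> Path:
    path = Path(path)
    data = {"time_h": series.time, "od": series.od}
    data["do_percent"] = (series.do_percent if series.do_percent is not None
                          else np.full(series.n, np.nan))
    for col, analyte in _COLUMN_TO_ANALYTE.items():
        data[col] = series.concentrations.get(analyte,
                                              np.full(series.n, np.nan))
    data["nh4_mM"] = (series.ammonium_mM if series.ammonium_mM is not None
                      else np.full(series.n, np.nan))
    data["co2_mmol_l_h"] = (series.co2_rate if series.co2_rate is not None
                            else np.full(series.n, np.nan))
    data["o2_mmol_l_h"] = (series.o2_rate if series.o2_rate is not None
                           else np.full(series.n, np.nan))
    pd.DataFrame(data, columns=CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# Growth rate and phases
# ---------------------------------------------------------------------------

def fit_growth_rate(series: TimeSeries,
                    window: tuple[float, float],
                    exclude_below_od: float | None = None,
                    ) -> tuple[float, float, float]:
    """Specific growth rate from a log-linear fit of OD versus time.

    Fits ln(OD) against time over ``window`` by least squares and
    returns ``(mu, standard error, r^2)``.  ``exclude_below_od`` drops
    early points still near the inoculum density (e.g. twice the
    initial OD) before fitting.
    """
    mask = series.window_mask(window) & np.isfinite(series.od)
    if exclude_below_od is not None:
        mask &= series.od >= exclude_below_od
    od = series.od[mask]
    t = series.time[mask]
    if np.any(od <= 0):
        raise ValueError("non-positive OD inside the fitting window")
    if len(od) < 3:
        raise ValueError("need at least 3 OD points to fit a growth rate")
    res = stats.linregress(t, np.log(od))
    if np.ptp(np.log(od)) < 1e-12:   # constant OD: zero growth, zero slope
        return 0.0, 0.0, 1.0
    return float(res.slope), float(res.stderr), float(res.rvalue ** 2)


def detect_phases(series: TimeSeries,
                  basis: str = "ammonium",
                  ammonium_threshold_mM: float = 0.1,
                  do_smooth_points: int = 3,
                  do_rise_points: int = 2) -> PhaseAnnotation:
    """Locate the exponential -> nitrogen-limitation transition.

    ``basis="ammonium"``: the Nlim phase starts at the first sample with
    ammonium below ``ammonium_threshold_mM``.  ``basis="do"``: the
    transition is the local minimum of the (moving-average smoothed)
    dissolved-oxygen trace that is followed by a sustained rise — the
    oxygen uptake rate peaks at the end of exponential growth and falls
    once nitrogen runs out.  If no transition is found a single-phase
    annotation is returned with a warning.
    """
    t0, t_end = float(series.time[0]), float(series.time[-1])
    if basis == "manual":
        raise ValueError("manual basis requires explicit intervals; "
                         "construct PhaseAnnotation directly")
    if basis == "ammonium":
        if series.ammonium_mM is None:
            raise ValueError("series has no ammonium channel")
        nh4 = np.asarray(series.ammonium_mM, dtype=float)
        below = np.isfinite(nh4) & (nh4 < ammonium_threshold_mM)
        if not below.any():
            warnings.warn("no ammonium depletion found; single-phase run")
            return PhaseAnnotation((t0, t_end), None, "ammonium")
        t_switch = float(series.time[int(np.argmax(below))])
    elif basis == "do":
        if series.do_percent is None:
            raise ValueError("series has no %DO channel")
        do = np.asarray(series.do_percent, dtype=float)
        k = do_smooth_points
        kernel = np.ones(k) / k
        sm = np.convolve(do, kernel, mode="valid")
        tm = series.time[k - 1:]  # time of last point in each window
        idx = None
        for i in range(1, len(sm) - do_rise_points):
            if sm[i] <= sm[i - 1] and all(
                    sm[i + j + 1] > sm[i + j] - 1e-12
                    for j in range(do_rise_points)) and sm[i + do_rise_points] > sm[i]:
                idx = i
                break
        if idx is None:
            warnings.warn("no %DO change-point found; single-phase run")
            return PhaseAnnotation((t0, t_end), None, "do")
        t_switch = float(tm[idx])
    else:
        raise ValueError(f"unknown phase-detection basis {basis!r}")
    if t_switch <= t0:
        t_switch = float(series.time[min(1, series.n - 1)])
    return PhaseAnnotation((t0, t_switch), (t_switch, t_end), basis)


# ---------------------------------------------------------------------------
# Specific rates and yields
# ---------------------------------------------------------------------------

def _biomass_time_integral(time: np.ndarray, cdw: np.ndarray) -> np.ndarray:
    """Cumulative integral of CDW over time (g*h/L), trapezoidal."""
    out = np.zeros_like(cdw)
    out[1:] = np.cumsum(0.5 * (cdw[1:] + cdw[:-1]) * np.diff(time))
    return out


def specific_rate(series: TimeSeries,
                  analyte: str,
                  phase: tuple[float, float],
                  od_to_cdw_coeff: float = 0.3) -> float:
    """Biomass-specific conversion rate q (mmol/gCDW/h) over a phase.

    Regresses the analyte amount (mmol/L) against the biomass-time
    integral (gCDW*h/L): d(analyte)/dt = q * X implies the amount is
    linear in the integral of X with slope q.  Consumption is negative,
    production positive.
    """
    if analyte == "ammonium":
        if series.ammonium_mM is None:
            raise ValueError("series has no ammonium channel")
        mmol = np.asarray(series.ammonium_mM, dtype=float)
    else:
        if analyte not in series.concentrations:
            raise ValueError(f"series has no {analyte!r} channel")
        mmol = series.concentrations[analyte] / MOLAR_MASSES[analyte] * 1000.0
    mask = series.window_mask(phase) & np.isfinite(mmol) & np.isfinite(series.od)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points inside the phase")
    t = series.time[mask]
    cdw = od_to_cdw(series.od[mask], od_to_cdw_coeff)
    if np.max(cdw) <= 0:
        raise ValueError("zero biomass in the phase window")
    integral = _biomass_time_integral(t, cdw)
    if np.ptp(integral) < 1e-12:
        raise ValueError("degenerate biomass-time integral")
    res = stats.linregress(integral, mmol[mask])
    return float(res.slope)


def molar_yield(delta_product_mmol: float, delta_substrate_mmol: float) -> float:
    """Molar yield (mol/mol) of product on consumed substrate."""
    if delta_substrate_mmol <= 0:
        raise ValueError("substrate consumption must be positive")
    return delta_product_mmol / delta_substrate_mmol


def cmol_yield(delta_product_mmol: float, delta_substrate_mmol: float,
               product: str = "ga", substrate: str = "eg") -> float:
    """Carbon-mole yield: molar yield weighted by carbon counts."""
    return (molar_yield(delta_product_mmol, delta_substrate_mmol)
            * CARBON_COUNTS[product] / CARBON_COUNTS[substrate])


def mass_yield(delta_product_mmol: float, delta_substrate_mmol: float,
               product: str = "ga", substrate: str = "eg") -> float:
    """Mass yield (g/g): molar yield weighted by molar masses."""
    return (molar_yield(delta_product_mmol, delta_substrate_mmol)
            * MOLAR_MASSES[product] / MOLAR_MASSES[substrate])


def regression_yield(substrate_consumed_mmol: Sequence[float],
                     product_formed_mmol: Sequence[float],
                     ) -> tuple[float, float]:
    """Conversion yield as the slope of product formed versus substrate
    consumed (both cumulative, paired in time; intercept left free).

    Returns ``(slope, standard error)``.
    """
    x = np.asarray(substrate_consumed_mmol, dtype=float)
    y = np.asarray(product_formed_mmol, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    # the underlying consumption is non-decreasing; small dips are
    # measurement noise, but a gross reversal signals mispaired inputs
    span = np.ptp(x)
    if np.any(np.diff(x) < -max(0.25 * span, 1e-9)):
        raise ValueError("cumulative substrate consumption must be "
                         "non-decreasing (beyond noise level)")
    if np.ptp(x) < 1e-12:
        raise ValueError("substrate consumption is constant; slope undefined")
    res = stats.linregress(x, y)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return float(res.slope), se


def carbon_balance(y_x_s_cmol: float, y_co2_s_cmol: float,
                   extra_product_cmol_yields: Mapping[str, float] | None = None,
                   ) -> float:
    """Carbon-balance closure: Cmol of biomass, CO2 and any net products
    recovered per Cmol of consumed substrate."""
    if y_x_s_cmol < 0 or y_co2_s_cmol < 0:
        raise ValueError("Cmol yields must be non-negative")
    total = y_x_s_cmol + y_co2_s_cmol
    for name, y in (extra_product_cmol_yields or {}).items():
        if y < 0:
            raise ValueError(f"negative Cmol yield for {name!r}")
        total += y
    return total


def respiratory_quotient(y_co2_x: float, y_o2_x: float) -> float:
    """RQ: mol CO2 evolved per mol O2 consumed (from yields on biomass)."""
    if y_o2_x <= 0:
        raise ValueError("O2 yield must be positive")
    return y_co2_x / y_o2_x


# ---------------------------------------------------------------------------
# Media stoichiometry
# ---------------------------------------------------------------------------

def cn_ratio_molar(sugars_g_l: Mapping[str, float],
                   ammonium_sulfate_g_l: float) -> float:
    """Molar carbon-to-nitrogen ratio of a medium.

    Carbon from the sugar concentrations (ethylene glycol is deliberately
    not counted — it contributes no biomass carbon); nitrogen from
    ammonium sulfate (2 N per formula unit).
    """
    if ammonium_sulfate_g_l <= 0:
        raise ValueError("ammonium sulfate concentration must be positive")
    mol_c = sum(g * CARBON_FRACTIONS[s] for s, g in sugars_g_l.items()
                if s != "eg") / ATOMIC_MASSES["C"]
    mol_n = ammonium_sulfate_g_l * 2.0 / AMMONIUM_SULFATE_MASS
    return mol_c / mol_n


def ammonium_from_as(ammonium_sulfate_mg_l: float) -> float:
    """NH4+ concentration (mg/L) contributed by ammonium sulfate (mg/L)."""
    if ammonium_sulfate_mg_l < 0:
        raise ValueError("concentration must be non-negative")
    return ammonium_sulfate_mg_l * 2.0 * _NH4_MASS / AMMONIUM_SULFATE_MASS


def mm_to_gl(conc_mM: float, molar_mass: float) -> float:
    """Convert mM to g/L."""
    if conc_mM < 0 or molar_mass < 0:
        raise ValueError("inputs must be non-negative")
    return conc_mM * molar_mass / 1000.0


def gl_to_mm(conc_g_l: float, molar_mass: float) -> float:
    """Convert g/L to mM."""
    if conc_g_l < 0 or molar_mass <= 0:
        raise ValueError("invalid inputs")
    return conc_g_l / molar_mass * 1000.0


def od_to_cdw(od, coeff: float = 0.3):
    """Cell dry weight (g/L) from optical density via a linear
    calibration coefficient (default 0.3 g/L per OD unit)."""
    od_arr = np.asarray(od, dtype=float)
    if np.any(od_arr < 0):
        raise ValueError("OD must be non-negative")
    out = od_arr * coeff
    return float(out) if np.isscalar(od) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# End-to-end summary
# ---------------------------------------------------------------------------

def _delta(series: TimeSeries, analyte: str, mask: np.ndarray) -> float:
    """Signed concentration change (g/L, or mM for ammonium) over a mask."""
    if analyte == "ammonium":
        arr = series.ammonium_mM
    else:
        arr = series.concentrations.get(analyte)
    if arr is None:
        return 0.0
    vals = arr[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        return 0.0
    return float(vals[-1] - vals[0])


def summarize(series: TimeSeries,
              od_to_cdw_coeff: float = 0.3,
              basis: str | None = None,
              phases: PhaseAnnotation | None = None) -> PhysiologySummary:
    """Full physiology workup of one batch run.

    Detects phases (ammonium basis when the channel is present, %DO
    otherwise), fits per-phase growth rates, computes biomass-specific
    rates for every available analyte and the off-gas channels, and
    derives yields, RQ and the carbon-balance closure over the
    nitrogen-limited phase (falling back to the whole run when no
    transition was found).
    """
    if phases is None:
        if basis is None:
            basis = "ammonium" if series.ammonium_mM is not None else "do"
        phases = detect_phases(series, basis=basis)
    # the sample at the phase boundary mixes both regimes; exclude it from
    # the exponential fit so the slope reflects pure exponential growth
    t_exp = series.time[series.window_mask(phases.exponential)]
    exp_fit_window = (phases.exponential[0],
                      float(t_exp[-2]) if phases.nlim is not None
                      and len(t_exp) >= 4 else phases.exponential[1])
    mu_exp, mu_exp_se, _ = fit_growth_rate(series, exp_fit_window)
    if phases.nlim is not None:
        # growth stops once sugars run out; restrict the Nlim mu fit to
        # samples where substrate is still present
        nlim_end = phases.nlim[1]
        sugar = sum(series.concentrations.get(a, np.zeros(series.n))
                    for a in ("glucose", "xylose"))
        with_sugar = series.window_mask(phases.nlim) & (sugar > 1e-6)
        if with_sugar.sum() >= 3:
            nlim_end = float(series.time[with_sugar][-1])
        mu_nlim, mu_nlim_se, _ = fit_growth_rate(
            series, (phases.nlim[0], nlim_end))
        yield_window = phases.nlim
    else:
        mu_nlim = mu_nlim_se = None
        yield_window = phases.exponential

    def rates(window):
        out = {}
        for analyte in list(series.concentrations) + (
                ["ammonium"] if series.ammonium_mM is not None else []):
            try:
                out[analyte] = specific_rate(series, analyte, window,
                                             od_to_cdw_coeff)
            except ValueError:
                pass
        return out

    q_exp = rates(phases.exponential)
    q_nlim = rates(yield_window)

    mask = series.window_mask(yield_window)
    cdw = od_to_cdw(series.od, od_to_cdw_coeff)
    dx = float(cdw[mask][-1] - cdw[mask][0]) if mask.sum() >= 2 else 0.0
    yields: dict[str, float] = {}
    d_sub = {a: -_delta(series, a, mask) for a in ("glucose", "xylose")}
    sugar_g = sum(max(v, 0.0) for v in d_sub.values())
    d_eg = -_delta(series, "eg", mask)
    d_ga = _delta(series, "ga", mask)
    if sugar_g > 1e-9 and dx > 0:
        yields["Y_X/S_g_g"] = dx / sugar_g
        sugar_cmol = sum(max(v, 0.0) / MOLAR_MASSES[a] * CARBON_COUNTS[a]
                         for a, v in d_sub.items())
        yields["Y_X/S_cmol_cmol"] = (dx * BIOMASS_CARBON_FRACTION
                                     / ATOMIC_MASSES["C"]) / sugar_cmol
    if d_eg > 1e-9:
        eg_mmol = d_eg / MOLAR_MASSES["eg"] * 1000.0
        ga_mmol = d_ga / MOLAR_MASSES["ga"] * 1000.0
        yields["Y_GA/EG_mol_mol"] = molar_yield(ga_mmol, eg_mmol)
        yields["Y_GA/EG_g_g"] = mass_yield(ga_mmol, eg_mmol)
        yields["Y_GA/EG_cmol_cmol"] = cmol_yield(ga_mmol, eg_mmol)

    rq = float("nan")
    carbon_closure = float("nan")
    if series.co2_rate is not None and series.o2_rate is not None and dx > 0:
        # off-gas channels are interval-average rates over the preceding
        # sampling interval; rate * dt summed over the window therefore
        # gives the exact evolved amount
        idx = np.flatnonzero(mask)
        dt = np.diff(series.time[idx])
        co2 = float(np.sum(series.co2_rate[idx[1:]] * dt))  # mmol/L evolved
        o2 = float(np.sum(series.o2_rate[idx[1:]] * dt))
        if dx > 0:
            yields["Y_CO2/X_mmol_g"] = co2 / dx
            yields["Y_O2/X_mmol_g"] = o2 / dx
        if o2 > 0:
            rq = respiratory_quotient(co2, o2)
        c_in = (sum(max(v, 0.0) * CARBON_FRACTIONS[a] / ATOMIC_MASSES["C"]
                    for a, v in d_sub.items())
                + max(d_eg, 0.0) * CARBON_FRACTIONS["eg"] / ATOMIC_MASSES["C"])
        if c_in > 1e-12:
            c_out = (dx * BIOMASS_CARBON_FRACTION / ATOMIC_MASSES["C"]
                     + co2 / 1000.0
                     + max(d_ga, 0.0) * CARBON_FRACTIONS["ga"] / ATOMIC_MASSES["C"])
            carbon_closure = c_out / c_in
            if sugar_g > 1e-9:
                yields["Y_CO2/S_cmol_cmol"] = (co2 / 1000.0) / (
                    sum(max(v, 0.0) * CARBON_FRACTIONS[a] / ATOMIC_MASSES["C"]
                        for a, v in d_sub.items()))
    if carbon_closure > 1.05:
        warnings.warn(f"carbon closure {carbon_closure:.3f} exceeds 1.05")

    return PhysiologySummary(mu_exp, mu_exp_se, mu_nlim, mu_nlim_se, phases,
                             q_exp, q_nlim, yields, rq, carbon_closure)
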