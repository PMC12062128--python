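"""Seeded generator of two-phase batch-fermentation time series.

Emulates the batch cultures the physiology analysis expects: an
exponential growth phase that ends when ammonium runs out, a
nitrogen-limited (Nlim) phase in which residual sugar is converted to
lipid-like storage biomass at a lower rate, glucose-repressed or
co-consumed ethylene-glycol (EG) oxidation to glycolic acid (GA) at a
configured 1:1-capped molar yield, an optional extra-GA route that
drains xylose carbon (emulating the proposed xylulose-1P pathway, which
pushes apparent GA/EG yields above 100 %), off-gas CO2/O2 at a
configured respiratory quotient, a phenomenological dissolved-oxygen
trace, and multiplicative (OD) / additive (concentration) measurement
noise applied at sampling times only.

Integration is exact rather than Euler-approximate: within each regime
the biomass trajectory is the closed-form exponential, all pools are
linked to biomass growth (or the biomass-time integral) analytically,
and regime switches (ammonium, glucose, xylose or EG exhaustion) are
located by solving the closed forms, so the configured ground truth
(growth rates, specific rates, yields, RQ) is recoverable to machine
precision from noise-free output and the carbon ledger closes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .model_core import ATOMIC_MASSES, BIOMASS_COMPOSITION, cmol_mass
from .physiology import (AMMONIUM_SULFATE_MASS, CARBON_COUNTS, MOLAR_MASSES,
                         TimeSeries, ammonium_from_as, write_timeseries)

__all__ = ["SimulationConfig", "SimulationResult", "simulate_batch",
           "write_fixture_suite", "FIXTURE_REGIMES"]

_EPS = 1e-12
_M_CMOL = cmol_mass(BIOMASS_COMPOSITION)
#: biomass nitrogen mass fraction implied by CH1.8O0.5N0.2 (~11.4 %)
DEFAULT_BIOMASS_N_FRACTION = (BIOMASS_COMPOSITION["N"] * ATOMIC_MASSES["N"]
                              / _M_CMOL)
BIOMASS_C_FRACTION = ATOMIC_MASSES["C"] / _M_CMOL

GATING_MODES = ("glucose_nlim_only", "xylose_coconsume", "none")


@dataclass
class SimulationConfig:
    """Ground-truth parameters of one synthetic batch culture.

    Defaults reproduce the glucose bioreactor condition: 40 g/L glucose
    at a molar C/N near 40, exponential growth at 0.34 1/h switching to
    0.084 1/h after ammonium depletion, biomass yield 0.42 g/g, EG
    oxidised only after the onset of nitrogen limitation at a fully
    conserved 1.0 mol GA per mol EG, and a respiratory quotient of 1.36.
    """

    glucose_g_l: float = 40.0
    xylose_g_l: float = 0.0
    eg_g_l: float = 4.655       # 75 mM
    ammonium_sulfate_g_l: float = 2.02
    inoculum_cdw_g_l: float = 0.15
    mu_exp: float = 0.34        # 1/h
    mu_nlim: float = 0.084      # 1/h
    y_xs: float = 0.42          # g CDW per g sugar
    y_ga_eg: float = 1.0        # mol GA per mol EG, <= 1 (EG-derived)
    extra_ga_factor: float = 0.0  # extra mol GA per mol EG via xylose carbon
    rq: float = 1.36
    eg_gating: str = "glucose_nlim_only"
    q_eg: float = 0.15          # mmol EG /gCDW/h while the gate is open
    sampling_interval_h: float = 2.0
    horizon_h: float = 72.0
    od_noise_sigma: float = 0.0       # multiplicative (lognormal) on OD
    conc_noise_sigma: float = 0.0     # additive (g/L; mM for ammonium)
    seed: int | None = None
    od_coeff: float = 0.3             # g CDW per OD unit
    biomass_n_fraction: float = DEFAULT_BIOMASS_N_FRACTION

    def validate(self) -> None:
        if min(self.glucose_g_l, self.xylose_g_l, self.eg_g_l,
               self.ammonium_sulfate_g_l) < 0:
            raise ValueError("initial concentrations must be non-negative")
        if self.inoculum_cdw_g_l <= 0:
            raise ValueError("inoculum CDW must be positive")
        if min(self.mu_exp, self.mu_nlim, self.y_xs, self.q_eg,
               self.extra_ga_factor, self.rq) < 0:
            raise ValueError("rates and yields must be non-negative")
        if self.mu_nlim > self.mu_exp:
            raise ValueError("mu_nlim must not exceed mu_exp")
        if not 0.0 <= self.y_ga_eg <= 1.0:
            raise ValueError("y_ga_eg must be in [0, 1]; apparent yields "
                             "above 1 arise via extra_ga_factor")
        if self.eg_gating not in GATING_MODES:
            raise ValueError(f"unknown gating mode {self.eg_gating!r}")
        if self.sampling_interval_h <= 0 or self.horizon_h <= 0:
            raise ValueError("sampling interval and horizon must be positive")
        if (self.od_noise_sigma > 0 or self.conc_noise_sigma > 0) \
                and self.seed is None:
            raise ValueError("a seed is mandatory when noise is enabled")


@dataclass
class SimulationResult:
    series: TimeSeries
    ground_truth: dict


# ---------------------------------------------------------------------------
# Exact segment integration
# ---------------------------------------------------------------------------

@dataclass
class _State:
    t: float
    x: float            # g CDW / L
    glc: float          # g/L
    xyl: float
    eg: float
    ga: float
    nh4: float          # g NH4+ / L
    co2: float = 0.0    # cumulative mmol/L
    o2: float = 0.0


def _regime(state: _State, cfg: SimulationConfig):
    """Current growth rate, active sugar and EG-gate state."""
    n_avail = state.nh4 > _EPS
    sugar = "glc" if state.glc > _EPS else ("xyl" if state.xyl > _EPS else None)
    if sugar is None:
        mu = 0.0
    elif n_avail:
        mu = cfg.mu_exp
    else:
        mu = cfg.mu_nlim
    if cfg.eg_gating == "glucose_nlim_only":
        # repressed while both glucose and nitrogen are available
        gate = not (state.glc > _EPS and n_avail)
    else:  # xylose_coconsume / none: no repression
        gate = True
    eg_active = gate and state.eg > _EPS and cfg.q_eg > 0
    return mu, sugar, n_avail, eg_active


def _advance(state: _State, cfg: SimulationConfig, dt_max: float) -> float:
    """Advance the state by at most ``dt_max`` hours, stopping exactly at
    the first pool-exhaustion event.  Returns the time actually advanced."""
    mu, sugar, n_avail, eg_active = _regime(state, cfg)
    extra_active = eg_active and state.xyl > _EPS and not n_avail \
        and cfg.extra_ga_factor > 0

    # per-unit demands
    m_eg = MOLAR_MASSES["eg"] / 1000.0      # g per mmol
    m_ga = MOLAR_MASSES["ga"] / 1000.0
    m_xyl = MOLAR_MASSES["xylose"] / 1000.0
    # EG drain per biomass-time integral I = int X dt  (g/L per gCDW*h/L)
    eg_per_i = cfg.q_eg * m_eg if eg_active else 0.0
    # extra GA route: mol GA per mol EG, carbon from xylose (2 C per 5 C)
    extra_xyl_per_i = (cfg.extra_ga_factor * cfg.q_eg
                       * (CARBON_COUNTS["ga"] / CARBON_COUNTS["xylose"])
                       * m_xyl) if extra_active else 0.0

    def dx_of(dt):      # biomass increment after dt
        return state.x * np.expm1(mu * dt) if mu > 0 else 0.0

    def i_of(dt):       # biomass-time integral over dt
        return (state.x * np.expm1(mu * dt) / mu) if mu > 0 else state.x * dt

    # earliest event: solve pool(t) = 0 in closed form
    t_event = dt_max
    if mu > 0 and n_avail:
        dx_n = state.nh4 * (ATOMIC_MASSES["N"] / MOLAR_MASSES["ammonium"]) \
            / cfg.biomass_n_fraction
        t_event = min(t_event, np.log1p(dx_n / state.x) / mu)
    if mu > 0 and sugar is not None:
        avail = state.glc if sugar == "glc" else state.xyl
        # sugar drain: growth (dX / y_xs) plus, on xylose, the extra-GA route
        if sugar == "xyl" and extra_xyl_per_i > 0:
            # avail = dX/y_xs + extra_xyl_per_i * dX/mu  -> linear in dX
            denom = 1.0 / cfg.y_xs + extra_xyl_per_i / mu
        else:
            denom = 1.0 / cfg.y_xs
        t_event = min(t_event, np.log1p(avail / denom / state.x) / mu)
    if extra_xyl_per_i > 0 and sugar != "xyl" and state.xyl > _EPS:
        # xylose drained only by the extra-GA route (growth on glucose or
        # stationary): solve extra_xyl_per_i * I(t) = xylose remaining
        if mu > 0:
            t_event = min(t_event, np.log1p(
                state.xyl * mu / (extra_xyl_per_i * state.x)) / mu)
        else:
            t_event = min(t_event, state.xyl / (extra_xyl_per_i * state.x))
    if eg_per_i > 0:
        if mu > 0:
            t_event = min(t_event,
                          np.log1p(state.eg * mu / (eg_per_i * state.x)) / mu)
        else:
            t_event = min(t_event, state.eg / (eg_per_i * state.x))

    dt = max(min(t_event, dt_max), 0.0)
    if dt <= 0:
        return 0.0
    dx = dx_of(dt)
    i_int = i_of(dt)

    # pools
    sugar_used = dx / cfg.y_xs if sugar is not None else 0.0
    eg_mmol = eg_per_i * i_int / m_eg
    extra_mmol_ga = cfg.extra_ga_factor * eg_mmol if extra_active else 0.0
    extra_xyl_g = extra_xyl_per_i * i_int
    ga_from_eg_mmol = cfg.y_ga_eg * eg_mmol

    if sugar == "glc":
        state.glc = max(state.glc - sugar_used, 0.0)
    elif sugar == "xyl":
        state.xyl = max(state.xyl - sugar_used, 0.0)
    state.xyl = max(state.xyl - extra_xyl_g, 0.0)
    state.eg = max(state.eg - eg_per_i * i_int, 0.0)
    state.ga += (ga_from_eg_mmol + extra_mmol_ga) * m_ga
    if n_avail and mu > 0:
        nh4_used = dx * cfg.biomass_n_fraction \
            * MOLAR_MASSES["ammonium"] / ATOMIC_MASSES["N"]
        state.nh4 = max(state.nh4 - nh4_used, 0.0)

    # carbon ledger -> CO2 (mmol C = mmol CO2)
    c_sugar = sugar_used * (CARBON_COUNTS["glucose" if sugar == "glc" else "xylose"]
                            / MOLAR_MASSES["glucose" if sugar == "glc" else "xylose"]
                            * 1000.0) if sugar is not None else 0.0
    c_biomass = dx * BIOMASS_C_FRACTION / ATOMIC_MASSES["C"] * 1000.0
    c_eg_loss = eg_mmol * CARBON_COUNTS["eg"] * (1.0 - cfg.y_ga_eg)
    co2 = (c_sugar - c_biomass) + c_eg_loss
    state.co2 += co2
    state.o2 += co2 / cfg.rq if cfg.rq > 0 else 0.0

    state.x += dx
    state.t += dt
    return dt


def simulate_batch(config: SimulationConfig) -> SimulationResult:
    """Integrate one batch culture and sample it on a regular grid.

    Returns the (optionally noisy) :class:`~egflux.physiology.TimeSeries`
    together with a ground-truth record holding every configured
    parameter, the event times (nitrogen/glucose/xylose/EG exhaustion)
    and the derived per-phase true specific rates, for recovery tests.
    """
    config.validate()
    cfg = config
    state = _State(0.0, cfg.inoculum_cdw_g_l, cfg.glucose_g_l, cfg.xylose_g_l,
                   cfg.eg_g_l, 0.0,
                   ammonium_from_as(cfg.ammonium_sulfate_g_l * 1000.0) / 1000.0)

    n_samples = int(round(cfg.horizon_h / cfg.sampling_interval_h)) + 1
    sample_times = np.arange(n_samples) * cfg.sampling_interval_h

    events: dict[str, float] = {}
    rows = []

    def record():
        rows.append((state.t, state.x, state.glc, state.xyl, state.eg,
                     state.ga, state.nh4, state.co2, state.o2))

    record()
    prev = {"nh4": state.nh4 > _EPS, "glc": state.glc > _EPS,
            "xyl": state.xyl > _EPS, "eg": state.eg > _EPS}
    for ts in sample_times[1:]:
        guard = 0
        while state.t < ts - 1e-9:
            advanced = _advance(state, cfg, ts - state.t)
            for key, attr in (("nh4", "nh4"), ("glc", "glc"),
                              ("xyl", "xyl"), ("eg", "eg")):
                now = getattr(state, attr) > _EPS
                if prev[key] and not now:
                    events[f"t_{key}_depleted"] = state.t
                prev[key] = now
            if advanced <= 0:
                state.t = ts  # nothing left to integrate in this regime
            guard += 1
            if guard > 10000:
                raise RuntimeError("integration failed to advance (step "
                                   "instability)")
        state.t = ts
        record()

    arr = np.asarray(rows)
    t, x = arr[:, 0], arr[:, 1]
    od = x / cfg.od_coeff
    glc, xyl, eg, ga = arr[:, 2], arr[:, 3], arr[:, 4], arr[:, 5]
    nh4_mm = arr[:, 6] / MOLAR_MASSES["ammonium"] * 1000.0
    co2_cum, o2_cum = arr[:, 7], arr[:, 8]
    # off-gas channels are interval-average evolution rates (mmol/L/h over
    # the preceding sampling interval, as an off-gas analyzer reports);
    # summing rate * dt therefore reconstructs cumulative gas exactly.
    r_co2 = np.zeros(len(t))
    r_o2 = np.zeros(len(t))
    r_co2[1:] = np.diff(co2_cum) / np.diff(t)
    r_o2[1:] = np.diff(o2_cum) / np.diff(t)

    # dissolved oxygen: affine, decreasing in the oxygen uptake rate
    peak = r_o2.max()
    do = 100.0 - (80.0 * r_o2 / peak if peak > 0 else 0.0)
    do = np.clip(do, 0.0, 100.0)

    if cfg.od_noise_sigma > 0 or cfg.conc_noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        if cfg.od_noise_sigma > 0:
            od = od * np.exp(cfg.od_noise_sigma * rng.standard_normal(len(od)))
        if cfg.conc_noise_sigma > 0:
            s = cfg.conc_noise_sigma
            glc = np.clip(glc + s * rng.standard_normal(len(t)), 0, None)
            xyl = np.clip(xyl + s * rng.standard_normal(len(t)), 0, None)
            eg = np.clip(eg + s * rng.standard_normal(len(t)), 0, None)
            ga = np.clip(ga + s * rng.standard_normal(len(t)), 0, None)
            nh4_mm = np.clip(nh4_mm + s * rng.standard_normal(len(t)), 0, None)

    series = TimeSeries(
        t, od, do_percent=do,
        concentrations={"glucose": glc, "xylose": xyl, "eg": eg, "ga": ga,
                        "glycerol": np.zeros(len(t))},
        ammonium_mM=nh4_mm, co2_rate=r_co2, o2_rate=r_o2)

    # derived true rates
    q_sugar_exp = {}
    for name, col in (("glucose", "glc_g_l"), ("xylose", "xyl_g_l")):
        init = cfg.glucose_g_l if name == "glucose" else cfg.xylose_g_l
        if init > 0:
            q_sugar_exp[f"q_{name}"] = (-cfg.mu_exp / cfg.y_xs
                                        / MOLAR_MASSES[name] * 1000.0)
    truth = {
        "config": asdict(cfg),
        "events": events,
        "t_nlim_start": events.get("t_nh4_depleted"),
        "true_rates": {
            "mu_exp": cfg.mu_exp, "mu_nlim": cfg.mu_nlim,
            **q_sugar_exp,
            "q_eg_active": -cfg.q_eg,
            "q_ga_active": cfg.q_eg * cfg.y_ga_eg,
            "y_ga_eg_effective_nlim_xylose":
                cfg.y_ga_eg + (cfg.extra_ga_factor if cfg.xylose_g_l > 0 else 0.0),
            "rq": cfg.rq,
        },
        "final_state": {"x": state.x, "glucose": state.glc, "xylose": state.xyl,
                        "eg": state.eg, "ga": state.ga,
                        "co2_cum_mmol_l": state.co2, "o2_cum_mmol_l": state.o2},
        "cumulative": {"co2_mmol_l": co2_cum.tolist(),
                       "o2_mmol_l": o2_cum.tolist()},
    }
    return SimulationResult(series, truth)


def total_carbon_mmol(result: SimulationResult, at_index: int = -1) -> float:
    """Total carbon (mmol C/L) in biomass, residual substrates, GA and
    cumulative CO2 at a sampled time point of a noise-free run."""
    s = result.series
    i = at_index if at_index >= 0 else s.n + at_index
    cdw = s.od[i] * result.ground_truth["config"]["od_coeff"]
    total = cdw * BIOMASS_C_FRACTION / ATOMIC_MASSES["C"] * 1000.0
    for analyte in ("glucose", "xylose", "eg", "ga"):
        total += (s.concentrations[analyte][i] / MOLAR_MASSES[analyte]
                  * 1000.0 * CARBON_COUNTS[analyte])
    total += result.ground_truth["cumulative"]["co2_mmol_l"][i]
    return float(total)


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------

#: the four desk-scale shake-flask regimes, each generated with and
#: without EG (150 mM): substrate mix, ammonium sulfate (g/L) and gating
FIXTURE_REGIMES = {
    "glc_cn80": dict(glucose_g_l=10.0, xylose_g_l=0.0,
                     ammonium_sulfate_g_l=0.275, mu_exp=0.34,
                     eg_gating="glucose_nlim_only"),
    "glc_cn8.8": dict(glucose_g_l=20.0, xylose_g_l=0.0,
                      ammonium_sulfate_g_l=5.0, mu_exp=0.34,
                      eg_gating="glucose_nlim_only"),
    "xyl_cn80": dict(glucose_g_l=0.0, xylose_g_l=10.0,
                     ammonium_sulfate_g_l=0.275, mu_exp=0.11,
                     eg_gating="xylose_coconsume"),
    "glcxyl_cn80": dict(glucose_g_l=10.0, xylose_g_l=10.0,
                        ammonium_sulfate_g_l=0.550, mu_exp=0.34,
                        eg_gating="glucose_nlim_only"),
}

_FLASK_EG_G_L = 9.3105  # 150 mM


def write_fixture_suite(directory: str | Path, seed: int) -> list[Path]:
    """Write the eight paired CSV/JSON desk-scale fixtures (the four
    flask regimes, each with and without 150 mM EG).  Deterministic for
    a given seed; repeated calls produce byte-identical files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    idx = 0
    for name, regime in FIXTURE_REGIMES.items():
        for with_eg in (False, True):
            cfg = SimulationConfig(
                **regime,
                eg_g_l=_FLASK_EG_G_L if with_eg else 0.0,
                inoculum_cdw_g_l=0.06,  # OD 0.2 at coefficient 0.3
                horizon_h=144.0, sampling_interval_h=4.0,
                od_noise_sigma=0.02, conc_noise_sigma=0.05,
                seed=int(seed) + idx)
            result = simulate_batch(cfg)
            stem = f"{name}_{'eg' if with_eg else 'ctrl'}"
            csv_path = write_timeseries(result.series, directory / f"{stem}.csv")
            json_path = directory / f"{stem}.json"
            json_path.write_text(
                json.dumps(result.ground_truth, indent=1, sort_keys=True) + "\n")
            paths.extend([csv_path, json_path])
            idx += 1
    return paths
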