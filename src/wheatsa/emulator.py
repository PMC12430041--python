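"""Deterministic daily-step wheat emulator and the simulator adapter contract.

The emulator maps a 21-parameter set, one season of daily weather, and an
irrigation treatment plan to aboveground dry matter (WAGT) and grain
yield, both in kg/ha.  It is an *emulator*: a compact, fully documented
stand-in for a mechanistic crop model, engineered so that the global
sensitivity structure of its two outputs reproduces the qualitative
findings reported for APSIM-Wheat under the same parameter bounds
(WAGT driven by the phenology thermal-time targets T1/T2/T4 and water
demand E1; yield additionally by grain number G1, grain-set window T3,
filling rate P1, and canopy extinction K).  It makes no claim of
agronomic fidelity beyond that structure.

Model stages, run in a single daily loop, vectorized over a batch of
parameter sets:

1. Phenology: development thermal time tt_dev = min(cap, max(0,
   Tmean - Tbase_dev)); cumulative tt_dev crosses T1 (jointing), T1+T2
   (flowering), +T3 (grain-fill onset), +T4 (maturity).  The
   development base temperature sits above the growth base, and hot
   days saturate at the cap, so stage boundaries spread widely across
   the spring calendar.  Pre-jointing development is slowed by
   1/(1 + 0.02 (P4 + V1)) (photoperiod/vernalization).
2. Canopy: leaf area starts from I1 x plant density; pre-jointing it
   expands at a thermal-time-driven rate (leaf appearance is
   temperature-paced), weakly modulated by specific leaf area Y1 and
   initial plant leaf area I1, capped at I2; water stress senesces it
   at a rate proportional to S1; during grain fill green area declines
   with filling progress.
3. Biomass: dW = R1 x radiation x f x Wfac x Nfac x Tgrow, where
   Wfac = Wstress^e_veg before flowering (vegetative wheat tolerates
   moderate deficit through osmotic adjustment), Wstress through
   flowering, and Wstress^e_gf > 1 during grain fill (filling is the
   drought-critical phase), with
   light interception f = 1 - exp(-k_eff LAI), k_eff = k0 + k1 K
   (stem/ear floor plus leaf extinction); during grain fill the
   intercepting area is the remaining green fraction.  The nitrogen
   term blends Nfac = clamp(2 - 0.5 N1, 0.5, 1.25) with a baseline
   (1 - wN + wN Nfac): the site is fertilized to local practice, so
   nitrogen-response parameters express only partially.  A temperature
   ramp Tgrow stops growth below 0 degC (no winter assimilation).
4. Water: single bucket under proportional drip-irrigation control:
   daily inflow closes a fixed fraction of the deficit to the phase's
   moisture setpoint (partway from the treatment's lower limit back to
   field capacity), so refills are gradual, the season-mean moisture
   rises monotonically with the lower limit, and the store never
   exceeds field capacity (soil moisture is monitored continuously and
   the drip system regulated); daily demand is E1 x
   reference demand, capped at an atmospheric ceiling; extraction is
   capped at a fixed fraction of stored water; Wstress = supply/demand
   clipped to [0, 1].
5. Grain: grain number = G1 x an anthesis-window basis (shoot growth
   accumulated between jointing and grain-fill onset plus a fraction of
   standing shoot mass) x duration windows for tillering (T1/600)^a,
   spike growth (T2/800)^b and grain set (T3/T3ref)^g -- grain number
   in wheat integrates the durations of these phases; slow lag filling
   at a rate tied to P2;
   main filling co-limited by the P1-driven sink rate (reduced by the
   X1 cold penalty) and the assimilate supply per grain (the share of
   current assimilation exportable to grain -- set by green-leaf
   interception with leaf extinction K -- plus a stem-reserve flow),
   blended by a q-norm co-limitation
   rate = (sink^-q + source^-q)^(-1/q); per-grain mass capped at
   M2; grain N accumulation (M1, P3) drains reserves; yield = grain
   number x grain mass, capped at 0.55 WAGT.

All tuning constants live in :class:`EmulatorConstants`; they were fixed
once, against the published influential-parameter sets, and ship frozen
with a regression test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np

from .param_space import PARAMETER_CODES, ParameterSet, load_bounds
from .synthetic_env import TreatmentPlan, WeatherSeries

_IDX = {c: i for i, c in enumerate(PARAMETER_CODES)}


class MaturityError(RuntimeError):
    """Raised when the supplied weather ends before crop maturity."""


@dataclass(frozen=True)
class SimOutput:
    """Aboveground dry matter and grain yield at maturity, kg/ha."""

    wagt: float
    grain_yield: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.wagt) and np.isfinite(self.grain_yield)):
            raise ValueError("non-finite simulator output")
        if not (0.0 <= self.grain_yield <= self.wagt + 1e-9):
            raise ValueError("grain yield must lie in [0, WAGT]")


class SimulatorAdapter(Protocol):
    """Contract any batch-drivable simulator must honor.

    ``evaluate`` must be pure (deterministic in its inputs); the driver
    modules rely on this when replaying stored design points.
    """

    name: str
    output_variables: tuple[str, ...]

    def evaluate(
        self,
        params: Mapping[str, float],
        weather: WeatherSeries,
        plan: TreatmentPlan,
    ) -> SimOutput: ...


@dataclass(frozen=True)
class EmulatorConstants:
    """Frozen tuning constants of the emulator (one configuration block)."""

    tbase: float = 0.0            # degC, thermal-time base (growth)
    tbase_dev: float = 2.5        # degC, thermal-time base (development)
    dev_cap: float = 20.0         # degC d, daily development thermal-time cap
    dev_slow: float = 0.02        # photoperiod/vernalization slow-down per index unit
    plant_density: float = 300.0  # plants m-2
    tgrow_full: float = 8.0       # degC, temperature ramp reaches 1 here
    # reference water demand
    rd_radn: float = 0.20         # mm per MJ m-2
    rd_temp: float = 0.06         # mm per degC of positive mean temperature
    ku: float = 0.072             # daily extractable fraction of stored water
    demand_cap: float = 12.0      # mm/day, atmospheric ceiling on crop demand
    veg_stress_exp: float = 0.5   # stress exponent before flowering
    gf_stress_exp: float = 2.4    # stress exponent during grain fill
    irr_rate: float = 0.5         # daily closure fraction of the quota deficit
    quota_frac: float = 0.5       # setpoint as fraction from lower limit to FC
    # canopy
    k_floor: float = 0.48         # stem/ear interception floor on extinction
    k_scale: float = 0.12         # leaf extinction contribution of K, vegetative
    k_gf_floor: float = 0.03      # residual extinction during grain fill
    k_gf_scale: float = 1.25      # leaf extinction contribution of K, grain fill
    lai_tt_rate: float = 0.0045   # LAI per degC d expansion rate, pre-jointing
    y1_mid: float = 33500.0       # mm2 g-1, reference specific leaf area
    y1_exp: float = 0.25          # SLA modulation exponent on expansion
    i1_mid: float = 200.0         # mm2, reference initial plant leaf area
    i1_exp: float = 0.15          # initial-leaf-area modulation exponent
    lai_rate1: float = 0.35       # stage-1 expansion rate as fraction of pre-jointing
    sen_fac: float = 0.45         # water-stress senescence multiplier on S1
    gf_sen: float = 0.75          # green-area decline over grain fill
    min_green: float = 0.10       # floor on green fraction during grain fill
    # grain
    stem_frac: float = 0.65       # stem share of biomass at flowering
    grain_stock_frac: float = 0.2 # shoot-stock contribution to the grain-number basis
    gset_ref: float = 180.0       # degC d, full grain-set window
    gset_exp: float = 0.75        # grain-set window exponent
    t1_ref: float = 600.0         # degC d, full tillering window
    t1_exp: float = 0.75          # tillering window exponent
    t2_ref: float = 800.0         # degC d, full spike-growth window
    t2_exp: float = 0.45          # spike-growth window exponent
    fill_eff: float = 0.20        # efficiency on the P1 sink rate
    colimit_q: float = 2.3        # sharpness of sink/source co-limitation
    lag_eff: float = 0.25         # efficiency on the P2 lag rate
    fill_frac: float = 0.90       # assimilate fraction available to grain
    remob_frac: float = 0.10      # stem fraction remobilizable as reserve
    res_flow: float = 0.04        # daily reserve drawdown fraction
    n_cost: float = 1.5           # reserve mass drain per unit grain-N rate
    n1_weight: float = 0.55       # expression weight of the nitrogen factor
    cold_t: float = 12.0          # degC, cold penalty reaches 0 here
    hi_max: float = 0.55          # harvest-index ceiling
    winter_window: int = 15       # days, smoothing window for the winter mask


DEFAULT_CONSTANTS = EmulatorConstants()


def reference_demand(
    maxt, mint, radn, consts: EmulatorConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Reference crop water demand (mm/day) before the E1 multiplier.

    Nonnegative, nondecreasing in temperature and radiation, zero under
    zero forcing; growth-season gated by the same temperature ramp as
    assimilation so frozen winter days carry no demand.
    """
    tmean = 0.5 * (np.asarray(maxt, float) + np.asarray(mint, float))
    ramp = np.clip(tmean / consts.tgrow_full, 0.0, 1.0)
    base = consts.rd_radn * np.asarray(radn, float) + consts.rd_temp * np.clip(tmean, 0.0, None)
    return base * ramp


def winter_mask(weather: WeatherSeries, consts: EmulatorConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Days whose smoothed mean temperature is below freezing."""
    k = np.ones(consts.winter_window) / consts.winter_window
    smoothed = np.convolve(weather.tmean, k, mode="same")
    return smoothed < 0.0


def _forcing(weather: WeatherSeries, consts: EmulatorConstants) -> dict:
    """Per-day forcing arrays derived from one weather series."""
    tmean = weather.tmean
    winter = winter_mask(weather, consts)
    w_idx = np.nonzero(winter)[0]
    return {
        "radn": weather.radn,
        "rain": weather.rain,
        "tt": np.clip(tmean - consts.tbase, 0.0, None),
        "tt_dev": np.clip(tmean - consts.tbase_dev, 0.0, consts.dev_cap),
        "tgrow": np.clip(tmean / consts.tgrow_full, 0.0, 1.0),
        "refd": reference_demand(weather.maxt, weather.mint, weather.radn, consts),
        "coldpen": np.clip((consts.cold_t - tmean) / consts.cold_t, 0.0, 1.0),
        "winter": winter,
        "winter_start": int(w_idx[0]) if w_idx.size else weather.season_days + 1,
        "days": weather.season_days,
    }


def simulate_batch(
    P: np.ndarray,
    weather: WeatherSeries,
    plan: TreatmentPlan,
    consts: EmulatorConstants = DEFAULT_CONSTANTS,
    return_detail: bool = False,
):
    """Run the emulator for a batch of parameter sets.

    ``P`` is (B, 21) in physical units, columns in ``PARAMETER_CODES``
    order.  Returns ``(wagt, grain_yield)`` arrays of shape (B,), both
    kg/ha, plus a phenology/grain detail dict when requested.  Raises
    :class:`MaturityError` if any batch member fails to mature within
    the supplied weather (never silently truncates).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(PARAMETER_CODES):
        raise ValueError("P must be (B, 21) in canonical code order")
    B = P.shape[0]
    forcing = _forcing(weather, consts)
    trig = np.tile(plan.trigger_mm()[:, None], (1, B))
    return _simulate_core(
        P, forcing, trig, plan.soil.fc_mm, consts, return_detail
    )


def simulate_cells(
    P_chains: np.ndarray,
    cells: Sequence[tuple[WeatherSeries, TreatmentPlan]],
    consts: EmulatorConstants = DEFAULT_CONSTANTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate R parameter sets across C (weather, treatment) cells at once.

    Returns ``(wagt, grain_yield)`` of shape (R, C).  All cells must
    share the same season length and soil; used by the calibration
    likelihood, where one Metropolis step needs every chain evaluated
    in every observation cell.
    """
    P_chains = np.asarray(P_chains, dtype=float)
    R = P_chains.shape[0]
    C = len(cells)
    days = {w.season_days for w, _ in cells}
    if len(days) != 1:
        raise ValueError("all cells must share one season length")
    fcs = {plan.soil.fc_mm for _, plan in cells}
    if len(fcs) != 1:
        raise ValueError("all cells must share one soil profile")
    keys = ("radn", "rain", "tt", "tt_dev", "tgrow", "refd", "coldpen")
    per_cell = [_forcing(w, consts) for w, _ in cells]
    forcing = {
        k: np.tile(np.column_stack([f[k] for f in per_cell]), (1, R))
        for k in keys
    }
    forcing["winter"] = np.tile(
        np.column_stack([f["winter"] for f in per_cell]), (1, R)
    )
    forcing["winter_start"] = np.tile(
        np.array([f["winter_start"] for f in per_cell]), R
    )
    forcing["days"] = per_cell[0]["days"]
    trig = np.tile(
        np.column_stack([plan.trigger_mm() for _, plan in cells]), (1, R)
    )
    P = np.repeat(P_chains, C, axis=0)
    wagt, grain_yield = _simulate_core(
        P, forcing, trig, cells[0][1].soil.fc_mm, consts, False
    )
    return wagt.reshape(R, C), grain_yield.reshape(R, C)


def _simulate_core(
    P: np.ndarray,
    forcing: dict,
    trig: np.ndarray,
    fcmm: float,
    consts: EmulatorConstants,
    return_detail: bool,
):
    B = P.shape[0]
    D = forcing["days"]
    radn = forcing["radn"]
    rain = forcing["rain"]
    tt = forcing["tt"]
    tt_dev = forcing["tt_dev"]
    tgrow = forcing["tgrow"]
    refd = forcing["refd"]
    coldpen = forcing["coldpen"]
    winter = forcing["winter"]
    winter_start = forcing["winter_start"]

    # --- per-member parameters ---
    g = lambda c: P[:, _IDX[c]]
    p1, p2, p3, m1 = g("P1"), g("P2"), g("P3"), g("M1")
    p4, v1, g1, m2 = g("P4"), g("V1"), g("G1"), g("M2")
    t1, t2, t3, t4 = g("T1"), g("T2"), g("T3"), g("T4")
    kpar, r1, y1, i1 = g("K"), g("R1"), g("Y1"), g("I1")
    s1, e1, n1, i2, x1 = g("S1"), g("E1"), g("N1"), g("I2"), g("X1")

    devscale = 1.0 / (1.0 + consts.dev_slow * (p4 + v1))
    c1 = t1
    c2 = c1 + t2
    c3 = c2 + t3
    c4 = c3 + t4
    keff = consts.k_floor + consts.k_scale * kpar
    nfac = 1.0 + consts.n1_weight * (np.clip(2.0 - 0.5 * n1, 0.5, 1.25) - 1.0)
    gset = (
        (t3 / consts.gset_ref) ** consts.gset_exp
        * (t1 / consts.t1_ref) ** consts.t1_exp
        * (t2 / consts.t2_ref) ** consts.t2_exp
    )
    sink_rate = p1 * consts.fill_eff
    lag_rate = p2 * consts.lag_eff
    n_drain = consts.n_cost * 0.5 * (m1 + p3)
    lai0 = i1 * 1e-6 * consts.plant_density
    lai_rate = (
        consts.lai_tt_rate
        * (y1 / consts.y1_mid) ** consts.y1_exp
        * (i1 / consts.i1_mid) ** consts.i1_exp
    )
    cols = np.arange(B)

    # --- state ---
    cumtt = np.zeros(B)
    stage = np.zeros(B, dtype=np.int64)
    lai = lai0.copy()
    w = np.zeros(B)
    moist = np.full(B, fcmm)
    grains = np.zeros(B)
    grain_m = np.zeros(B)
    reserve = np.zeros(B)
    lai_at_gf = np.zeros(B)
    w_joint = np.zeros(B)
    gf_tt = np.zeros(B)
    flowered = np.zeros(B, dtype=bool)
    gf_started = np.zeros(B, dtype=bool)
    matured = np.zeros(B, dtype=bool)
    d_joint = np.full(B, -1)
    d_flower = np.full(B, -1)
    d_gf = np.full(B, -1)
    d_mat = np.full(B, -1)

    for d in range(D):
        if matured.all():
            break
        active = ~matured

        # phenology
        dev = np.where(stage == 0, devscale, 1.0)
        cumtt = cumtt + tt_dev[d] * dev * active
        new_stage = (
            (cumtt >= c1).astype(np.int64)
            + (cumtt >= c2)
            + (cumtt >= c3)
            + (cumtt >= c4)
        )
        just_joint = (new_stage >= 1) & (d_joint < 0)
        d_joint[just_joint] = d
        w_joint = np.where(just_joint, w, w_joint)
        just_flower = (new_stage >= 2) & ~flowered
        flowered |= just_flower
        d_flower[just_flower] = d
        just_gf = (new_stage >= 3) & ~gf_started
        basis = np.maximum(w - w_joint, 0.0) + consts.grain_stock_frac * w
        grains = np.where(just_gf, g1 * basis * gset, grains)
        reserve = np.where(just_gf, consts.remob_frac * consts.stem_frac * w, reserve)
        lai_at_gf = np.where(just_gf, lai, lai_at_gf)
        gf_started |= just_gf
        d_gf[just_gf] = d
        just_mat = (new_stage >= 4) & ~matured
        d_mat[just_mat] = d
        # fraction of this day's thermal time actually needed to mature
        overshoot = np.where(just_mat & (tt_dev[d] > 1e-9), (cumtt - c4) / np.maximum(tt_dev[d], 1e-9), 0.0)
        dayfrac = np.clip(1.0 - overshoot, 0.0, 1.0)
        stage = new_stage

        # irrigation phase: seedling/wintering/greening resolved by the
        # calendar winter window, later phases by development stage
        phase = np.where(
            winter[d],
            1,
            np.where(
                stage == 0,
                np.where(d < winter_start, 0, 2),
                np.minimum(stage + 2, 6),
            ),
        )
        thresh = trig[phase, cols]

        # water bucket with proportional drip irrigation toward the trigger
        demand = np.minimum(e1 * refd[d], consts.demand_cap)
        supply = np.minimum(demand, consts.ku * moist)
        wstress = np.where(demand > 1e-9, np.clip(supply / np.maximum(demand, 1e-12), 0.0, 1.0), 1.0)
        setpoint = thresh + consts.quota_frac * (fcmm - thresh)
        irrig = consts.irr_rate * np.maximum(setpoint - moist, 0.0)
        moist = np.clip(moist - supply + rain[d] + irrig, 0.0, fcmm)

        # interception and growth: whole-shoot extinction on the green
        # (non-senesced) area; during grain fill K additionally sets the
        # exportable-to-grain share of assimilate via green-leaf
        # interception efficiency
        in_fill = stage == 3
        green = lai_at_gf * np.clip(1.0 - consts.gf_sen * gf_tt / t4, consts.min_green, 1.0)
        f = 1.0 - np.exp(-keff * np.where(in_fill, green, lai))
        export = 1.0 - np.exp(-(consts.k_gf_floor + consts.k_gf_scale * kpar) * green)
        growing = active & (stage <= 3)
        wfac = np.where(
            stage <= 1,
            wstress ** consts.veg_stress_exp,
            np.where(in_fill, wstress ** consts.gf_stress_exp, wstress),
        )
        dw = r1 * radn[d] * f * wfac * nfac * tgrow[d] * growing
        dw = np.where(just_mat, dw * dayfrac, dw)
        w = w + dw

        # canopy expansion (thermal-time paced; slower after jointing,
        # none after flowering) and stress senescence
        dlai = lai_rate * tt_dev[d] * np.where(
            stage == 0, dev, consts.lai_rate1 * (stage == 1)
        )
        sen = consts.sen_fac * s1 * (1.0 - wstress) * lai
        lai = np.minimum(np.maximum(lai + dlai - sen, 0.01), i2)

        # grain filling
        lagging = active & (stage == 2)
        grain_m = grain_m + lag_rate * tgrow[d] * lagging
        filling = active & (stage == 3)
        source_pg = (consts.fill_frac * dw * export + consts.res_flow * reserve) / np.maximum(grains, 1.0)
        sink_pg = sink_rate * (1.0 - x1 * coldpen[d])
        q = consts.colimit_q
        rate = (
            np.maximum(sink_pg, 1e-12) ** -q + np.maximum(source_pg, 1e-12) ** -q
        ) ** (-1.0 / q)
        grain_m = np.minimum(grain_m + rate * filling, m2)
        reserve = np.maximum(reserve * (1.0 - consts.res_flow * filling) - grains * n_drain * filling, 0.0)
        gf_tt = gf_tt + tt_dev[d] * np.where(just_mat, dayfrac, 1.0) * filling
        matured = matured | just_mat

    if not matured.all():
        n_bad = int((~matured).sum())
        raise MaturityError(
            f"{n_bad}/{B} parameter sets did not reach maturity within "
            f"{D} days of weather; supply a longer series"
        )

    wagt = 10.0 * w
    grain_yield = np.minimum(grains * grain_m, consts.hi_max * w) * 10.0
    if return_detail:
        detail = {
            "day_jointing": d_joint,
            "day_flowering": d_flower,
            "day_grain_fill": d_gf,
            "day_maturity": d_mat,
            "grain_number": grains,
            "grain_mass": grain_m,
        }
        return wagt, grain_yield, detail
    return wagt, grain_yield


class WheatEmulator:
    """Adapter-contract wrapper around :func:`simulate_batch`."""

    name = "wheatsa synthetic wheat emulator"
    output_variables = ("wagt", "yield")

    def __init__(self, consts: EmulatorConstants = DEFAULT_CONSTANTS, specs=None):
        self.consts = consts
        self.specs = list(specs) if specs is not None else load_bounds()

    def _to_matrix(self, params: Mapping[str, float]) -> np.ndarray:
        missing = [c for c in PARAMETER_CODES if c not in params]
        if missing:
            raise ValueError(f"incomplete parameter set, missing {missing}")
        # bounds check through the registry
        ps = params if isinstance(params, ParameterSet) else ParameterSet(params)
        ps.validate(self.specs, complete=True)
        return np.array([[params[c] for c in PARAMETER_CODES]])

    def evaluate(
        self,
        params: Mapping[str, float],
        weather: WeatherSeries,
        plan: TreatmentPlan,
    ) -> SimOutput:
        wagt, grain_yield = simulate_batch(
            self._to_matrix(params), weather, plan, self.consts
        )
        return SimOutput(wagt=float(wagt[0]), grain_yield=float(grain_yield[0]))

    def evaluate_batch(
        self, P: np.ndarray, weather: WeatherSeries, plan: TreatmentPlan
    ) -> tuple[np.ndarray, np.ndarray]:
        return simulate_batch(P, weather, plan, self.consts)


def run_emulator(
    params: Mapping[str, float],
    weather: WeatherSeries,
    plan: TreatmentPlan,
    consts: EmulatorConstants = DEFAULT_CONSTANTS,
) -> SimOutput:
    """Single-point convenience wrapper honoring the adapter contract."""
    return WheatEmulator(consts=consts).evaluate(params, weather, plan)
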