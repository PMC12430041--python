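"""Synthetic weather, soil, and irrigation-treatment inputs.

Emulates the study conditions of an arid continental winter-wheat site
(annual precipitation near 190 mm, annual mean temperature near 6.5 degC,
mid-September sowing): a harmonic seasonal temperature cycle with a deep
winter, clear-sky-like seasonal radiation, sparse precipitation events,
a single-bucket soil store at 26.15% volumetric field capacity, and the
six soil-moisture treatments W1-W6 defined by phase-wise lower irrigation
limits at 50/65/80% of field capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Growth phases used by the irrigation treatment plans, in season order.
PHASES = (
    "seedling",
    "wintering",
    "greening",
    "jointing",
    "heading",
    "grain_filling",
    "maturity",
)

#: Phase-wise lower irrigation limits (% of field capacity) per treatment.
TREATMENT_TABLE: dict[str, tuple[int, ...]] = {
    #       seed win  green joint head  fill  mat
    "W1": (65, 65, 65, 65, 65, 65, 65),
    "W2": (65, 65, 65, 65, 50, 50, 65),
    "W3": (65, 65, 65, 65, 80, 80, 65),
    "W4": (65, 65, 80, 80, 65, 65, 65),
    "W5": (65, 65, 50, 50, 65, 65, 65),
    "W6": (65, 65, 50, 50, 50, 65, 65),
}

TREATMENT_CODES = tuple(TREATMENT_TABLE)


@dataclass(frozen=True)
class ClimateConfig:
    """Annual-cycle constants of the synthetic site climate.

    The temperature cycle is ``mean - a1*cos(w(doy-phase)) - a2*cos(2w(doy-phase))``;
    the second harmonic deepens the winter and broadens the warm season,
    which is characteristic of the continental target climate and is what
    lets every phenology corner of the parameter bounds reach maturity
    within one season of supplied weather.
    """

    annual_mean_temp: float = 6.5      # degC
    temp_amp1: float = 19.0            # degC, fundamental harmonic
    temp_amp2: float = 5.5             # degC, second harmonic
    coldest_doy: int = 15              # mid-January
    diurnal_range: float = 12.0        # degC, Tmax - Tmin
    temp_noise_sd: float = 1.6         # degC, day-to-day noise on the mean
    half_range_noise_sd: float = 0.8   # degC, noise on the diurnal half-range
    rad_mean: float = 16.5             # MJ m-2 d-1
    rad_amp: float = 10.5              # MJ m-2 d-1
    rad_noise_sd: float = 1.8          # MJ m-2 d-1
    annual_precip: float = 190.0       # mm, expected annual total
    wet_day_prob: float = 0.18         # Bernoulli event probability per day
    sowing_doy: int = 258              # mid-September

    @property
    def wet_day_mean(self) -> float:
        return self.annual_precip / (365.0 * self.wet_day_prob)


CHANGJI = ClimateConfig()


@dataclass
class WeatherSeries:
    """Daily weather for one season, indexed by day-from-sowing."""

    day: np.ndarray     # int, 0..season_days-1
    maxt: np.ndarray    # degC
    mint: np.ndarray    # degC
    rain: np.ndarray    # mm
    radn: np.ndarray    # MJ m-2
    seed: int | None = None
    annual_precip_mm: float | None = None
    annual_mean_temp_c: float | None = None

    def __post_init__(self) -> None:
        n = len(self.day)
        for name in ("maxt", "mint", "rain", "radn"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise ValueError(f"column {name} length mismatch")
        if np.any(self.maxt < self.mint):
            raise ValueError("Tmax < Tmin on some day")
        if np.any(self.rain < 0) or np.any(self.radn < 0):
            raise ValueError("negative rain or radiation")

    @property
    def season_days(self) -> int:
        return len(self.day)

    @property
    def tmean(self) -> np.ndarray:
        return 0.5 * (self.maxt + self.mint)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "maxt": self.maxt, "mint": self.mint,
             "rain": self.rain, "radn": self.radn}
        )

    def write(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, index=False, sep=sep)

    @classmethod
    def read(cls, path) -> "WeatherSeries":
        df = pd.read_csv(path, sep=None, engine="python")
        missing = {"day", "maxt", "mint", "rain", "radn"} - set(df.columns)
        if missing:
            raise ValueError(f"weather file missing columns {sorted(missing)}")
        return cls(
            day=df["day"].to_numpy(int),
            maxt=df["maxt"].to_numpy(float),
            mint=df["mint"].to_numpy(float),
            rain=df["rain"].to_numpy(float),
            radn=df["radn"].to_numpy(float),
        )


def seasonal_mean_temp(doy: np.ndarray, climate: ClimateConfig = CHANGJI) -> np.ndarray:
    """Noise-free daily mean temperature of the annual cycle."""
    w = 2.0 * np.pi * (np.asarray(doy, float) - climate.coldest_doy) / 365.0
    return (climate.annual_mean_temp
            - climate.temp_amp1 * np.cos(w)
            - climate.temp_amp2 * np.cos(2.0 * w))


def seasonal_radiation(doy: np.ndarray, climate: ClimateConfig = CHANGJI) -> np.ndarray:
    """Noise-free clear-sky-like daily radiation of the annual cycle."""
    w = 2.0 * np.pi * (np.asarray(doy, float) - climate.coldest_doy) / 365.0
    return climate.rad_mean - climate.rad_amp * np.cos(w)


def generate_weather(
    seed: int = 0,
    season_days: int = 365,
    climate: ClimateConfig = CHANGJI,
) -> WeatherSeries:
    """Generate one season of daily weather starting at sowing.

    Pure in ``(seed, season_days, climate)``.  Annualized precipitation
    and mean temperature are recorded from a full 365-day realization of
    the same stochastic process so they can be checked against the site
    climate regardless of season length.
    """
    if season_days < 30:
        raise ValueError("season_days must be >= 30")
    rng = np.random.default_rng(seed)
    n = max(int(season_days), 365)
    doy = (climate.sowing_doy + np.arange(n)) % 365

    tmean = seasonal_mean_temp(doy, climate) + rng.normal(0.0, climate.temp_noise_sd, n)
    half = np.abs(
        0.5 * climate.diurnal_range + rng.normal(0.0, climate.half_range_noise_sd, n)
    )
    maxt = tmean + half
    mint = tmean - half

    radn = seasonal_radiation(doy, climate) + rng.normal(0.0, climate.rad_noise_sd, n)
    radn = np.clip(radn, 0.5, None)

    wet = rng.random(n) < climate.wet_day_prob
    rain = np.where(wet, rng.exponential(climate.wet_day_mean, n), 0.0)

    annual_precip = float(rain[:365].sum())
    annual_mean = float(tmean[:365].mean())

    s = slice(0, season_days)
    return WeatherSeries(
        day=np.arange(season_days),
        maxt=maxt[s], mint=mint[s], rain=rain[s], radn=radn[s],
        seed=seed,
        annual_precip_mm=annual_precip,
        annual_mean_temp_c=annual_mean,
    )


@dataclass(frozen=True)
class SoilProfile:
    """Single-bucket soil store over the rooting depth."""

    field_capacity: float = 26.15   # volumetric %
    bulk_density: float = 1.62      # g cm-3
    rooting_depth: float = 600.0    # mm

    def __post_init__(self) -> None:
        if not (0.0 < self.field_capacity < 100.0):
            raise ValueError("field capacity must be in (0, 100) volumetric %")
        if self.bulk_density <= 0:
            raise ValueError("bulk density must be positive")

    @property
    def fc_mm(self) -> float:
        """Water stored at field capacity over the rooting depth (mm)."""
        return self.field_capacity / 100.0 * self.rooting_depth


@dataclass(frozen=True)
class TreatmentPlan:
    """Phase-wise lower irrigation limits for one treatment.

    ``lower_limits`` are % of field capacity; ``smc`` is the derived
    allowable depletion per phase in volumetric % (field capacity minus
    the trigger level).
    """

    code: str
    lower_limits: tuple[float, ...]          # % FC, one per phase
    soil: SoilProfile = field(default_factory=SoilProfile)

    def __post_init__(self) -> None:
        if len(self.lower_limits) != len(PHASES):
            raise ValueError("one lower limit per growth phase required")
        if any(v not in (50, 65, 80) for v in self.lower_limits):
            raise ValueError("lower limits must be in {50, 65, 80} %FC")

    @property
    def smc(self) -> tuple[float, ...]:
        """Allowable depletion per phase, volumetric % (FC x (1 - limit))."""
        fc = self.soil.field_capacity
        return tuple(fc * (1.0 - v / 100.0) for v in self.lower_limits)

    def trigger_mm(self) -> np.ndarray:
        """Irrigation trigger level per phase in mm of stored water."""
        return np.array(
            [self.soil.fc_mm * v / 100.0 for v in self.lower_limits]
        )


def build_treatment(code: str, soil: SoilProfile | None = None) -> TreatmentPlan:
    """Instantiate one of the six study treatments W1-W6."""
    if code not in TREATMENT_TABLE:
        raise KeyError(f"unknown treatment code {code!r}; expected one of {TREATMENT_CODES}")
    return TreatmentPlan(
        code=code,
        lower_limits=tuple(float(v) for v in TREATMENT_TABLE[code]),
        soil=soil or SoilProfile(),
    )


def generate_observations(
    simulate,
    true_params: Mapping[str, float],
    treatments: Sequence[TreatmentPlan],
    weather_by_year: Mapping[int, WeatherSeries],
    noise_sd: float = 300.0,
    seed: int = 0,
    variables: Sequence[str] = ("wagt", "yield"),
) -> pd.DataFrame:
    """Synthetic observed records: emulator truth plus Gaussian noise.

    ``simulate`` is any adapter-contract callable
    ``(params, weather, plan) -> SimOutput``.  Returns a tidy frame with
    columns ``treatment, year, variable, value`` (kg ha-1).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for year, weather in weather_by_year.items():
        for plan in treatments:
            out = simulate(true_params, weather, plan)
            truth = {"wagt": out.wagt, "yield": out.grain_yield}
            for var in variables:
                rows.append(
                    {
                        "treatment": plan.code,
                        "year": int(year),
                        "variable": var,
                        "value": truth[var] + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)
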