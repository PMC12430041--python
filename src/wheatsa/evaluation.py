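"""Goodness-of-fit metrics and performance grading for simulated yields.

Six agreement statistics between observed and predicted series — R^2
(squared Pearson correlation), Willmott's index of agreement d, RMSE,
MAE, Nash-Sutcliffe efficiency NSE, and the RMSE-to-observed-SD ratio
RSR — plus a Moriasi-style grade.  Population (divide-by-n) variance is
used throughout so the identity RSR^2 = 1 - NSE holds exactly.

Grade bands (NSE lower bound exclusive, RSR upper bound inclusive):
Excellent NSE > 0.75, RSR <= 0.50; Good NSE > 0.65, RSR <= 0.60;
Satisfactory NSE > 0.50, RSR <= 0.70; otherwise Unacceptable.  The
bands are data (``GRADE_BANDS``), not logic, and may be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: (label, NSE lower bound (exclusive), RSR upper bound (inclusive)),
#: best band first; a row must pass both limits to earn the label.
GRADE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("Excellent", 0.75, 0.50),
    ("Good", 0.65, 0.60),
    ("Satisfactory", 0.50, 0.70),
)

UNACCEPTABLE = "Unacceptable"


@dataclass(frozen=True)
class FitMetrics:
    """Agreement statistics for one observed/predicted series pair."""

    r2: float
    d_index: float
    rmse: float
    mae: float
    nse: float
    rsr: float
    grade: str
    n: int


def grade(nse: float, rsr: float, bands=GRADE_BANDS) -> str:
    """Grade label from (NSE, RSR); the worse of the two bands wins."""
    for label, nse_lo, rsr_hi in bands:
        if nse > nse_lo and rsr <= rsr_hi:
            return label
    return UNACCEPTABLE


def fit_metrics(observed, predicted, bands=GRADE_BANDS) -> FitMetrics:
    """All six metrics plus the grade for one series pair."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    n = len(o)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    o_mean = o.mean()
    sd_o = o.std()  # population convention, consistent with NSE
    if sd_o == 0.0:
        raise ValueError("observed series has zero variance")
    resid = p - o
    sse = float(np.sum(resid**2))
    rmse = float(np.sqrt(sse / n))
    mae = float(np.mean(np.abs(resid)))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(o, p)[0, 1]
    r2 = float(r**2) if np.isfinite(r) else 0.0
    d_index = float(
        1.0 - sse / np.sum((np.abs(p - o_mean) + np.abs(o - o_mean)) ** 2)
    )
    nse = float(1.0 - sse / np.sum((o - o_mean) ** 2))
    rsr = float(rmse / sd_o)
    return FitMetrics(
        r2=r2, d_index=d_index, rmse=rmse, mae=mae, nse=nse, rsr=rsr,
        grade=grade(nse, rsr, bands), n=n,
    )


def evaluation_report(
    observations: pd.DataFrame,
    parameter_sets: Mapping[str, Mapping[str, float]],
    simulate,
    treatments: Sequence,
    weather_by_year: Mapping[int, object],
    variable: str = "yield",
) -> pd.DataFrame:
    """Year-by-year evaluation table for several candidate parameter sets.

    ``observations`` is tidy (treatment, year, variable, value);
    ``parameter_sets`` maps a label (e.g. ``Default`` / ``Optimized``)
    to a complete parameter mapping; ``simulate`` is an adapter-contract
    callable.  Returns one row per year x parameter set with the six
    metrics and the grade — the shape of the published evaluation table.
    """
    obs = observations[observations["variable"] == variable]
    plan_by_code = {plan.code: plan for plan in treatments}
    rows = []
    for year in sorted(obs["year"].unique()):
        obs_y = obs[obs["year"] == year]
        for label, params in parameter_sets.items():
            o, p = [], []
            for rec in obs_y.itertuples():
                plan = plan_by_code[rec.treatment]
                out = simulate(params, weather_by_year[rec.year], plan)
                pred = {"wagt": out.wagt, "yield": out.grain_yield}[variable]
                o.append(rec.value)
                p.append(pred)
            m = fit_metrics(o, p)
            rows.append(
                {
                    "year": year, "parameter_set": label, "r2": m.r2,
                    "d_index": m.d_index, "rmse": m.rmse, "mae": m.mae,
                    "nse": m.nse, "rsr": m.rsr, "grade": m.grade,
                }
            )
    return pd.DataFrame(rows)
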