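"""Bayesian calibration of influential parameters by random-walk Metropolis.

Uniform priors over the published physical bounds (sampled in the unit
hypercube), a Gaussian observation likelihood

    log L(theta) = sum_j [ -1/2 log(2 pi sigma_o^2)
                           - (O_j - P_j(theta))^2 / (2 sigma_o^2) ]

with per-observation residuals matched by (treatment, year, variable),
and independent Gaussian proposal steps per free coordinate.  Proposals
outside the bounds are rejected (the uniform prior's density is zero
there).  By default only the eight yield-influential parameters are
free; the rest are pinned (midpoints unless supplied).

Several independent chains with independent observation sets can run
simultaneously; each Metropolis step then evaluates every chain in
every observation cell through one vectorized emulator call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .emulator import DEFAULT_CONSTANTS, EmulatorConstants, simulate_cells
from .param_space import (
    PARAMETER_CODES as _CODES,
    ParameterSet,
    load_bounds,
    midpoint_defaults,
)
from .synthetic_env import TreatmentPlan, WeatherSeries, build_treatment

#: The eight yield-influential parameters, free by default.
DEFAULT_FREE_CODES = ("K", "T4", "P1", "T2", "E1", "G1", "T1", "T3")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings."""

    free_codes: tuple[str, ...] = DEFAULT_FREE_CODES
    chain_length: int = 4000
    burn_in_frac: float = 0.25
    proposal_scale: float = 0.03   # fraction of each bound width
    sigma_o: float = 300.0         # kg/ha observation SD
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.burn_in_frac < 1.0):
            raise ValueError("burn_in_frac must be in [0, 1)")
        if self.chain_length * (1.0 - self.burn_in_frac) < 2:
            raise ValueError("chain length must exceed burn-in")
        if self.proposal_scale <= 0:
            raise ValueError("proposal scale must be positive")
        if self.sigma_o <= 0:
            raise ValueError("sigma_o must be positive")


@dataclass
class MCMCChain:
    """Post-burn-in draws and summaries for one chain."""

    free_codes: tuple[str, ...]
    draws: np.ndarray          # (n_draws, n_free), physical units
    log_posterior: np.ndarray  # (n_draws,)
    acceptance_rate: float
    config: MCMCConfig
    pinned: ParameterSet = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        q = np.percentile(self.draws, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame(
            {
                "code": self.free_codes,
                "mean": self.draws.mean(axis=0),
                "median": q[1],
                "q2.5": q[0],
                "q97.5": q[2],
            }
        )

    def write(self, path, sep: str = ",") -> None:
        df = pd.DataFrame(self.draws, columns=list(self.free_codes))
        df.insert(0, "draw", np.arange(len(df)))
        df["log_posterior"] = self.log_posterior
        df.to_csv(path, index=False, sep=sep)


def log_likelihood(
    observed: np.ndarray, predicted: np.ndarray, sigma_o: float
) -> float:
    """Gaussian log-likelihood with per-observation residuals."""
    if sigma_o <= 0:
        raise ValueError("sigma_o must be positive")
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size == 0:
        raise ValueError("observations must be nonempty")
    if o.shape != p.shape:
        raise ValueError("observed/predicted shape mismatch")
    m = o.size
    return float(
        -0.5 * m * np.log(2.0 * np.pi * sigma_o**2)
        - np.sum((o - p) ** 2) / (2.0 * sigma_o**2)
    )


def _observation_layout(observations: pd.DataFrame):
    """Cells (treatment, year) and per-record (cell index, variable index)."""
    cells = sorted(
        {(r.treatment, int(r.year)) for r in observations.itertuples()}
    )
    cell_index = {c: i for i, c in enumerate(cells)}
    var_index = {"wagt": 0, "yield": 1}
    rec_cell = np.array(
        [cell_index[(r.treatment, int(r.year))] for r in observations.itertuples()]
    )
    rec_var = np.array(
        [var_index[r.variable] for r in observations.itertuples()]
    )
    values = observations["value"].to_numpy(float)
    return cells, rec_cell, rec_var, values


def predict_observations(
    params: Mapping[str, float],
    observations: pd.DataFrame,
    weather_by_year: Mapping[int, WeatherSeries],
    treatments: Sequence[TreatmentPlan] | None = None,
    consts: EmulatorConstants = DEFAULT_CONSTANTS,
) -> np.ndarray:
    """Emulator predictions aligned with a tidy observation frame."""
    cells, rec_cell, rec_var, _ = _observation_layout(observations)
    plan_by_code = (
        {p.code: p for p in treatments} if treatments is not None else {}
    )
    cell_objs = [
        (
            weather_by_year[year],
            plan_by_code.get(code) or build_treatment(code),
        )
        for code, year in cells
    ]
    row = np.array([[params[c] for c in _CODES]])
    wagt, grain_yield = simulate_cells(row, cell_objs, consts)
    both = np.stack([wagt[0], grain_yield[0]], axis=1)  # (C, 2)
    return both[rec_cell, rec_var]


def metropolis_unit_cube(
    log_target,
    n_dim: int,
    chain_length: int,
    burn_in_frac: float = 0.25,
    proposal_scale: float = 0.03,
    seed: int = 0,
    n_chains: int = 1,
    adapt_burn_in: bool = True,
):
    """Random-walk Metropolis on [0, 1]^n with a uniform prior.

    ``log_target`` maps a (n_chains, n_dim) state matrix to per-chain
    log densities; proposals leaving the cube are rejected.  During
    burn-in the per-chain step size is adapted toward a 0.25 acceptance
    rate (Robbins-Monro on the log scale) and frozen afterwards, so the
    kept draws come from a fixed, valid kernel.  Returns
    ``(draws, log_density, acceptance_rates)`` with draws of shape
    (n_chains, kept, n_dim) in unit coordinates.  This is the sampling
    core of :func:`run_mcmc`, exposed so its balance can be checked on
    analytic targets.
    """
    rng = np.random.default_rng(seed)
    R = n_chains
    U = np.full((R, n_dim), 0.5)
    lp = np.asarray(log_target(U), dtype=float)
    n_keep = chain_length - int(chain_length * burn_in_frac)
    draws = np.empty((R, n_keep, n_dim))
    lp_trace = np.empty((R, n_keep))
    accepted = np.zeros(R)
    keep0 = chain_length - n_keep
    scale = np.full(R, proposal_scale)
    # running moments for the covariance proposal (Haario-style),
    # refreshed with diminishing frequency through the whole run
    mean = np.zeros((R, n_dim))
    m2 = np.zeros((R, n_dim, n_dim))
    n_mom = 0
    chol = np.tile(np.eye(n_dim), (R, 1, 1))
    cov_start = max(100, n_dim * 20) if adapt_burn_in else chain_length + 1
    for step in range(chain_length):
        z = rng.normal(0.0, 1.0, size=(R, n_dim))
        prop = U + scale[:, None] * np.einsum("rij,rj->ri", chol, z)
        inside = np.all((prop >= 0.0) & (prop <= 1.0), axis=1)
        prop_eval = np.where(inside[:, None], prop, U)
        lp_prop = np.asarray(log_target(prop_eval), dtype=float)
        accept = inside & (np.log(rng.random(R)) < (lp_prop - lp))
        U = np.where(accept[:, None], prop, U)
        lp = np.where(accept, lp_prop, lp)
        if adapt_burn_in:
            gamma = 3.0 / (10.0 + step)
            scale = np.clip(
                scale * np.exp(gamma * (accept.astype(float) - 0.25)),
                1e-5, 0.5,
            )
            n_mom += 1
            delta = U - mean
            mean += delta / n_mom
            m2 += np.einsum("ri,rj->rij", delta, U - mean)
            if step >= cov_start and n_mom > n_dim and step % 25 == 0:
                cov = m2 / (n_mom - 1)
                cov += 1e-7 * np.eye(n_dim)
                try:
                    new_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    new_chol = chol
                # renormalize so `scale` keeps its step-size meaning
                norms = np.sqrt(
                    np.einsum("rij,rij->r", new_chol, new_chol) / n_dim
                )
                chol = new_chol / np.maximum(norms, 1e-12)[:, None, None]
        if step >= keep0:
            accepted += accept
            draws[:, step - keep0] = U
            lp_trace[:, step - keep0] = lp
    return draws, lp_trace, accepted / max(n_keep, 1)


def run_mcmc(
    config: MCMCConfig,
    observations: pd.DataFrame,
    weather_by_year: Mapping[int, WeatherSeries],
    treatments: Sequence[TreatmentPlan] | None = None,
    pinned: Mapping[str, float] | None = None,
    specs=None,
    consts: EmulatorConstants = DEFAULT_CONSTANTS,
) -> MCMCChain:
    """Sample the posterior of the free parameters for one observation set."""
    return run_mcmc_replicates(
        config, [observations], weather_by_year, treatments, pinned, specs, consts
    )[0]


def run_mcmc_replicates(
    config: MCMCConfig,
    observation_sets: Sequence[pd.DataFrame],
    weather_by_year: Mapping[int, WeatherSeries],
    treatments: Sequence[TreatmentPlan] | None = None,
    pinned: Mapping[str, float] | None = None,
    specs=None,
    consts: EmulatorConstants = DEFAULT_CONSTANTS,
) -> list[MCMCChain]:
    """Run independent chains, one per observation set, in lockstep.

    All observation sets must share the same (treatment, year, variable)
    layout; every Metropolis step evaluates all chains in all cells
    through a single vectorized emulator call.
    """
    specs = list(specs) if specs is not None else load_bounds()
    by_code = {s.code: s for s in specs}
    unknown = set(config.free_codes) - set(by_code)
    if unknown:
        raise ValueError(f"unknown free codes: {sorted(unknown)}")
    free = list(config.free_codes)
    n_free = len(free)
    R = len(observation_sets)

    layouts = [_observation_layout(obs) for obs in observation_sets]
    cells0 = layouts[0][0]
    for lay in layouts[1:]:
        if lay[0] != cells0 or not (
            np.array_equal(lay[1], layouts[0][1])
            and np.array_equal(lay[2], layouts[0][2])
        ):
            raise ValueError("observation sets must share one layout")
    rec_cell, rec_var = layouts[0][1], layouts[0][2]
    O = np.stack([lay[3] for lay in layouts])  # (R, M)
    M = O.shape[1]
    if M == 0:
        raise ValueError("observations must be nonempty")

    plan_by_code = (
        {p.code: p for p in treatments} if treatments is not None else {}
    )
    cell_objs = [
        (weather_by_year[year], plan_by_code.get(code) or build_treatment(code))
        for code, year in cells0
    ]

    base = midpoint_defaults(specs)
    if pinned:
        base.update(pinned)
    base_row = np.array([base[c] for c in _CODES])
    free_idx = np.array([_CODES.index(c) for c in free])
    lo = np.array([by_code[c].lower for c in free])
    width = np.array([by_code[c].width for c in free])

    def predict(U: np.ndarray) -> np.ndarray:
        P = np.tile(base_row, (R, 1))
        P[:, free_idx] = lo + U * width
        wagt, grain_yield = simulate_cells(P, cell_objs, consts)
        both = np.stack([wagt, grain_yield], axis=2)  # (R, C, 2)
        return both[:, rec_cell, rec_var]             # (R, M)

    def loglik(pred: np.ndarray) -> np.ndarray:
        return (
            -0.5 * M * np.log(2.0 * np.pi * config.sigma_o**2)
            - np.sum((O - pred) ** 2, axis=1) / (2.0 * config.sigma_o**2)
        )

    unit_draws, lp_trace, rates = metropolis_unit_cube(
        lambda U: loglik(predict(U)),
        n_dim=n_free,
        chain_length=config.chain_length,
        burn_in_frac=config.burn_in_frac,
        proposal_scale=config.proposal_scale,
        seed=config.seed,
        n_chains=R,
    )
    if np.any(rates == 0.0):
        raise RuntimeError(
            "a chain accepted no proposals; proposal scale is pathological"
        )
    return [
        MCMCChain(
            free_codes=tuple(free),
            draws=lo + unit_draws[r] * width,
            log_posterior=lp_trace[r],
            acceptance_rate=float(rates[r]),
            config=config,
            pinned=ParameterSet(base),
        )
        for r in range(R)
    ]


def posterior_point_estimate(chain: MCMCChain, kind: str = "mean") -> ParameterSet:
    """Posterior mean (default) or MAP draw, merged over pinned values.

    Returns a complete 21-parameter set: free codes from the chain,
    everything else from the pinned baseline.
    """
    if len(chain.draws) == 0:
        raise ValueError("empty chain")
    if kind == "mean":
        vals = chain.draws.mean(axis=0)
    elif kind == "map":
        vals = chain.draws[np.argmax(chain.log_posterior)]
    else:
        raise ValueError("kind must be 'mean' or 'map'")
    full = ParameterSet(chain.pinned)
    full.update(dict(zip(chain.free_codes, vals)))
    return full
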