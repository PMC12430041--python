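"""Morris elementary-effects screening.

One-at-a-time trajectories on a p-level grid in the unit hypercube; for
each single-factor move of size +/-Delta the elementary effect is the
finite difference of the output, and each factor is summarized by the
mean absolute effect mu* (main influence), the signed mean mu, and the
standard deviation sigma (interaction/nonlinearity strength).  Effects
are computed in unit-hypercube coordinates, i.e. per unit of normalized
parameter range, so mu* is directly comparable across parameters with
different physical units.  A factor is classified influential when its
mu* exceeds the across-factor mean of mu* (the top-ranked factor is
always retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class TrajectoryDesign:
    """t random trajectories of n+1 points each on a p-level grid."""

    n: int
    p: int
    t: int
    delta: float
    points: np.ndarray        # (t*(n+1), n), unit hypercube
    moved_factor: np.ndarray  # (t, n) factor index of each step
    step_sign: np.ndarray     # (t, n) +1 / -1
    seed: int | None = None

    @property
    def n_evaluations(self) -> int:
        return self.t * (self.n + 1)

    def trajectory(self, k: int) -> np.ndarray:
        return self.points[k * (self.n + 1): (k + 1) * (self.n + 1)]


@dataclass(frozen=True)
class MorrisSummary:
    """Per-factor mu, mu*, sigma with mu*-descending ranks."""

    table: pd.DataFrame  # columns: factor, mu, mu_star, sigma, rank, influential

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank")["factor"])

    def write(self, path, sep: str = ",") -> None:
        self.table.to_csv(path, index=False, sep=sep)


def build_trajectories(n: int, p: int = 4, t: int = 10, seed: int = 0) -> TrajectoryDesign:
    """Random Morris trajectories with Delta = p / (2(p-1)).

    Base points sit on the grid {0, 1/(p-1), ..., 1}; each trajectory
    perturbs every factor exactly once, in random order and direction,
    and every point stays inside [0, 1].
    """
    if p < 2 or p % 2 != 0:
        raise ValueError("p must be even and >= 2 for Delta = p/(2(p-1))")
    if t < 2:
        raise ValueError("at least 2 trajectories required")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    delta = p / (2.0 * (p - 1))
    levels = np.arange(p) / (p - 1)
    pts = np.empty((t * (n + 1), n))
    moved = np.empty((t, n), dtype=np.int64)
    signs = np.empty((t, n), dtype=np.int64)
    for k in range(t):
        x = levels[rng.integers(0, p, size=n)].astype(float)
        order = rng.permutation(n)
        row = k * (n + 1)
        # clamp the base so the chosen direction stays inside [0, 1]
        dirs = rng.choice([-1.0, 1.0], size=n)
        for j, i in enumerate(order):
            if dirs[i] > 0 and x[i] + delta > 1.0 + 1e-12:
                dirs[i] = -1.0
            elif dirs[i] < 0 and x[i] - delta < -1e-12:
                dirs[i] = 1.0
        pts[row] = x
        for j, i in enumerate(order):
            x = x.copy()
            x[i] = x[i] + dirs[i] * delta
            pts[row + j + 1] = x
            moved[k, j] = i
            signs[k, j] = int(dirs[i])
    pts = np.clip(pts, 0.0, 1.0)
    return TrajectoryDesign(
        n=n, p=p, t=t, delta=delta, points=pts,
        moved_factor=moved, step_sign=signs, seed=seed,
    )


def elementary_effects(design: TrajectoryDesign, outputs: np.ndarray) -> np.ndarray:
    """Elementary effects per factor from outputs aligned with the design.

    Returns an (t, n) array: one effect per trajectory per factor,
    EE = (y_after - y_before) / (signed step).
    """
    y = np.asarray(outputs, dtype=float)
    if y.shape != (design.n_evaluations,):
        raise ValueError(
            f"expected {design.n_evaluations} outputs, got {y.shape}"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite model output in Morris replay")
    ee = np.empty((design.t, design.n))
    for k in range(design.t):
        row = k * (design.n + 1)
        dy = np.diff(y[row: row + design.n + 1])
        step = design.step_sign[k] * design.delta
        ee[k, design.moved_factor[k]] = dy / step
    return ee


def summarize(
    effects: np.ndarray, factor_names: Sequence[str] | None = None
) -> MorrisSummary:
    """mu, mu* (mean absolute), sigma (sample SD) and mu*-ranks per factor."""
    ee = np.asarray(effects, dtype=float)
    if ee.ndim != 2 or ee.shape[0] < 2:
        raise ValueError("need >= 2 elementary effects per factor")
    n = ee.shape[1]
    names = list(factor_names) if factor_names is not None else [f"x{i+1}" for i in range(n)]
    mu = ee.mean(axis=0)
    mu_star = np.abs(ee).mean(axis=0)
    sigma = ee.std(axis=0, ddof=1)
    rank = rankdata(-mu_star, method="ordinal").astype(int)
    influential = mu_star > mu_star.mean()
    table = pd.DataFrame(
        {
            "factor": names,
            "mu": mu,
            "mu_star": mu_star,
            "sigma": sigma,
            "rank": rank,
            "influential": influential,
        }
    )
    return MorrisSummary(table=table)


def classify_influential(summary: MorrisSummary) -> set[str]:
    """Factors whose mu* strictly exceeds the across-factor mean mu*."""
    t = summary.table
    return set(t.loc[t["influential"], "factor"])


def run_morris(
    func: Callable[[np.ndarray], np.ndarray],
    n: int,
    p: int = 4,
    t: int = 10,
    seed: int = 0,
    factor_names: Sequence[str] | None = None,
) -> MorrisSummary:
    """Convenience driver: design -> batch evaluate -> summarize.

    ``func`` maps an (N, n) unit-hypercube matrix to (N,) outputs.
    """
    design = build_trajectories(n=n, p=p, t=t, seed=seed)
    y = np.asarray(func(design.points), dtype=float)
    return summarize(elementary_effects(design, y), factor_names)
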