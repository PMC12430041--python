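"""Top-down concordance of sensitivity rankings (Savage scores, TDCC).

Agreement between m repeated sensitivity rankings of n factors is
measured with the top-down concordance coefficient: ranks are replaced
by Savage scores ss(r) = sum_{i=r}^{n} 1/i, which up-weight the top of
the ranking, and

    C_T = [sum_i (sum_j ss_ij)^2 - m^2 n] / [m^2 (n - sum_{i=1}^n 1/i)]

equals 1 for identical rankings.  Significance uses T = m (n-1) C_T,
asymptotically chi-squared with n-1 degrees of freedom under the null
of unrelated rankings; p < 0.05 flags significant consistency (p < 0.01
highly significant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata


@dataclass(frozen=True)
class RankMatrix:
    """n factors x m repetitions of ranks (1 = most sensitive)."""

    ranks: np.ndarray                 # (n, m) integer-valued (ties averaged)
    factors: tuple[str, ...]
    repetitions: tuple[str, ...]

    def __post_init__(self) -> None:
        n, m = self.ranks.shape
        if len(self.factors) != n or len(self.repetitions) != m:
            raise ValueError("label lengths must match the rank matrix shape")
        colsum = self.ranks.sum(axis=0)
        if not np.allclose(colsum, n * (n + 1) / 2):
            raise ValueError("each column must be a (tie-averaged) ranking of 1..n")


@dataclass(frozen=True)
class TDCCResult:
    """Concordance coefficient with its chi-squared significance."""

    c_t: float
    t_stat: float
    dof: int
    p_value: float
    n: int
    m: int

    @property
    def significant(self) -> bool:
        """Significant consistency at the 0.05 level."""
        return self.p_value < 0.05

    @property
    def highly_significant(self) -> bool:
        return self.p_value < 0.01


def rank_sensitivities(values: np.ndarray) -> np.ndarray:
    """Ranks per column, 1 = largest sensitivity measure; ties averaged."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return np.apply_along_axis(lambda c: rankdata(-c, method="average"), 0, values)


def savage_scores(ranks: Sequence[float]) -> np.ndarray:
    """Savage scores for one ranking; ss(r) = sum_{i=r}^{n} 1/i.

    Accepts tie-averaged ranks: tied items receive the mean of the
    Savage scores their positions span, preserving sum(ss) = n exactly.
    """
    r = np.asarray(ranks, dtype=float)
    n = len(r)
    order = np.sort(r)
    if not np.allclose(order.sum(), n * (n + 1) / 2):
        raise ValueError("ranks must be a permutation of 1..n (ties averaged)")
    base = np.cumsum(1.0 / np.arange(n, 0, -1))[::-1]  # ss for ranks 1..n
    out = np.empty(n)
    for rank_value in np.unique(r):
        idx = np.nonzero(r == rank_value)[0]
        k = len(idx)
        # positions spanned by this (possibly tied) rank value
        start = int(round(rank_value - (k - 1) / 2.0))
        out[idx] = base[start - 1: start - 1 + k].mean()
    return out


def tdcc(matrix: RankMatrix | np.ndarray) -> TDCCResult:
    """Top-down concordance coefficient of an n x m rank matrix."""
    ranks = matrix.ranks if isinstance(matrix, RankMatrix) else np.asarray(matrix, float)
    n, m = ranks.shape
    if n < 2:
        raise ValueError("need at least 2 factors (denominator vanishes at n = 1)")
    if m < 2:
        raise ValueError("need at least 2 repetitions")
    ss = np.column_stack([savage_scores(ranks[:, j]) for j in range(m)])
    row_sums = ss.sum(axis=1)
    denom = m**2 * (n - np.sum(1.0 / np.arange(1, n + 1)))
    c_t = (np.sum(row_sums**2) - m**2 * n) / denom
    t_stat = m * (n - 1) * c_t
    dof = n - 1
    p = float(chi2.sf(t_stat, dof))
    return TDCCResult(c_t=float(c_t), t_stat=float(t_stat), dof=dof, p_value=p, n=n, m=m)


def consistency_report(
    rankings: Mapping[str, Mapping[str, Sequence[str]]],
    mode: str = "columns",
) -> pd.DataFrame:
    """TDCC table across treatments, shaped like the study's result tables.

    ``rankings[cell][treatment]`` is an ordered factor list (most
    sensitive first) for one (year, variable) cell and treatment.  Two
    groupings are supported, because the source tables' per-treatment
    grouping is ambiguous:

    - ``columns``: all m treatments enter one rank matrix per cell,
      giving a single TDCC per cell (reported once per treatment-less
      row; the ``treatment`` column then reads ``all``).
    - ``consensus``: each treatment is paired with the consensus
      ranking (mean Savage score across treatments), giving one TDCC
      per treatment as in the published layout.

    Returns a tidy frame: cell, treatment, tdcc, t_stat, p.
    """
    if mode not in ("columns", "consensus"):
        raise ValueError("mode must be 'columns' or 'consensus'")
    rows = []
    for cell, per_treatment in rankings.items():
        treatments = list(per_treatment)
        if len(treatments) < 2:
            raise ValueError(f"cell {cell!r}: need >= 2 treatments")
        factors = sorted(per_treatment[treatments[0]])
        rank_cols = []
        for tr in treatments:
            order = list(per_treatment[tr])
            if sorted(order) != factors:
                raise ValueError(f"cell {cell!r}: inconsistent factor sets")
            rank_cols.append([order.index(f) + 1 for f in factors])
        ranks = np.array(rank_cols, dtype=float).T  # (n, m)
        if mode == "columns":
            res = tdcc(ranks)
            rows.append(
                {"cell": cell, "treatment": "all", "tdcc": res.c_t,
                 "t_stat": res.t_stat, "p": res.p_value}
            )
        else:
            ss = np.column_stack([savage_scores(ranks[:, j]) for j in range(ranks.shape[1])])
            for j, tr in enumerate(treatments):
                consensus = ss[:, [k for k in range(ranks.shape[1]) if k != j]].mean(axis=1)
                consensus_rank = rankdata(-consensus, method="average")
                pair = np.column_stack([ranks[:, j], consensus_rank])
                res = tdcc(pair)
                rows.append(
                    {"cell": cell, "treatment": tr, "tdcc": res.c_t,
                     "t_stat": res.t_stat, "p": res.p_value}
                )
    return pd.DataFrame(rows)
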