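"""Extended Fourier amplitude sensitivity test (extended FAST).

All factors are driven simultaneously along periodic search curves
x_j(s) = 1/2 + (1/pi) arcsin(sin(omega_j s + phi_j)); the output's
Fourier spectrum along the curve is partitioned by frequency: harmonics
of the factor-of-interest frequency give its first-order variance share
Si = Vi/V, and the low-frequency band carried by the complementary
factors gives V_(-i), hence the total-order index STi = 1 - V_(-i)/V.
One block of Ns samples is generated per factor of interest (the factor
of interest carries the highest interference-free frequency).

Small designs force the complementary factors to share few distinct
frequencies, which correlates them along a single curve; the design
therefore supports Nr independent random-phase resample curves per
block (Saltelli's resampling), whose spectra are pooled.  A full design
costs n x Ns x Nr model runs.

Influence rule: a factor is influential when Si > 0.05 and STi > 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: Published influence thresholds.
SI_THRESHOLD = 0.05
STI_THRESHOLD = 0.10
#: Sample-size validity rule: Ns per factor block should reach 65.
NS_VALIDITY = 65


@dataclass(frozen=True)
class FASTDesign:
    """Search-curve sample matrix: Nr resample curves of Ns points per factor."""

    n: int
    ns: int
    m: int                       # interference factor (harmonics used)
    nr: int                      # random-phase resample curves per block
    omega_max: int               # frequency of the factor of interest
    comp_max: int                # highest complementary frequency
    freqs: np.ndarray            # (n, n) frequency assignment per block
    phases: np.ndarray           # (nr, n, n) random phase shifts
    samples: np.ndarray          # (nr*n*ns, n), unit hypercube
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.nr * self.n * self.ns

    def block(self, i: int, r: int = 0) -> slice:
        """Sample rows of factor i's block on resample curve r."""
        start = (r * self.n + i) * self.ns
        return slice(start, start + self.ns)

    def resample(self, r: int) -> slice:
        """All sample rows belonging to resample curve r."""
        return slice(r * self.n * self.ns, (r + 1) * self.n * self.ns)


@dataclass(frozen=True)
class FASTResult:
    """Per-factor Si, STi with STi-descending ranks and influence flags."""

    table: pd.DataFrame  # columns: factor, Si, STi, rank, influential, degenerate

    @property
    def ranking(self) -> list[str]:
        return list(self.table.sort_values("rank")["factor"])

    def write(self, path, sep: str = ",") -> None:
        self.table.to_csv(path, index=False, sep=sep)


def build_fast_design(
    n: int, ns: int, m: int = 4, seed: int = 0, nr: int = 1, strict: bool = False
) -> FASTDesign:
    """Build the extended-FAST sample matrix.

    ``ns`` is the number of samples per factor-of-interest block per
    resample curve.  The factor of interest carries
    omega_max = floor((ns-1)/(2m)); the complementary factors get
    frequencies cycling over [1, max(1, omega_max // (2m))], and each of
    the ``nr`` resample curves draws an independent set of random phases.
    """
    if n < 2:
        raise ValueError("need at least 2 factors")
    if m < 1:
        raise ValueError("interference factor m must be >= 1")
    if nr < 1:
        raise ValueError("need at least one resample curve")
    if ns < NS_VALIDITY:
        msg = (
            f"Ns = {ns} is below the validity rule of {NS_VALIDITY} samples "
            "per factor block"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    omega_max = (ns - 1) // (2 * m)
    if omega_max < 1:
        raise ValueError(f"Ns = {ns} too small for interference factor m = {m}")
    comp_max = max(1, omega_max // (2 * m))
    rng = np.random.default_rng(seed)

    s = 2.0 * np.pi * np.arange(ns) / ns
    freqs = np.empty((n, n), dtype=np.int64)
    comp_cycle = 1 + np.arange(n - 1) % comp_max
    for i in range(n):
        w = np.empty(n, dtype=np.int64)
        w[i] = omega_max
        others = [j for j in range(n) if j != i]
        w[others] = comp_cycle
        freqs[i] = w
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(nr, n, n))
    samples = np.empty((nr * n * ns, n))
    for r in range(nr):
        for i in range(n):
            angles = np.outer(s, freqs[i]) + phases[r, i]
            start = (r * n + i) * ns
            samples[start: start + ns] = 0.5 + np.arcsin(np.sin(angles)) / np.pi
    return FASTDesign(
        n=n, ns=ns, m=m, nr=nr, omega_max=omega_max, comp_max=comp_max,
        freqs=freqs, phases=phases, samples=samples, seed=seed,
    )


def _block_spectrum(yb: np.ndarray) -> np.ndarray:
    """One-sided power spectrum of a block (mean removed, w >= 1)."""
    coeffs = np.fft.rfft(yb - yb.mean()) / len(yb)
    power = 2.0 * np.abs(coeffs) ** 2
    power[0] = 0.0
    return power


def variance_decomposition(
    design: FASTDesign,
    outputs: np.ndarray,
    factor_names: Sequence[str] | None = None,
) -> FASTResult:
    """Fourier variance partition of aligned outputs into Si and STi.

    Per block and resample curve: total variance V from the full
    spectrum; Vi from the harmonics {w, 2w, ..., m*w} of the block's
    factor frequency, after subtracting the local non-harmonic noise
    floor (complementary-factor images are broadband on small designs
    and deposit power onto the harmonics; the floor vanishes for
    well-separated designs); V_(-i) from the band below omega_max/2.
    Spectra are pooled across resample curves.  A block with zero
    output variance on every curve reports Si = STi = 0 and is flagged
    degenerate.
    """
    y = np.asarray(outputs, dtype=float)
    if y.shape != (design.n_samples,):
        raise ValueError(f"expected {design.n_samples} outputs, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite model output in FAST replay")
    n, m = design.n, design.m
    names = list(factor_names) if factor_names is not None else [f"x{i+1}" for i in range(n)]
    si = np.zeros(n)
    sti = np.zeros(n)
    degenerate = np.zeros(n, dtype=bool)
    low_cut = max(1, design.omega_max // 2)
    harmonics = design.omega_max * np.arange(1, m + 1)
    for i in range(n):
        v_tot = vi_tot = vcomp_tot = 0.0
        scale = 0.0
        for r in range(design.nr):
            yb = y[design.block(i, r)]
            power = _block_spectrum(yb)
            scale = max(scale, yb.var())
            h = harmonics[harmonics < len(power)]
            floor = np.empty(len(h))
            for j, k in enumerate(h):
                lo, hi = max(1, k - 4), min(len(power), k + 5)
                idx = np.arange(lo, hi)
                floor[j] = np.median(power[idx[idx != k]])
            v_tot += power.sum()
            vi_tot += np.maximum(power[h] - floor, 0.0).sum()
            vcomp_tot += power[1: low_cut + 1].sum()
        if v_tot <= 1e-12 * max(1.0, scale) or scale == 0.0:
            degenerate[i] = True
            continue
        si[i] = vi_tot / v_tot
        sti[i] = 1.0 - vcomp_tot / v_tot
    rank = rankdata(-sti, method="ordinal").astype(int)
    influential = (si > SI_THRESHOLD) & (sti > STI_THRESHOLD)
    table = pd.DataFrame(
        {
            "factor": names,
            "Si": si,
            "STi": sti,
            "rank": rank,
            "influential": influential,
            "degenerate": degenerate,
        }
    )
    return FASTResult(table=table)


def classify_influential_fast(result: FASTResult) -> set[str]:
    """Factors with Si > 0.05 and STi > 0.10."""
    t = result.table
    return set(t.loc[t["influential"], "factor"])


def run_efast(
    func: Callable[[np.ndarray], np.ndarray],
    n: int,
    ns: int,
    m: int = 4,
    seed: int = 0,
    nr: int = 1,
    factor_names: Sequence[str] | None = None,
    strict: bool = False,
) -> FASTResult:
    """Convenience driver: design -> batch evaluate -> decompose.

    ``func`` maps an (N, n) unit-hypercube matrix to (N,) outputs.
    """
    design = build_fast_design(n=n, ns=ns, m=m, seed=seed, nr=nr, strict=strict)
    y = np.asarray(func(design.samples), dtype=float)
    return variance_decomposition(design, y, factor_names)
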