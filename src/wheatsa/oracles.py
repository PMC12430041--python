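"""Analytic test functions and brute-force estimators.

Independent validation surface for the screening and variance-based
engines: closed-form Sobol indices for linear, g-function and Ishigami
test functions; a pick-and-freeze Monte-Carlo first-order estimator; and
a direct replay of elementary effects from stored design points.  All
functions take inputs in the unit hypercube (the Ishigami inputs are
mapped internally to [-pi, pi]^3 so the whole package keeps a single
coordinate convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morris import TrajectoryDesign


@dataclass(frozen=True)
class TestFunction:
    """A named analytic test function on the unit hypercube."""

    name: str  # linear | product | g_function | ishigami
    coeffs: tuple[float, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        if self.name == "ishigami":
            return 3
        if self.name == "product":
            return max(2, len(self.coeffs)) if self.coeffs else 2
        return len(self.coeffs)

    def __call__(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        if self.name == "linear":
            c = np.asarray(self.coeffs)
            return U @ c
        if self.name == "product":
            return np.prod(U, axis=1)
        if self.name == "g_function":
            a = np.asarray(self.coeffs)
            return np.prod((np.abs(4.0 * U - 2.0) + a) / (1.0 + a), axis=1)
        if self.name == "ishigami":
            A, B = self.coeffs if self.coeffs else (7.0, 0.1)
            X = np.pi * (2.0 * U - 1.0)
            return (
                np.sin(X[:, 0])
                + A * np.sin(X[:, 1]) ** 2
                + B * X[:, 2] ** 4 * np.sin(X[:, 0])
            )
        raise ValueError(f"unknown test function {self.name!r}")


def linear(*coeffs: float) -> TestFunction:
    return TestFunction("linear", tuple(coeffs))


def product(n: int = 2) -> TestFunction:
    return TestFunction("product", tuple([1.0] * n))


def g_function(*a: float) -> TestFunction:
    return TestFunction("g_function", tuple(a))


def ishigami(A: float = 7.0, B: float = 0.1) -> TestFunction:
    return TestFunction("ishigami", (A, B))


def analytic_sobol_indices(fn: TestFunction) -> np.ndarray:
    """Closed-form first-order Sobol indices, when available.

    linear sum(c_i x_i) on U(0,1): Si = c_i^2 / sum(c^2).
    g-function: Vi = (1/3)/(1+a_i)^2, V = prod(1+Vi) - 1, Si = Vi/V.
    Ishigami: the standard closed form.
    """
    if fn.name == "linear":
        c = np.asarray(fn.coeffs, dtype=float)
        return c**2 / np.sum(c**2)
    if fn.name == "g_function":
        a = np.asarray(fn.coeffs, dtype=float)
        vi = (1.0 / 3.0) / (1.0 + a) ** 2
        v = np.prod(1.0 + vi) - 1.0
        return vi / v
    if fn.name == "ishigami":
        A, B = fn.coeffs if fn.coeffs else (7.0, 0.1)
        v1 = 0.5 * (1.0 + B * np.pi**4 / 5.0) ** 2
        v2 = A**2 / 8.0
        v13 = B**2 * np.pi**8 * (1.0 / 18.0 - 1.0 / 50.0)
        v = v1 + v2 + v13
        return np.array([v1 / v, v2 / v, 0.0])
    raise ValueError(f"no closed form for {fn.name!r}")


def mc_sobol_first_order(fn, n_factors: int, n_samples: int = 10_000, seed: int = 0) -> np.ndarray:
    """Pick-and-freeze Monte-Carlo first-order Sobol estimates.

    Uses the Saltelli (2010) estimator Vi = mean(yB (yABi - yA)); costs
    n_samples x (n_factors + 2) evaluations of ``fn``.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(seed)
    A = rng.random((n_samples, n_factors))
    B = rng.random((n_samples, n_factors))
    yA = np.asarray(fn(A), dtype=float)
    yB = np.asarray(fn(B), dtype=float)
    v = np.var(np.concatenate([yA, yB]))
    si = np.empty(n_factors)
    for i in range(n_factors):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        yABi = np.asarray(fn(ABi), dtype=float)
        si[i] = np.mean(yB * (yABi - yA)) / v if v > 0 else 0.0
    return si


def brute_force_elementary_effects(fn, design: TrajectoryDesign) -> np.ndarray:
    """Recompute elementary effects directly from the stored design points.

    Independent of the screening module's bookkeeping: walks each
    trajectory, detects the moved coordinate from the points themselves,
    and divides the output difference by the signed step.
    """
    ee = np.full((design.t, design.n), np.nan)
    for k in range(design.t):
        traj = design.trajectory(k)
        y = np.asarray(fn(traj), dtype=float)
        for j in range(design.n):
            dx = traj[j + 1] - traj[j]
            (i,) = np.nonzero(np.abs(dx) > 1e-12)[0]
            ee[k, i] = (y[j + 1] - y[j]) / dx[i]
    return ee
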