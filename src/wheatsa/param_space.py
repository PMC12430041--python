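"""Registry of the 21 wheat-model parameters and hypercube <-> physical maps.

The sensitivity and calibration machinery works in the unit hypercube
[0, 1]^n; every parameter is assumed uniform over a closed physical
interval [lower, upper].  The bundled registry ships the 21 screened
parameters of the APSIM-Wheat study (phenology thermal-time targets
T1-T4, grain-filling rates P1-P3/M1, canopy traits K/Y1/I1/S1/I2,
radiation-use efficiency R1, water demand E1, and so on) with their
published perturbation bounds.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of the 21 parameter codes (registry row order).
PARAMETER_CODES = (
    "P1", "P2", "P3", "M1", "P4", "V1", "G1", "M2", "T1", "T2", "T3",
    "T4", "K", "R1", "Y1", "I1", "S1", "E1", "N1", "I2", "X1",
)


@dataclass(frozen=True)
class ParameterSpec:
    """One named model parameter with its uniform sampling interval."""

    code: str
    definition: str
    unit: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lower) or not np.isfinite(self.upper):
            raise ValueError(f"{self.code}: non-finite bounds")
        if self.lower >= self.upper:
            raise ValueError(
                f"{self.code}: degenerate interval [{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


class ParameterSet(dict):
    """Mapping code -> value in physical units.

    A *complete* set carries all 21 codes; partial sets are only
    meaningful inside calibration, where unlisted codes are pinned.
    """

    def validate(self, specs: Sequence[ParameterSpec], complete: bool = True) -> None:
        by_code = {s.code: s for s in specs}
        unknown = set(self) - set(by_code)
        if unknown:
            raise ValueError(f"unknown parameter codes: {sorted(unknown)}")
        for code, value in self.items():
            s = by_code[code]
            if not (s.lower <= value <= s.upper):
                raise ValueError(
                    f"{code}={value} outside [{s.lower}, {s.upper}]"
                )
        if complete and set(self) != set(by_code):
            missing = sorted(set(by_code) - set(self))
            raise ValueError(f"incomplete parameter set, missing {missing}")


def load_bounds(source=None, strict: bool = True) -> list[ParameterSpec]:
    """Load parameter specs from a delimited bounds table.

    ``source`` may be a path or file-like object with columns
    ``code,definition,unit,lower,upper``; ``None`` loads the bundled
    registry (the published table, verbatim).  With ``strict`` on, any
    code outside the canonical 21 is rejected.
    """
    if source is None:
        ref = importlib.resources.files("wheatsa.data") / "parameter_bounds.csv"
        with ref.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh, sep=None, engine="python")
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    required = {"code", "definition", "unit", "lower", "upper"}
    if not required.issubset(df.columns):
        raise ValueError(f"bounds table must have columns {sorted(required)}")
    codes = list(df["code"])
    if len(set(codes)) != len(codes):
        dup = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate parameter codes: {dup}")
    if strict:
        unknown = set(codes) - set(PARAMETER_CODES)
        if unknown:
            raise ValueError(f"unknown parameter codes: {sorted(unknown)}")
    specs = [
        ParameterSpec(
            code=str(r.code),
            definition=str(r.definition),
            unit=str(r.unit),
            lower=float(r.lower),
            upper=float(r.upper),
        )
        for r in df.itertuples()
    ]
    return specs


def write_bounds(specs: Sequence[ParameterSpec], path) -> None:
    """Write specs back to a delimited table (round-trips bit-identically)."""
    df = pd.DataFrame(
        {
            "code": [s.code for s in specs],
            "definition": [s.definition for s in specs],
            "unit": [s.unit for s in specs],
            "lower": [np.format_float_positional(s.lower, trim="-") for s in specs],
            "upper": [np.format_float_positional(s.upper, trim="-") for s in specs],
        }
    )
    df.to_csv(path, index=False)


def to_physical(u: Iterable[float], specs: Sequence[ParameterSpec]) -> ParameterSet:
    """Map unit-interval coordinates (in spec order) to physical units."""
    u = np.asarray(list(u), dtype=float)
    if u.shape != (len(specs),):
        raise ValueError(f"expected {len(specs)} coordinates, got {u.shape}")
    if np.any(u < 0.0) or np.any(u > 1.0):
        raise ValueError("unit coordinates must lie in [0, 1]")
    return ParameterSet(
        {s.code: s.lower + ui * s.width for s, ui in zip(specs, u)}
    )


def to_unit(params: Mapping[str, float], specs: Sequence[ParameterSpec]) -> np.ndarray:
    """Exact inverse of :func:`to_physical` (spec order)."""
    return np.array([(params[s.code] - s.lower) / s.width for s in specs])


def to_physical_matrix(U: np.ndarray, specs: Sequence[ParameterSpec]) -> np.ndarray:
    """Vectorized hypercube -> physical map for an (n_points, n_factors) array."""
    U = np.asarray(U, dtype=float)
    lo = np.array([s.lower for s in specs])
    w = np.array([s.width for s in specs])
    if U.ndim != 2 or U.shape[1] != len(specs):
        raise ValueError("U must be (n_points, n_factors)")
    if U.min() < 0.0 or U.max() > 1.0:
        raise ValueError("unit coordinates must lie in [0, 1]")
    return lo + U * w


def midpoint_defaults(specs: Sequence[ParameterSpec]) -> ParameterSet:
    """Per-code interval midpoints, used as the emulator's baseline set."""
    return ParameterSet({s.code: s.midpoint for s in specs})
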