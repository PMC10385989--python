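"""Abraham solvation parameter model and the D' system-similarity metric.

The solvation parameter model is a linear free-energy relationship (LFER)
that correlates the logarithm of a solute property SP (a partition
coefficient, a chromatographic retention factor, a permeability of the
neutral species, ...) with five solute descriptors::

    log SP = c + eE + sS + aA + bB + vV

The coefficients (c, e, s, a, b, v) characterize the *system*; the
descriptors (E, S, A, B, V) characterize the *solute*.  Two systems fitted
to the common model can then be compared through the Euclidean distance D'
between their coefficient vectors (e, s, a, b, v) — the intercept c is a
scale offset and is excluded by construction.  Small D' (conventionally
<= 1) indicates that one system can emulate the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SoluteDescriptors",
    "SystemCoefficients",
    "DistanceMatrix",
    "predict_log_sp",
    "dprime",
    "dprime_matrix",
]

#: Fixed axis order of the descriptor space / coefficient vector used
#: everywhere (radial plots, PCA, D').
COEFFICIENT_AXES = ("e", "s", "a", "b", "v")


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"field {name!r} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SoluteDescriptors:
    """Abraham descriptors of one solute.

    E: excess molar refractivity (cm3 mol-1 / 10)
    S: dipolarity/polarizability
    A: hydrogen-bond acidity
    B: hydrogen-bond basicity
    V: McGowan characteristic volume (cm3 mol-1 / 100)
    """

    E: float
    S: float
    A: float
    B: float
    V: float

    def __post_init__(self) -> None:
        for name in ("E", "S", "A", "B", "V"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.S, self.A, self.B, self.V], dtype=float)


@dataclass(frozen=True)
class SystemCoefficients:
    """LFER coefficients of one partition/permeation system.

    ``c`` may be ``None`` for systems compiled from the literature without a
    reported intercept; D' never needs it, but :func:`predict_log_sp` does.
    Diagnostics (standard errors, N, SD, R2, F), when present, describe the
    regression the coefficients came from.
    """

    system_id: str
    e: float
    s: float
    a: float
    b: float
    v: float
    c: float | None = None
    category: str = "pampa"
    name: str | None = None
    std_errors: dict[str, float] | None = None
    n: int | None = None
    sd: float | None = None
    r2: float | None = None
    f: float | None = None

    def __post_init__(self) -> None:
        for nm in COEFFICIENT_AXES:
            object.__setattr__(self, nm, _require_finite(nm, getattr(self, nm)))
        if self.c is not None:
            object.__setattr__(self, "c", _require_finite("c", self.c))
        if self.n is not None and self.n < 7:
            raise ValueError(f"N must be >= 7 (one more than parameters), got {self.n}")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"SD must be >= 0, got {self.sd}")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"R2 must lie in [0, 1], got {self.r2}")

    def vector(self) -> np.ndarray:
        """The (e, s, a, b, v) vector — the D' comparison space."""
        return np.array([self.e, self.s, self.a, self.b, self.v], dtype=float)


def predict_log_sp(coeffs: SystemCoefficients, d: SoluteDescriptors) -> float:
    """Evaluate log SP = c + eE + sS + aA + bB + vV for one solute."""
    if coeffs.c is None:
        raise ValueError(
            f"system {coeffs.system_id!r} has no intercept c; "
            "log SP cannot be predicted"
        )
    return float(coeffs.c + coeffs.vector() @ d.as_array())


def dprime(i: SystemCoefficients, j: SystemCoefficients) -> float:
    """Euclidean distance between two systems over (e, s, a, b, v).

    The intercept is structurally excluded: the distance is taken over
    :meth:`SystemCoefficients.vector`, which never contains c.
    """
    return float(np.linalg.norm(i.vector() - j.vector()))


@dataclass
class DistanceMatrix:
    """Symmetric D' matrix over an ordered list of systems."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")

    def get(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])

    def submatrix(self, rows: list[str], cols: list[str]) -> np.ndarray:
        ri = [self.ids.index(r) for r in rows]
        ci = [self.ids.index(c) for c in cols]
        return self.values[np.ix_(ri, ci)]

    def condensed(self) -> np.ndarray:
        """Upper-triangle condensed form (scipy pdist order)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def dprime_matrix(systems: list[SystemCoefficients]) -> DistanceMatrix:
    """All pairwise D' distances, in input order."""
    if len(systems) < 2:
        raise ValueError("need at least 2 systems")
    ids = [s.system_id for s in systems]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate system_ids: {dupes}")
    coords = np.stack([s.vector() for s in systems])
    diff = coords[:, None, :] - coords[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=ids, values=values)
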