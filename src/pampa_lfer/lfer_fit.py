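"""Fit the solvation parameter model to a solute dataset by OLS.

The model applies to the neutral species, so before fitting, compounds
appreciably ionized at their measurement pH are excluded: the ionized
fraction follows Henderson-Hasselbalch (for an acid 1/(1+10^(pKa-pH)),
for a base 1/(1+10^(pH-pKa)); multiprotic compounds take the maximum over
sites), and any compound above the threshold (default 0.02) is dropped.

The regression is plain ordinary least squares of log Pe on
[1, E, S, A, B, V] — no weighting, no standardization.  Reported
diagnostics follow the field's conventions: SD is the residual standard
error sqrt(RSS/(N-6)), R2 the determination coefficient, and
F = (R2/5)/((1-R2)/(N-6)) the Fisher statistic with (5, N-6) degrees of
freedom.  Per-coefficient significance is a two-sided t-test at the 95%
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .lfer_core import SoluteDescriptors, SystemCoefficients

__all__ = [
    "SoluteRecord",
    "FitResult",
    "ExclusionReport",
    "ionized_fraction",
    "filter_neutral",
    "fit_lfer",
    "f_statistic",
]

_COEF_NAMES = ("c", "e", "s", "a", "b", "v")
_N_PARAMS = 6  # intercept + five descriptors


@dataclass(frozen=True)
class SoluteRecord:
    """One compound: descriptors, measured log Pe, and ionization data.

    ``pKa`` is a list of (value, kind) sites with kind 'acid' or 'base';
    an empty list means the compound has no ionizable group in range.
    ``pH`` is the pH of the permeability measurement.
    """

    name: str
    descriptors: SoluteDescriptors
    log_pe: float
    pKa: tuple[tuple[float, str], ...] = ()
    pH: float = 7.4

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_pe):
            raise ValueError(f"log_pe must be finite for {self.name!r}")
        object.__setattr__(self, "pKa", tuple(tuple(site) for site in self.pKa))


@dataclass
class FitResult:
    """OLS fit of the solvation parameter model with the usual diagnostics."""

    coefficients: SystemCoefficients
    std_errors: dict[str, float]
    N: int
    SD: float
    R2: float
    F: float
    significant_95: dict[str, bool]

    def equation_text(self, property_label: str = "log Pe") -> str:
        """Coefficient (SE) presentation, e.g. '-4.181 (0.088) + 0.064 (0.104) E ...'."""
        c = self.coefficients
        terms = [f"{c.c:.3f} ({self.std_errors['c']:.3f})"]
        for nm in ("e", "s", "a", "b", "v"):
            val = getattr(c, nm)
            sign = "+" if val >= 0 else "-"
            terms.append(
                f"{sign} {abs(val):.3f} ({self.std_errors[nm]:.3f}) {nm.upper()}"
            )
        stats = f"N = {self.N}; SD = {self.SD:.3f}; R2 = {self.R2:.3f}; F = {self.F:.1f}"
        return f"{property_label} = " + " ".join(terms) + "\n" + stats


@dataclass
class ExclusionReport:
    retained: list[SoluteRecord]
    excluded: list[tuple[SoluteRecord, float]]  # record, ionized fraction
    no_pka: list[str]  # names retained because no pKa was given
    threshold: float


def ionized_fraction(pKa: float, pH: float, kind: str) -> float:
    """Henderson-Hasselbalch ionized fraction of a monoprotic site."""
    if not (math.isfinite(pKa) and math.isfinite(pH)):
        raise ValueError("pKa and pH must be finite")
    if kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (pKa - pH))
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (pH - pKa))
    raise ValueError(f"unknown ionizable kind {kind!r}; expected 'acid' or 'base'")


def _record_ionized_fraction(rec: SoluteRecord) -> float:
    """Worst-case (maximum) ionized fraction over all sites of a compound."""
    return max(
        (ionized_fraction(pka, rec.pH, kind) for pka, kind in rec.pKa), default=0.0
    )


def filter_neutral(
    records: list[SoluteRecord], threshold: float = 0.02
) -> ExclusionReport:
    """Drop compounds ionized above ``threshold`` at their measurement pH.

    Records without pKa data are treated as neutral: retained and listed
    in the report's ``no_pka`` so the assumption is visible.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    retained: list[SoluteRecord] = []
    excluded: list[tuple[SoluteRecord, float]] = []
    no_pka: list[str] = []
    for rec in records:
        if not rec.pKa:
            no_pka.append(rec.name)
            retained.append(rec)
            continue
        frac = _record_ionized_fraction(rec)
        if frac <= threshold:
            retained.append(rec)
        else:
            excluded.append((rec, frac))
    return ExclusionReport(
        retained=retained, excluded=excluded, no_pka=no_pka, threshold=threshold
    )


def f_statistic(r2: float, n: int, n_predictors: int = 5) -> float:
    """Fisher F from R2 with (n_predictors, n - n_predictors - 1) df."""
    df_resid = n - n_predictors - 1
    if df_resid <= 0:
        raise ValueError(f"need n > {n_predictors + 1}, got n={n}")
    return (r2 / n_predictors) / ((1.0 - r2) / df_resid)


def fit_lfer(records: list[SoluteRecord], system_id: str = "fit") -> FitResult:
    """Ordinary least squares of log Pe on [1, E, S, A, B, V]."""
    n = len(records)
    if n < 7:
        raise ValueError(f"need at least 7 compounds to fit 6 parameters, got {n}")
    X = np.stack([r.descriptors.as_array() for r in records])
    y = np.array([r.log_pe for r in records])
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd)
    if rank < _N_PARAMS:
        # name the offending column for the error message
        labels = ["intercept", "E", "S", "A", "B", "V"]
        for j in range(Xd.shape[1]):
            others = np.delete(Xd, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise ValueError(
                    f"descriptor matrix is rank deficient: column {labels[j]!r} "
                    "is linearly dependent on the others"
                )
        raise ValueError("descriptor matrix is rank deficient")

    model = sm.OLS(y, Xd).fit()
    params = dict(zip(_COEF_NAMES, model.params))
    bse = dict(zip(_COEF_NAMES, model.bse))
    resid = model.resid
    rss = float(resid @ resid)
    sd = math.sqrt(rss / (n - _N_PARAMS))
    r2 = float(model.rsquared)
    fval = f_statistic(r2, n) if r2 < 1.0 else math.inf
    significant = {nm: bool(p < 0.05) for nm, p in zip(_COEF_NAMES, model.pvalues)}

    coeffs = SystemCoefficients(
        system_id=system_id,
        c=params["c"],
        e=params["e"],
        s=params["s"],
        a=params["a"],
        b=params["b"],
        v=params["v"],
        category="pampa",
        std_errors=bse,
        n=n,
        sd=sd,
        r2=min(max(r2, 0.0), 1.0),
        f=fval,
    )
    return FitResult(
        coefficients=coeffs,
        std_errors=bse,
        N=n,
        SD=sd,
        R2=r2,
        F=fval,
        significant_95=significant,
    )
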