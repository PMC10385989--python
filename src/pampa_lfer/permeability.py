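"""Effective permeability from raw PAMPA concentration measurements.

A PAMPA well has a donor compartment (volume V_D), an acceptor compartment
(V_A) and an artificial lipid membrane of area A and apparent porosity
eps_a between them.  After incubation for time t, the donor and acceptor
concentrations give the membrane retention

    RM = 1 - C_D(t)/C_D(0) - (V_A/V_D) * C_A(t)/C_D(0)

(the fraction of solute mass lost to the membrane), the lag time before
steady-state flux t_ss, and the effective permeability

    Pe = [-2.303 V_D / (A (t - t_ss) eps_a)] * [1/(1+r)]
         * log10( -r + (1+r)/(1-RM) * C_D(t)/C_D(0) )

where r is the volume ratio r_v = V_D/V_A in an iso-pH experiment (equal
pH on both sides), or the asymmetry ratio r_a = r_v * Pe(A->D)/Pe(D->A)
under a pH gradient.  In the gradient case r_a depends on the unknown
Pe(D->A), so the equation is solved iteratively: Pe(A->D) comes from a
companion iso-pH experiment (where the two directional permeabilities are
equal), r_a starts at r_v and is refreshed from each new Pe(D->A) until
self-consistent.

``forward_simulate`` is the exact algebraic inverse of this chain and
serves as the independent oracle in tests: a record it produces, fed back
through ``pe_iso``/``pe_gradient``, returns the permeabilities it was
built from.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "PampaGeometry",
    "ConcentrationRecord",
    "PermeabilityResult",
    "InconsistentRecordError",
    "EquilibriumError",
    "ConvergenceError",
    "membrane_retention",
    "lag_time",
    "pe_iso",
    "pe_gradient",
    "forward_simulate",
    "LAG_TIME_SLOPE",
    "LAG_TIME_BASE_S",
]

# t_ss = (LAG_TIME_SLOPE * RM + 1) * LAG_TIME_BASE_S.  The slope is a
# parameter of lag_time so an alternative lag model can be swapped in
# without touching the permeability equations.
LAG_TIME_SLOPE = 5.0 / 4.0
LAG_TIME_BASE_S = 60.0

#: Small negative retentions (|RM| below this) are treated as measurement
#: noise and clamped to zero; anything more negative is a data error.
RM_NOISE_TOLERANCE = 0.02


class InconsistentRecordError(ValueError):
    """Concentrations violate mass balance beyond measurement noise."""


class EquilibriumError(ValueError):
    """The well is at/beyond equilibrium; Pe is not determinable."""


class ConvergenceError(RuntimeError):
    """The gradient-pH iteration failed to converge."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class PampaGeometry:
    """Plate geometry. Defaults: 180 uL donor (stirring bar takes 20 uL of
    the nominal 200), 200 uL acceptor, 0.3 cm2 filter, porosity 0.76."""

    V_D: float = 0.18  # donor volume, cm3
    V_A: float = 0.20  # acceptor volume, cm3
    area: float = 0.3  # membrane area, cm2
    porosity: float = 0.76  # apparent porosity eps_a

    def __post_init__(self) -> None:
        for nm in ("V_D", "V_A", "area", "porosity"):
            val = getattr(self, nm)
            if not (math.isfinite(val) and val > 0):
                raise ValueError(f"{nm} must be positive and finite, got {val!r}")
        if self.porosity > 1:
            raise ValueError(f"porosity must be <= 1, got {self.porosity}")

    @property
    def r_v(self) -> float:
        """Volume ratio V_D/V_A."""
        return self.V_D / self.V_A


@dataclass(frozen=True)
class ConcentrationRecord:
    """One PAMPA well experiment.

    Concentrations are in mol cm-3 (any common unit works — only ratios to
    C_D0 enter the equations); time in seconds.
    """

    C_D0: float
    C_Dt: float
    C_At: float
    t: float
    pH_donor: float = 7.4
    pH_acceptor: float = 7.4

    def __post_init__(self) -> None:
        if self.C_D0 <= 0:
            raise ValueError(f"C_D0 must be > 0, got {self.C_D0}")
        if self.C_Dt < 0 or self.C_At < 0:
            raise ValueError("concentrations must be >= 0")
        if self.C_Dt > self.C_D0 * (1 + 1e-12):
            raise ValueError("C_Dt cannot exceed C_D0")
        if self.t <= 0:
            raise ValueError(f"t must be > 0, got {self.t}")

    @property
    def is_iso_ph(self) -> bool:
        return math.isclose(self.pH_donor, self.pH_acceptor)


@dataclass
class PermeabilityResult:
    """Directional permeabilities and the quantities derived on the way."""

    Pe_DA: float  # donor -> acceptor effective permeability, cm/s
    Pe_AD: float  # acceptor -> donor effective permeability, cm/s
    RM: float  # membrane retention fraction
    t_ss: float  # lag time, s
    r_a: float  # asymmetry ratio
    iterations: int
    converged: bool


def membrane_retention(rec: ConcentrationRecord, geom: PampaGeometry) -> float:
    """Membrane retention factor RM by donor/acceptor mass balance.

    RM = 1 - C_D(t)/C_D(0) - (V_A/V_D) C_A(t)/C_D(0).  Small negative
    values (within ``RM_NOISE_TOLERANCE``) are clamped to 0 with a
    warning; values below -tolerance or >= 1 are rejected.
    """
    rm = 1.0 - rec.C_Dt / rec.C_D0 - (geom.V_A / geom.V_D) * rec.C_At / rec.C_D0
    if rm < 0:
        if rm >= -RM_NOISE_TOLERANCE:
            warnings.warn(
                f"RM={rm:.4f} slightly negative (measurement noise); clamped to 0",
                stacklevel=2,
            )
            return 0.0
        raise InconsistentRecordError(
            f"RM={rm:.4f} < -{RM_NOISE_TOLERANCE}: acceptor+donor mass exceeds "
            "the initial donor mass beyond noise"
        )
    if rm >= 1.0:
        raise InconsistentRecordError(f"RM={rm:.4f} >= 1: no solute left anywhere")
    return rm


def lag_time(
    rm: float, slope: float = LAG_TIME_SLOPE, base_s: float = LAG_TIME_BASE_S
) -> float:
    """Lag time t_ss = (slope*RM + 1) * base seconds before steady-state flux."""
    if not 0.0 <= rm < 1.0:
        raise ValueError(f"RM must lie in [0, 1), got {rm}")
    return (slope * rm + 1.0) * base_s


def _pe_from_record(
    rec: ConcentrationRecord, geom: PampaGeometry, r: float
) -> tuple[float, float, float]:
    """Shared kernel of the iso and gradient Pe equations.

    Returns (Pe, RM, t_ss) for ratio r (= r_v or the current r_a)."""
    rm = membrane_retention(rec, geom)
    tss = lag_time(rm)
    if rec.t <= tss:
        raise ValueError(
            f"incubation time {rec.t} s is shorter than the lag time {tss:.1f} s"
        )
    arg = -r + (1.0 + r) / (1.0 - rm) * (rec.C_Dt / rec.C_D0)
    if arg <= 0:
        raise EquilibriumError(
            "donor concentration is at/beyond the equilibrium plateau; "
            "Pe is not determinable from this record"
        )
    pe = (
        -2.303
        * geom.V_D
        / (geom.area * (rec.t - tss) * geom.porosity)
        / (1.0 + r)
        * math.log10(arg)
    )
    return pe, rm, tss


def pe_iso(rec: ConcentrationRecord, geom: PampaGeometry | None = None) -> float:
    """Effective permeability of an iso-pH experiment (r = r_v = V_D/V_A)."""
    geom = geom or PampaGeometry()
    pe, _, _ = _pe_from_record(rec, geom, geom.r_v)
    return pe


def pe_gradient(
    iso_rec: ConcentrationRecord,
    grad_rec: ConcentrationRecord,
    geom: PampaGeometry | None = None,
    tol: float = 1e-3,
    max_iterations: int = 100,
) -> PermeabilityResult:
    """Directional permeabilities from an iso-pH / gradient-pH pair.

    Pe(A->D) is read directly off the iso-pH record (the two directions are
    equal there).  Pe(D->A) then solves the gradient equation
    self-consistently with r_a = r_v * Pe(A->D)/Pe(D->A): starting from
    r_a = r_v, each iteration computes Pe(D->A) at the current r_a and
    refreshes r_a, until successive Pe(D->A) values agree within ``tol``
    (relative).
    """
    geom = geom or PampaGeometry()
    if not iso_rec.is_iso_ph:
        raise ValueError(
            f"iso record has pH {iso_rec.pH_donor} / {iso_rec.pH_acceptor}; "
            "donor and acceptor pH must match"
        )
    pe_ad = pe_iso(iso_rec, geom)
    if pe_ad <= 0:
        raise EquilibriumError("iso-pH record yields non-positive Pe(A->D)")

    r_a = geom.r_v
    trace: list[float] = []
    pe_da_prev: float | None = None
    for iteration in range(1, max_iterations + 1):
        pe_da, rm, tss = _pe_from_record(grad_rec, geom, r_a)
        if pe_da <= 0:
            raise EquilibriumError("gradient record yields non-positive Pe(D->A)")
        trace.append(pe_da)
        r_a = geom.r_v * pe_ad / pe_da
        if pe_da_prev is not None and abs(pe_da - pe_da_prev) <= tol * abs(pe_da):
            return PermeabilityResult(
                Pe_DA=pe_da,
                Pe_AD=pe_ad,
                RM=rm,
                t_ss=tss,
                r_a=r_a,
                iterations=iteration,
                converged=True,
            )
        pe_da_prev = pe_da
    raise ConvergenceError(
        f"gradient-pH iteration did not reach {tol} relative precision "
        f"in {max_iterations} iterations",
        trace,
    )


def forward_simulate(
    Pe_DA: float,
    Pe_AD: float,
    RM: float,
    geom: PampaGeometry | None = None,
    t: float = 14400.0,
    C_D0: float = 5e-8,
    pH_donor: float | None = None,
    pH_acceptor: float = 7.4,
) -> ConcentrationRecord:
    """Exact concentration record for known directional permeabilities.

    Inverts the Pe equation in closed form:

        C_D(t)/C_D(0) = (1-RM) * (r + 10^-k) / (1+r),
        k = Pe_DA * A * eps_a * (t - t_ss) * (1+r) / (2.303 * V_D),

    with r = r_v * Pe_AD/Pe_DA (= r_v when the permeabilities are equal),
    and C_A(t) from the retention mass balance.  Default C_D0 matches a
    50 uM sample in mol cm-3; default t is a 4 h incubation.  The donor pH
    defaults to the acceptor pH for symmetric permeabilities and to 5.0
    otherwise, marking the record as gradient-pH.
    """
    geom = geom or PampaGeometry()
    if Pe_DA <= 0 or Pe_AD <= 0:
        raise ValueError("permeabilities must be > 0")
    if not 0.0 <= RM < 1.0:
        raise ValueError(f"RM must lie in [0, 1), got {RM}")
    tss = lag_time(RM)
    if t <= tss:
        raise ValueError(f"t={t} s must exceed the lag time {tss:.1f} s")
    r = geom.r_v * Pe_AD / Pe_DA
    k = Pe_DA * geom.area * geom.porosity * (t - tss) * (1.0 + r) / (2.303 * geom.V_D)
    cd_ratio = (1.0 - RM) * (r + 10.0 ** (-k)) / (1.0 + r)
    ca_ratio = (geom.V_D / geom.V_A) * (1.0 - RM - cd_ratio)
    symmetric = math.isclose(Pe_DA, Pe_AD, rel_tol=1e-12)
    if pH_donor is None:
        pH_donor = pH_acceptor if symmetric else 5.0
    return ConcentrationRecord(
        C_D0=C_D0,
        C_Dt=C_D0 * cd_ratio,
        C_At=C_D0 * ca_ratio,
        t=t,
        pH_donor=pH_donor,
        pH_acceptor=pH_acceptor,
    )
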