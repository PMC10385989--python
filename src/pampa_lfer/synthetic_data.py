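"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the shape of the study data without mimicking any
specific compound: solute descriptors are drawn uniformly over drug-like
Abraham ranges, log Pe values follow the solvation parameter model plus
Gaussian residual noise, and raw PAMPA concentration records are
forward-simulated from known permeabilities and membrane retention under
the plate geometry, optionally with multiplicative log-normal measurement
noise (the behaviour of UPLC quantification).  Everything is a pure
function of the configuration, so the same seed always reproduces the
same data.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .lfer_core import SoluteDescriptors, SystemCoefficients, predict_log_sp
from .permeability import ConcentrationRecord, PampaGeometry, forward_simulate
from .lfer_fit import SoluteRecord, ionized_fraction

__all__ = [
    "GeneratorConfig",
    "DEFAULT_TRUE_COEFFICIENTS",
    "generate_descriptors",
    "generate_lfer_dataset",
    "generate_pampa_experiments",
]

# Ground-truth system used by default: the certramide-based skin membrane
# equation (a realistic, well-determined coefficient set).
DEFAULT_TRUE_COEFFICIENTS = SystemCoefficients(
    system_id="truth",
    c=-4.181,
    e=0.064,
    s=-0.594,
    a=-1.038,
    b=-2.269,
    v=1.730,
    category="pampa",
)

#: Drug-like Abraham descriptor ranges (uniform draws).
DEFAULT_DESCRIPTOR_RANGES: dict[str, tuple[float, float]] = {
    "E": (0.0, 2.0),
    "S": (0.0, 2.5),
    "A": (0.0, 1.5),
    "B": (0.0, 2.0),
    "V": (0.5, 2.5),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    noise_sd is the residual SD on log Pe (0.15 matches a typical
    regression SD for this kind of assay); retention_range bounds the
    membrane retention of simulated wells; ionizable_fraction assigns a
    pKa to that share of compounds so the neutrality filter has work to
    do; concentration_cv is the multiplicative (log-normal) noise on
    simulated concentrations.
    """

    seed: int = 0
    n_compounds: int = 45
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_RANGES)
    )
    noise_sd: float = 0.15
    true_coefficients: SystemCoefficients = DEFAULT_TRUE_COEFFICIENTS
    geometry: PampaGeometry = field(default_factory=PampaGeometry)
    retention_range: tuple[float, float] = (0.0, 0.5)
    ionizable_fraction: float = 0.0
    concentration_cv: float = 0.0
    incubation_time_s: float = 14400.0  # 4 h
    measurement_pH: float = 7.4
    #: optional 5x5 correlation matrix over (E,S,A,B,V); descriptors are
    #: then drawn through a Gaussian copula (Cholesky factor) so their
    #: rank correlations approximate it while marginals stay uniform
    #: within the configured ranges.  None (the default) = independent.
    descriptor_correlation: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_compounds < 0:
            raise ValueError("n_compounds must be >= 0")
        for name, (lo, hi) in self.descriptor_ranges.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"degenerate range for descriptor {name}: ({lo}, {hi})")
        lo, hi = self.retention_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(f"retention_range must lie in [0, 1), got ({lo}, {hi})")
        if not 0.0 <= self.ionizable_fraction <= 1.0:
            raise ValueError("ionizable_fraction must lie in [0, 1]")
        if self.concentration_cv < 0:
            raise ValueError("concentration_cv must be >= 0")
        if self.descriptor_correlation is not None:
            corr = np.asarray(self.descriptor_correlation, dtype=float)
            if corr.shape != (5, 5):
                raise ValueError("descriptor_correlation must be 5x5")
            if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
                raise ValueError(
                    "descriptor_correlation must be symmetric with unit diagonal"
                )
            eigvals = np.linalg.eigvalsh(corr)
            if eigvals.min() < -1e-10:
                raise ValueError("descriptor_correlation must be positive semidefinite")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible substream per generator stage."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


def generate_descriptors(cfg: GeneratorConfig) -> list[SoluteDescriptors]:
    """Descriptor draws with uniform marginals within the configured ranges.

    Independent by default; with ``descriptor_correlation`` set, a
    Gaussian copula (Cholesky factor of the correlation matrix, then the
    normal CDF) couples the draws while keeping the marginals uniform.
    """
    rng = cfg.rng("descriptors")
    names = list(cfg.descriptor_ranges)
    if cfg.n_compounds == 0:
        return []
    if cfg.descriptor_correlation is None:
        unit = rng.uniform(size=(cfg.n_compounds, len(names)))
    else:
        from scipy import stats

        corr = np.asarray(cfg.descriptor_correlation, dtype=float)
        # small jitter keeps Cholesky defined for semidefinite inputs
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
        z = rng.standard_normal(size=(cfg.n_compounds, 5)) @ chol.T
        unit = stats.norm.cdf(z)
    out = []
    for row in unit:
        vals = {
            name: lo + (hi - lo) * u
            for (name, (lo, hi)), u in zip(cfg.descriptor_ranges.items(), row)
        }
        out.append(SoluteDescriptors(**vals))
    return out


def generate_lfer_dataset(cfg: GeneratorConfig) -> list[SoluteRecord]:
    """Solute records with log Pe = LFER prediction + N(0, noise_sd).

    A fraction ``ionizable_fraction`` of compounds receives a pKa placed
    so that roughly half of them exceed the default 0.02 ionized-fraction
    threshold at the measurement pH, exercising the neutrality filter.
    """
    descriptors = generate_descriptors(cfg)
    rng = cfg.rng("lfer")
    records: list[SoluteRecord] = []
    for i, d in enumerate(descriptors):
        log_pe = predict_log_sp(cfg.true_coefficients, d)
        if cfg.noise_sd > 0:
            log_pe += rng.normal(0.0, cfg.noise_sd)
        pka: tuple[tuple[float, str], ...] = ()
        if cfg.ionizable_fraction > 0 and rng.uniform() < cfg.ionizable_fraction:
            kind = "acid" if rng.uniform() < 0.5 else "base"
            # pKa offset from pH between -1 and +4 units on the neutral
            # side: spans clearly ionized through clearly neutral
            offset = rng.uniform(-1.0, 4.0)
            value = cfg.measurement_pH + offset if kind == "acid" else cfg.measurement_pH - offset
            pka = ((value, kind),)
        records.append(
            SoluteRecord(
                name=f"cmpd-{i + 1:03d}",
                descriptors=d,
                log_pe=log_pe,
                pKa=pka,
                pH=cfg.measurement_pH,
            )
        )
    return records


def generate_pampa_experiments(
    cfg: GeneratorConfig, pe_da: float, pe_ad: float
) -> tuple[ConcentrationRecord, ConcentrationRecord]:
    """Matched iso-pH and gradient-pH wells for known permeabilities.

    The iso-pH record is simulated with both directions at ``pe_ad`` (the
    directional permeabilities coincide without a pH gradient); the
    gradient record uses the full (pe_da, pe_ad) pair.  Membrane retention
    is drawn from ``retention_range``.  With ``concentration_cv`` > 0,
    measured concentrations get independent multiplicative log-normal
    noise of that coefficient of variation.
    """
    rng = cfg.rng("pampa")
    rm = rng.uniform(*cfg.retention_range)
    iso = forward_simulate(
        Pe_DA=pe_ad,
        Pe_AD=pe_ad,
        RM=rm,
        geom=cfg.geometry,
        t=cfg.incubation_time_s,
        pH_acceptor=cfg.measurement_pH,
    )
    grad = forward_simulate(
        Pe_DA=pe_da,
        Pe_AD=pe_ad,
        RM=rm,
        geom=cfg.geometry,
        t=cfg.incubation_time_s,
        pH_acceptor=cfg.measurement_pH,
    )
    if cfg.concentration_cv > 0:
        iso = _add_concentration_noise(iso, cfg.concentration_cv, rng)
        grad = _add_concentration_noise(grad, cfg.concentration_cv, rng)
    return iso, grad


def _add_concentration_noise(
    rec: ConcentrationRecord, cv: float, rng: np.random.Generator
) -> ConcentrationRecord:
    """Multiplicative log-normal noise with unit median on each measurement."""
    sigma = math.sqrt(math.log(1.0 + cv**2))

    def jitter(x: float) -> float:
        return x * math.exp(rng.normal(0.0, sigma))

    c_d0 = jitter(rec.C_D0)
    c_dt = min(jitter(rec.C_Dt), c_d0)
    return ConcentrationRecord(
        C_D0=c_d0,
        C_Dt=c_dt,
        C_At=jitter(rec.C_At),
        t=rec.t,
        pH_donor=rec.pH_donor,
        pH_acceptor=rec.pH_acceptor,
    )
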