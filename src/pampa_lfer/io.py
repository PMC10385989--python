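"""CSV/JSON readers and writers, packaged reference tables, reports.

All files are UTF-8 with a dot decimal separator.  Permeabilities are
serialized in scientific notation with at least six significant digits.
Validation errors name the offending column or row explicitly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .lfer_core import (
    DistanceMatrix,
    SoluteDescriptors,
    SystemCoefficients,
)
from .lfer_fit import FitResult, SoluteRecord
from .permeability import ConcentrationRecord
from .similarity import DendrogramNode, EmulationEntry, PcaResult

__all__ = [
    "ValidationError",
    "AnalysisReport",
    "load_reference_systems",
    "load_reference_dprime",
    "read_systems",
    "write_systems",
    "read_dataset",
    "write_dataset",
    "read_wells",
    "write_distance_matrix",
    "fit_result_to_dict",
    "write_report",
    "read_report",
]


class ValidationError(ValueError):
    """Malformed input file: missing/extra columns or bad values."""


_SYSTEM_REQUIRED = ["system_id", "category", "c", "e", "s", "a", "b", "v"]
_SYSTEM_OPTIONAL = [
    "name",
    "se_c", "se_e", "se_s", "se_a", "se_b", "se_v",
    "n", "sd", "r2", "f", "ref",
]
_DATASET_REQUIRED = ["name", "E", "S", "A", "B", "V", "log_pe"]
_DATASET_OPTIONAL = ["pKa", "acid_base", "pH"]
_WELLS_REQUIRED = [
    "compound", "experiment_type", "c_d0", "c_dt", "c_at",
    "t_s", "ph_donor", "ph_acceptor",
]


def _check_columns(df: pd.DataFrame, required: list[str], optional: list[str],
                   what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required + optional]
    if extra:
        raise ValidationError(f"{what}: unrecognized column(s) {extra}")


def _read_csv(path, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{what}: file {path} is empty") from None
    if df.empty:
        raise ValidationError(f"{what}: file {path} has a header but no rows")
    return df


def _float_cell(df: pd.DataFrame, row: int, col: str, what: str,
                required: bool = True) -> float | None:
    raw = df.at[row, col] if col in df.columns else None
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        if required:
            raise ValidationError(f"{what}: row {row + 2}: column {col!r} is empty")
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{what}: row {row + 2}: column {col!r} has malformed value {raw!r}"
        ) from None


# ---------------------------------------------------------------------------
# systems

def read_systems(path) -> list[SystemCoefficients]:
    """System-coefficient CSV -> SystemCoefficients list."""
    what = "systems file"
    df = _read_csv(path, what)
    _check_columns(df, _SYSTEM_REQUIRED, _SYSTEM_OPTIONAL, what)
    systems: list[SystemCoefficients] = []
    for i in df.index:
        coeffs = {nm: _float_cell(df, i, nm, what) for nm in "esabv"}
        c = _float_cell(df, i, "c", what, required=False)
        se_cols = ["se_c", "se_e", "se_s", "se_a", "se_b", "se_v"]
        ses = {
            col[3:]: _float_cell(df, i, col, what, required=False)
            for col in se_cols if col in df.columns
        }
        ses = {k: v for k, v in ses.items() if v is not None}
        n = _float_cell(df, i, "n", what, required=False)
        name = None
        if "name" in df.columns and isinstance(df.at[i, "name"], str):
            name = df.at[i, "name"]
        systems.append(
            SystemCoefficients(
                system_id=str(df.at[i, "system_id"]),
                category=str(df.at[i, "category"]),
                name=name,
                c=c,
                **coeffs,
                std_errors=ses or None,
                n=int(n) if n is not None else None,
                sd=_float_cell(df, i, "sd", what, required=False),
                r2=_float_cell(df, i, "r2", what, required=False),
                f=_float_cell(df, i, "f", what, required=False),
            )
        )
    ids = [s.system_id for s in systems]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{what}: duplicate system_id values")
    return systems


def write_systems(systems: list[SystemCoefficients], path) -> None:
    rows = []
    for s in systems:
        row = {
            "system_id": s.system_id,
            "name": s.name,
            "category": s.category,
            "c": s.c,
            **{nm: getattr(s, nm) for nm in "esabv"},
        }
        if s.std_errors:
            row.update({f"se_{k}": v for k, v in s.std_errors.items()})
        row.update({"n": s.n, "sd": s.sd, "r2": s.r2, "f": s.f})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_systems() -> list[SystemCoefficients]:
    """The packaged 14-system coefficient compilation (9 PAMPA membranes and
    5 biological reference processes)."""
    with resources.as_file(
        resources.files("pampa_lfer") / "data" / "systems.csv"
    ) as p:
        return read_systems(p)


def load_reference_dprime() -> pd.DataFrame:
    """Packaged reference D' table: biological systems (rows 10-14) against
    PAMPA systems 1-8, rounded to 2 decimals."""
    with resources.as_file(
        resources.files("pampa_lfer") / "data" / "dprime_reference.csv"
    ) as p:
        df = pd.read_csv(p, dtype={"biological_id": str})
    return df.set_index("biological_id")


# ---------------------------------------------------------------------------
# solute datasets

def read_dataset(path) -> list[SoluteRecord]:
    """Solute dataset CSV -> SoluteRecord list.

    Multiprotic compounds list semicolon-separated values in the pKa and
    acid_base columns (e.g. "4.2;9.8" with "acid;base").
    """
    what = "dataset file"
    df = _read_csv(path, what)
    _check_columns(df, _DATASET_REQUIRED, _DATASET_OPTIONAL, what)
    records: list[SoluteRecord] = []
    for i in df.index:
        desc = SoluteDescriptors(
            **{nm: _float_cell(df, i, nm, what) for nm in "ESABV"}
        )
        pka_sites: tuple[tuple[float, str], ...] = ()
        raw_pka = df.at[i, "pKa"] if "pKa" in df.columns else None
        if raw_pka is not None and not (
            isinstance(raw_pka, float) and math.isnan(raw_pka)
        ):
            kinds_raw = df.at[i, "acid_base"] if "acid_base" in df.columns else None
            if kinds_raw is None or (
                isinstance(kinds_raw, float) and math.isnan(kinds_raw)
            ):
                raise ValidationError(
                    f"{what}: row {i + 2}: pKa given without acid_base"
                )
            values = str(raw_pka).split(";")
            kinds = str(kinds_raw).split(";")
            if len(values) != len(kinds):
                raise ValidationError(
                    f"{what}: row {i + 2}: {len(values)} pKa value(s) but "
                    f"{len(kinds)} acid_base entrie(s)"
                )
            try:
                pka_sites = tuple(
                    (float(v), k.strip()) for v, k in zip(values, kinds)
                )
            except ValueError:
                raise ValidationError(
                    f"{what}: row {i + 2}: malformed pKa value in {raw_pka!r}"
                ) from None
        ph = _float_cell(df, i, "pH", what, required=False)
        records.append(
            SoluteRecord(
                name=str(df.at[i, "name"]),
                descriptors=desc,
                log_pe=_float_cell(df, i, "log_pe", what),
                pKa=pka_sites,
                pH=ph if ph is not None else 7.4,
            )
        )
    return records


def write_dataset(records: list[SoluteRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "name": r.name,
                "E": r.descriptors.E,
                "S": r.descriptors.S,
                "A": r.descriptors.A,
                "B": r.descriptors.B,
                "V": r.descriptors.V,
                "log_pe": r.log_pe,
                "pKa": ";".join(str(v) for v, _ in r.pKa) or None,
                "acid_base": ";".join(k for _, k in r.pKa) or None,
                "pH": r.pH,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PAMPA wells

def read_wells(path) -> dict[str, dict[str, ConcentrationRecord]]:
    """Well CSV -> {compound: {experiment_type: averaged record}}.

    Replicate rows of the same compound and experiment type are averaged
    (arithmetic mean of concentrations and time) before any calculation.
    """
    what = "wells file"
    df = _read_csv(path, what)
    _check_columns(df, _WELLS_REQUIRED, [], what)
    bad_types = df.loc[~df["experiment_type"].isin(["iso", "gradient"])]
    if not bad_types.empty:
        row = bad_types.index[0]
        raise ValidationError(
            f"{what}: row {row + 2}: experiment_type must be 'iso' or "
            f"'gradient', got {df.at[row, 'experiment_type']!r}"
        )
    for i in df.index:
        for col in ("c_d0", "c_dt", "c_at", "t_s", "ph_donor", "ph_acceptor"):
            _float_cell(df, i, col, what)
    out: dict[str, dict[str, ConcentrationRecord]] = {}
    grouped = df.groupby(["compound", "experiment_type"], sort=False)
    for (compound, etype), grp in grouped:
        ph_d = grp["ph_donor"].astype(float)
        ph_a = grp["ph_acceptor"].astype(float)
        if ph_d.nunique() > 1 or ph_a.nunique() > 1:
            raise ValidationError(
                f"{what}: compound {compound!r} ({etype}): replicate rows "
                "disagree on pH"
            )
        rec = ConcentrationRecord(
            C_D0=float(grp["c_d0"].astype(float).mean()),
            C_Dt=float(grp["c_dt"].astype(float).mean()),
            C_At=float(grp["c_at"].astype(float).mean()),
            t=float(grp["t_s"].astype(float).mean()),
            pH_donor=float(ph_d.iloc[0]),
            pH_acceptor=float(ph_a.iloc[0]),
        )
        out.setdefault(str(compound), {})[str(etype)] = rec
    return out


def write_wells(wells: dict[str, dict[str, ConcentrationRecord]], path) -> None:
    rows = []
    for compound, by_type in wells.items():
        for etype, rec in by_type.items():
            rows.append(
                {
                    "compound": compound,
                    "experiment_type": etype,
                    "c_d0": f"{rec.C_D0:.6e}",
                    "c_dt": f"{rec.C_Dt:.6e}",
                    "c_at": f"{rec.C_At:.6e}",
                    "t_s": rec.t,
                    "ph_donor": rec.pH_donor,
                    "ph_acceptor": rec.pH_acceptor,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# results

def write_distance_matrix(m: DistanceMatrix, path, fmt: str = "csv") -> None:
    path = Path(path)
    if fmt == "csv":
        m.to_frame().to_csv(path, index_label="system_id")
    elif fmt == "json":
        payload = {"ids": m.ids, "values": m.values.tolist()}
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def fit_result_to_dict(fit: FitResult) -> dict:
    c = fit.coefficients
    return {
        "coefficients": {nm: getattr(c, nm) for nm in ("c", "e", "s", "a", "b", "v")},
        "std_errors": dict(fit.std_errors),
        "N": fit.N,
        "SD": fit.SD,
        "R2": fit.R2,
        "F": fit.F if math.isfinite(fit.F) else None,
        "significant_95": dict(fit.significant_95),
        "equation": fit.equation_text(),
    }


@dataclass
class AnalysisReport:
    """Full-run output: everything the pipeline computed, JSON-serializable."""

    systems: list[dict]
    distance_matrix: dict
    dendrogram_newick: str
    pca: dict
    emulation_flags: list[dict]
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))


def build_report(
    systems: list[SystemCoefficients],
    matrix: DistanceMatrix,
    tree: DendrogramNode,
    pca: PcaResult,
    flags: list[EmulationEntry],
    provenance: dict | None = None,
) -> AnalysisReport:
    return AnalysisReport(
        systems=[
            {
                "system_id": s.system_id,
                "name": s.name,
                "category": s.category,
                "c": s.c,
                **{nm: getattr(s, nm) for nm in "esabv"},
            }
            for s in systems
        ],
        distance_matrix={"ids": matrix.ids, "values": matrix.values.tolist()},
        dendrogram_newick=tree.to_newick(),
        pca={
            "axes": list(pca.axes),
            "loadings": pca.loadings.tolist(),
            "explained_variance_fraction": pca.explained_variance_fraction.tolist(),
            "scores": pca.scores.tolist(),
            "ids": pca.ids,
        },
        emulation_flags=[
            {
                "biological_id": e.biological_id,
                "pampa_id": e.pampa_id,
                "dprime": e.dprime,
                "emulates": e.emulates,
            }
            for e in flags
        ],
        provenance=provenance or {},
    )


def write_report(report: AnalysisReport, path) -> None:
    Path(path).write_text(report.to_json(), encoding="utf-8")


def read_report(path) -> AnalysisReport:
    return AnalysisReport.from_json(Path(path).read_text(encoding="utf-8"))
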