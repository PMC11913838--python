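"""Domain model: event tables, code lists, and delimited-text I/O.

The pipeline operates on five longitudinal event tables, carried in memory as
pandas DataFrames inside an :class:`EventStore`:

``patients``
    one row per patient — sex, birth/death dates, socioeconomic fields and
    the most recent smoking-status observation;
``diagnoses``
    dated ICD-9 diagnosis records;
``prescriptions``
    dated ATC prescription records;
``labs``
    dated laboratory results from a closed analyte vocabulary;
``vitals``
    dated clinical measurements (BMI, SBP, DBP).

On disk each table is a UTF-8 comma-delimited file with a fixed header.
Readers validate row-level invariants (parseable ISO dates, known analytes,
non-negative values, ...) and reject offending rows with a counted reason
rather than aborting; a missing mandatory column aborts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

SEXES = ("male", "female")
SMOKING_STATUSES = ("current", "former", "never", "unknown")

#: Closed analyte vocabulary for the ``labs`` table, with units.
ANALYTES = {
    "crp": "mg/L",
    "serum_creatinine": "mg/dL",
    "uacr": "mg/g",
    "haemoglobin": "g/dL",
    "total_cholesterol": "mg/dL",
    "hdl_c": "mg/dL",
    "ldl_c": "mg/dL",
    "triglycerides": "mg/dL",
}

#: Closed vocabulary for the ``vitals`` table, with units.
VITAL_KINDS = {"bmi": "kg/m2", "sbp": "mmHg", "dbp": "mmHg"}

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": [
        "patient_id", "sex", "birth_date", "death_date",
        "reimbursement_rate_pct", "retired", "minimum_earnings",
        "smoking_status", "smoking_date",
    ],
    "diagnoses": ["patient_id", "date", "icd9_code"],
    "prescriptions": ["patient_id", "date", "atc_code"],
    "labs": ["patient_id", "date", "analyte", "value"],
    "vitals": ["patient_id", "date", "kind", "value"],
}

_EPOCH = pd.Timestamp("1970-01-01")


def day_number(dates: pd.Series) -> pd.Series:
    """Whole days since 1970-01-01; all window arithmetic runs on these."""
    return (pd.to_datetime(dates) - _EPOCH).dt.days


@dataclass(frozen=True)
class CodeList:
    """A named concept mapped to hierarchical code prefixes.

    Membership is string-prefix based and case-sensitive: a code belongs to
    the concept iff it starts with any configured prefix.  Both ICD-9 and ATC
    are prefix-hierarchical, so prefix lists express whole code families
    compactly (``410`` covers every acute-MI subcode).
    """

    name: str
    system: str  # "ICD9" or "ATC"
    prefixes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.prefixes:
            raise ValueError(f"code list {self.name!r} has no prefixes")
        if self.system not in ("ICD9", "ATC"):
            raise ValueError(f"unknown code system {self.system!r}")

    def match(self, code: str) -> bool:
        return any(code.startswith(p) for p in self.prefixes)

    def match_series(self, codes: pd.Series) -> pd.Series:
        """Vectorised membership test for a Series of codes."""
        mask = pd.Series(False, index=codes.index, dtype=bool)
        if len(codes) == 0:
            return mask
        for p in self.prefixes:
            mask |= codes.str.startswith(p)
        return mask


def concept_match(code: str, concept: CodeList | str,
                  code_lists: Mapping[str, CodeList] | None = None) -> bool:
    """True iff *code* starts with any prefix of *concept*.

    *concept* may be a :class:`CodeList` or a concept name resolved through
    *code_lists*; an unknown name raises KeyError listing what is available.
    """
    if isinstance(concept, str):
        if code_lists is None or concept not in code_lists:
            available = sorted(code_lists) if code_lists else []
            raise KeyError(
                f"unknown concept {concept!r}; available concepts: {available}"
            )
        concept = code_lists[concept]
    return concept.match(code)


@dataclass
class ReadReport:
    """Row-level accounting from a read: per-table counts and reject reasons."""

    rows_read: Counter = field(default_factory=Counter)
    rows_rejected: Counter = field(default_factory=Counter)
    reasons: Counter = field(default_factory=Counter)

    def reject(self, table: str, reason: str, n: int = 1) -> None:
        if n:
            self.rows_rejected[table] += n
            self.reasons[f"{table}:{reason}"] += n

    @property
    def total_rejected(self) -> int:
        return sum(self.rows_rejected.values())


@dataclass
class EventStore:
    """The five validated event tables."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    labs: pd.DataFrame
    vitals: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "patients": self.patients,
            "diagnoses": self.diagnoses,
            "prescriptions": self.prescriptions,
            "labs": self.labs,
            "vitals": self.vitals,
        }


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise ValueError(f"table {table!r} is missing mandatory columns {missing}")


def _parse_dates(df: pd.DataFrame, col: str, table: str, report: ReadReport,
                 required: bool) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    if required:
        bad = parsed.isna() & df[col].notna() | df[col].isna()
    else:
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
    report.reject(table, f"malformed {col}", int(bad.sum()))
    return parsed, bad


def _parse_bool(s: pd.Series) -> pd.Series:
    return s.map({"True": True, "False": False, True: True, False: False,
                  "true": True, "false": False, "1": True, "0": False})


def _read_csv(path: str | Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    _require_columns(df, table)
    return df


def _validate_patients(df: pd.DataFrame, report: ReadReport) -> pd.DataFrame:
    report.rows_read["patients"] += len(df)
    birth, bad_birth = _parse_dates(df, "birth_date", "patients", report, True)
    death, bad_death = _parse_dates(df, "death_date", "patients", report, False)
    bad_sex = ~df["sex"].isin(SEXES)
    report.reject("patients", "unknown sex", int(bad_sex.sum()))
    reimb = pd.to_numeric(df["reimbursement_rate_pct"], errors="coerce")
    bad_reimb = df["reimbursement_rate_pct"].notna() & (
        reimb.isna() | (reimb < 0) | (reimb > 100)
    )
    report.reject("patients", "reimbursement outside [0,100]", int(bad_reimb.sum()))
    bad_order = death.notna() & birth.notna() & (death < birth)
    report.reject("patients", "death before birth", int(bad_order.sum()))
    bad_smoke = df["smoking_status"].notna() & ~df["smoking_status"].isin(
        SMOKING_STATUSES
    )
    report.reject("patients", "unknown smoking status", int(bad_smoke.sum()))
    smoke_date, _ = _parse_dates(df, "smoking_date", "patients", report, False)
    keep = ~(bad_birth | bad_death | bad_sex | bad_reimb | bad_order | bad_smoke)
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "sex": df["sex"],
        "birth_date": birth,
        "death_date": death,
        "reimbursement_rate_pct": reimb,
        "retired": _parse_bool(df["retired"]),
        "minimum_earnings": _parse_bool(df["minimum_earnings"]),
        "smoking_status": df["smoking_status"],
        "smoking_date": smoke_date,
    })
    return out[keep].reset_index(drop=True)


def _validate_events(df: pd.DataFrame, table: str, code_col: str,
                     report: ReadReport) -> pd.DataFrame:
    report.rows_read[table] += len(df)
    date, bad_date = _parse_dates(df, "date", table, report, True)
    bad_code = df[code_col].isna() | (df[code_col].astype(str).str.len() == 0)
    report.reject(table, f"empty {code_col}", int(bad_code.sum()))
    keep = ~(bad_date | bad_code)
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "date": date,
        code_col: df[code_col],
    })
    return out[keep].reset_index(drop=True)


def _validate_valued(df: pd.DataFrame, table: str, kind_col: str,
                     vocab: Iterable[str], report: ReadReport,
                     strictly_positive: bool) -> pd.DataFrame:
    report.rows_read[table] += len(df)
    date, bad_date = _parse_dates(df, "date", table, report, True)
    bad_kind = ~df[kind_col].isin(set(vocab))
    report.reject(table, f"unknown {kind_col}", int(bad_kind.sum()))
    value = pd.to_numeric(df["value"], errors="coerce")
    if strictly_positive:
        bad_value = value.isna() | (value <= 0)
        reason = "non-positive value"
    else:
        bad_value = value.isna() | (value < 0)
        reason = "negative value"
    # CRP of exactly 0 mg/L is rejected at parse time: the geometric-mean
    # aggregation downstream is undefined at zero (assay floor).
    if table == "labs":
        bad_value |= (df[kind_col] == "crp") & (value == 0)
    report.reject(table, reason, int(bad_value.sum()))
    keep = ~(bad_date | bad_kind | bad_value)
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "date": date,
        kind_col: df[kind_col],
        "value": value,
    })
    return out[keep].reset_index(drop=True)


def read_event_tables(paths: Mapping[str, str | Path]) -> tuple[EventStore, ReadReport]:
    """Read and validate the five event tables.

    *paths* maps table name → file path; all five tables are mandatory.
    Returns the validated store plus a :class:`ReadReport` counting rejected
    rows per table and reason.
    """
    missing = [t for t in TABLE_COLUMNS if t not in paths]
    if missing:
        raise ValueError(f"missing table paths: {missing}")
    report = ReadReport()
    patients = _validate_patients(_read_csv(paths["patients"], "patients"), report)
    diagnoses = _validate_events(
        _read_csv(paths["diagnoses"], "diagnoses"), "diagnoses", "icd9_code", report
    )
    prescriptions = _validate_events(
        _read_csv(paths["prescriptions"], "prescriptions"), "prescriptions",
        "atc_code", report,
    )
    labs = _validate_valued(
        _read_csv(paths["labs"], "labs"), "labs", "analyte", ANALYTES, report,
        strictly_positive=False,
    )
    vitals = _validate_valued(
        _read_csv(paths["vitals"], "vitals"), "vitals", "kind", VITAL_KINDS, report,
        strictly_positive=True,
    )
    store = EventStore(patients, diagnoses, prescriptions, labs, vitals)
    return store, report


def write_event_tables(store: EventStore, outdir: str | Path) -> dict[str, Path]:
    """Write the five tables as CSV under *outdir*; returns table → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in store.tables().items():
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        path = outdir / f"{name}.csv"
        out.to_csv(path, index=False)
        paths[name] = path
    return paths
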