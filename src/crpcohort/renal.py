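"""eGFR (CKD-EPI 2021), CKD classification at a reference date, and staging.

The 2021 CKD-EPI refit removes the race term and estimates GFR from serum
creatinine (Scr, mg/dL), age (years) and sex:

    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200
               * 0.9938^age * (1.012 if female)

with k = 0.7 (female) / 0.9 (male) and a = -0.241 (female) / -0.302 (male),
in mL/min/1.73 m^2.  eGFR is always computed on the fly from stored
creatinine, keeping this function the single source of truth.

CKD at a reference date (the index date, or the data cutoff) holds if any of:

* a stage >=3 CKD diagnosis code on or before the reference date;
* the most recent eGFR strictly before the reference date is < 60
  (optionally, any historical value < 60 — a documented switch);
* the most recent UACR strictly before the reference date is >= 30 mg/g.

Status is ``no-CKD`` when at least one eGFR-evaluable creatinine exists and
no criterion fires, and ``unknown`` when the patient has neither a
creatinine measurement nor a CKD diagnosis (nor a qualifying UACR).

Stage, within CKD, follows the KDIGO eGFR bands on the same most-recent
prior measurements: stage 5 (< 15), stage 4 (15 <= eGFR < 30), stage 3
(30 <= eGFR < 60), stage 1/2 (eGFR >= 60 with UACR >= 30 mg/g).  A CKD
diagnosis code with no eGFR measurement stages as ``unknown``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .model import CodeList, day_number

CKD_STATUSES = ("CKD", "no-CKD", "unknown")
CKD_STAGES = ("stage5", "stage4", "stage3", "stage1/2", "unknown")

_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.241, "male": -0.302}
_SEX_FACTOR = {"female": 1.012, "male": 1.0}


def egfr_ckd_epi_2021(serum_creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m^2) from the 2021 CKD-EPI creatinine
    equation.  Accepts scalars or aligned arrays; *sex* is "male"/"female".

    Strictly decreasing in creatinine and in age.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    sex_arr = np.asarray(sex)
    kappa = np.where(sex_arr == "female", _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(sex_arr == "female", _ALPHA["female"], _ALPHA["male"])
    factor = np.where(sex_arr == "female", _SEX_FACTOR["female"], 1.0)
    ratio = scr / kappa
    egfr = (142.0
            * np.minimum(ratio, 1.0) ** alpha
            * np.maximum(ratio, 1.0) ** -1.200
            * 0.9938 ** age
            * factor)
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


def creatinine_for_egfr(target_egfr, age, sex):
    """Invert the 2021 equation: the Scr (mg/dL) giving *target_egfr*.

    Used by the synthetic-data generator to induce CKD mechanistically
    through creatinine rather than assigning labels.
    """
    target = np.asarray(target_egfr, dtype=float)
    age = np.asarray(age, dtype=float)
    sex_arr = np.asarray(sex)
    kappa = np.where(sex_arr == "female", _KAPPA["female"], _KAPPA["male"])
    alpha = np.where(sex_arr == "female", _ALPHA["female"], _ALPHA["male"])
    factor = np.where(sex_arr == "female", _SEX_FACTOR["female"], 1.0)
    base = 142.0 * 0.9938 ** age * factor  # eGFR at Scr == kappa
    ratio_hi = (target / base) ** (-1.0 / 1.200)   # valid when target <= base
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_lo = (target / base) ** (1.0 / alpha)  # valid when target >= base
    ratio = np.where(target <= base, ratio_hi, ratio_lo)
    out = ratio * kappa
    if out.ndim == 0:
        return float(out)
    return out


def _latest_prior(labs: pd.DataFrame, analyte: str,
                  reference: pd.DataFrame) -> pd.DataFrame:
    """Most recent lab of *analyte* strictly before each patient's reference
    date; returns patient_id, value, date (one row per patient with data)."""
    sub = labs[labs["analyte"] == analyte]
    if sub.empty:
        return pd.DataFrame(columns=["patient_id", "value", "date"])
    merged = sub.merge(reference, on="patient_id", how="inner")
    merged = merged[merged["date"] < merged["reference_date"]]
    if merged.empty:
        return pd.DataFrame(columns=["patient_id", "value", "date"])
    merged = merged.sort_values(["patient_id", "date"], kind="mergesort")
    last = merged.groupby("patient_id", sort=False).tail(1)
    return last[["patient_id", "value", "date"]].reset_index(drop=True)


def classify_ckd(
    patients: pd.DataFrame,
    labs: pd.DataFrame,
    diagnoses: pd.DataFrame,
    reference_dates: pd.DataFrame,
    ckd_dx_concept: CodeList,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """CKD status and stage for each patient at their reference date.

    Parameters
    ----------
    patients
        validated patients table (sex and birth_date are used for eGFR).
    reference_dates
        ``patient_id, reference_date`` — typically the index date, or the
        data cutoff for all patients.

    Returns one row per patient in *reference_dates* with columns
    ``patient_id, reference_date, latest_egfr, egfr_date, latest_uacr,
    uacr_date, ckd_status, ckd_stage``.
    """
    cfg = config or RunConfig()
    th = cfg.thresholds
    ref = reference_dates[["patient_id", "reference_date"]].copy()
    ref["reference_date"] = pd.to_datetime(ref["reference_date"])

    demo = patients.set_index("patient_id")

    creat = labs[labs["analyte"] == "serum_creatinine"]
    creat = creat.merge(ref, on="patient_id", how="inner")
    creat = creat[creat["date"] < creat["reference_date"]].copy()
    has_creatinine = set(creat["patient_id"])
    if not creat.empty:
        # age at the measurement date, in whole years
        birth = creat["patient_id"].map(demo["birth_date"])
        age = (day_number(creat["date"]) - day_number(birth)) / 365.25
        sex = creat["patient_id"].map(demo["sex"])
        creat["egfr"] = egfr_ckd_epi_2021(
            creat["value"].to_numpy(), age.to_numpy(), sex.to_numpy()
        )
        creat = creat.sort_values(["patient_id", "date"], kind="mergesort")
        latest = creat.groupby("patient_id", sort=False).tail(1)
        latest_egfr = latest.set_index("patient_id")["egfr"]
        egfr_date = latest.set_index("patient_id")["date"]
        min_egfr = creat.groupby("patient_id", sort=False)["egfr"].min()
    else:
        latest_egfr = pd.Series(dtype=float)
        egfr_date = pd.Series(dtype="datetime64[ns]")
        min_egfr = pd.Series(dtype=float)

    uacr_last = _latest_prior(labs, "uacr", ref).set_index("patient_id")
    ckd_dx = diagnoses[ckd_dx_concept.match_series(diagnoses["icd9_code"])]
    ckd_dx = ckd_dx.merge(ref, on="patient_id", how="inner")
    dx_prior = set(ckd_dx[ckd_dx["date"] <= ckd_dx["reference_date"]]["patient_id"])

    rows = []
    for pid, ref_date in zip(ref["patient_id"], ref["reference_date"]):
        egfr = latest_egfr.get(pid, np.nan)
        egfr_when = egfr_date.get(pid, pd.NaT)
        uacr = uacr_last["value"].get(pid, np.nan) if len(uacr_last) else np.nan
        uacr_when = uacr_last["date"].get(pid, pd.NaT) if len(uacr_last) else pd.NaT
        egfr_criterion = (
            (min_egfr.get(pid, np.nan) < th.egfr_ckd)
            if cfg.switches.egfr_any_historical
            else (egfr < th.egfr_ckd)
        )
        fired = (
            (pid in dx_prior)
            or bool(egfr_criterion)
            or (not np.isnan(uacr) and uacr >= th.uacr_ckd)
        )
        if fired:
            status = "CKD"
        elif pid in has_creatinine:
            status = "no-CKD"
        else:
            status = "unknown"

        stage = None
        if status == "CKD":
            if np.isnan(egfr):
                stage = "unknown"
            elif egfr < th.egfr_stage5:
                stage = "stage5"
            elif egfr < th.egfr_stage4:
                stage = "stage4"
            elif egfr < th.egfr_ckd:
                stage = "stage3"
            elif not np.isnan(uacr) and uacr >= th.uacr_ckd:
                stage = "stage1/2"
            else:
                stage = "unknown"
        rows.append((pid, ref_date, egfr, egfr_when, uacr, uacr_when,
                     status, stage))

    return pd.DataFrame(rows, columns=[
        "patient_id", "reference_date", "latest_egfr", "egfr_date",
        "latest_uacr", "uacr_date", "ckd_status", "ckd_stage",
    ])


def assign_stage(latest_egfr: float, latest_uacr: float,
                 ckd_status: str = "CKD",
                 config: RunConfig | None = None) -> str:
    """Stage a single CKD assessment from its most recent prior measurements.

    Raises if called with a non-CKD status.
    """
    if ckd_status != "CKD":
        raise ValueError("staging requires ckd_status == 'CKD'")
    th = (config or RunConfig()).thresholds
    egfr = float("nan") if latest_egfr is None else float(latest_egfr)
    uacr = float("nan") if latest_uacr is None else float(latest_uacr)
    if np.isnan(egfr):
        return "unknown"
    if egfr < th.egfr_stage5:
        return "stage5"
    if egfr < th.egfr_stage4:
        return "stage4"
    if egfr < th.egfr_ckd:
        return "stage3"
    if not np.isnan(uacr) and uacr >= th.uacr_ckd:
        return "stage1/2"
    return "unknown"
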