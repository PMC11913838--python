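"""Cohort assembly: ASCVD identification, patient-level exclusions,
low-SES derivation, index records, and the attrition flowchart.

The cohort comprises adult patients (>= 18 years at the index date) with at
least one ASCVD diagnosis, no chronic-infection diagnosis ever (HIV,
tuberculosis, viral hepatitis and similar), and at least one eligible
grouped CRP measurement.  The index date is the first grouped eligible CRP.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import RunConfig
from .eligibility import assign_index, run_eligibility
from .model import CodeList, EventStore
from .renal import classify_ckd

ASCVD_SUBTYPES = {
    "coronary": "ascvd_coronary",
    "cerebrovascular": "ascvd_cerebrovascular",
    "pad": "ascvd_pad",
    "other": "ascvd_other",
}


def first_ascvd(diagnoses: pd.DataFrame,
                code_lists: dict[str, CodeList]) -> pd.DataFrame:
    """Per-patient first ASCVD date plus ever-coded subtype flags.

    Subtype flags are non-exclusive (a patient may carry several); the first
    ASCVD date is the minimum date over all subtype-matching diagnoses.
    Patients with no ASCVD code do not appear.
    """
    masks = {
        sub: code_lists[concept].match_series(diagnoses["icd9_code"])
        for sub, concept in ASCVD_SUBTYPES.items()
    }
    any_mask = np.logical_or.reduce([m.to_numpy() for m in masks.values()])
    matched = diagnoses[any_mask]
    if matched.empty:
        return pd.DataFrame(columns=["patient_id", "first_ascvd_date",
                                     *ASCVD_SUBTYPES])
    first = matched.groupby("patient_id")["date"].min().rename("first_ascvd_date")
    out = first.reset_index()
    for sub in ASCVD_SUBTYPES:
        flagged = set(diagnoses.loc[masks[sub], "patient_id"])
        out[sub] = out["patient_id"].isin(flagged)
    return out


def age_at(dates: pd.Series, birth_dates: pd.Series) -> pd.Series:
    """Completed years between birth date and a query date (calendar age)."""
    d = pd.to_datetime(dates)
    b = pd.to_datetime(birth_dates)
    before_birthday = (d.dt.month < b.dt.month) | (
        (d.dt.month == b.dt.month) & (d.dt.day < b.dt.day)
    )
    return d.dt.year - b.dt.year - before_birthday.astype(int)


def derive_low_ses(patients: pd.DataFrame) -> pd.Series:
    """Low socioeconomic status: minimum earnings, a 100% drug reimbursement
    rate, or non-retired with reimbursement >= 90%.

    Absent fields are treated as non-qualifying; the returned Series is
    aligned to *patients*.
    """
    def as_bool(col: pd.Series) -> pd.Series:
        return col.map(lambda v: bool(v) if pd.notna(v) else False)

    earnings = as_bool(patients["minimum_earnings"])
    reimb = pd.to_numeric(patients["reimbursement_rate_pct"], errors="coerce")
    retired = as_bool(patients["retired"])
    full = reimb.fillna(-1) == 100
    high_nonretired = (~retired) & (reimb.fillna(-1) >= 90)
    return earnings | full | high_nonretired


def ses_missingness(patients: pd.DataFrame) -> dict[str, int]:
    return {
        "minimum_earnings": int(patients["minimum_earnings"].isna().sum()),
        "reimbursement_rate_pct": int(
            patients["reimbursement_rate_pct"].isna().sum()),
        "retired": int(patients["retired"].isna().sum()),
    }


@dataclass
class FlowchartCounts:
    """Attrition accounting, non-increasing along the flow."""

    ascvd_identified: int
    after_patient_exclusions: int
    with_any_crp: int
    with_eligible_crp: int

    def __post_init__(self) -> None:
        seq = (self.ascvd_identified, self.after_patient_exclusions,
               self.with_any_crp, self.with_eligible_crp)
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"flowchart counts must be non-increasing: {seq}")

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def build_cohort(
    store: EventStore,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, FlowchartCounts]:
    """Run ASCVD identification, CRP eligibility and CKD classification.

    Returns ``(index_records, grouped_eligible_crps, exclusion_log,
    flowchart)``.  ``index_records`` has one row per included patient:
    patient_id, first_ascvd_date, index_date, index_crp, si_at_index,
    ckd_status, ckd_stage, subtype flags, age_at_index, sex, low_ses.
    """
    cfg = config or RunConfig()
    lists = cfg.resolved_code_lists()

    ascvd = first_ascvd(store.diagnoses, lists)
    n_identified = len(ascvd)

    # Patient-level exclusion: any chronic-infection diagnosis, ever.
    chronic = lists["chronic_infection"].match_series(store.diagnoses["icd9_code"])
    chronic_pids = set(store.diagnoses.loc[chronic, "patient_id"])
    ascvd = ascvd[~ascvd["patient_id"].isin(chronic_pids)].reset_index(drop=True)

    demo = store.patients.set_index("patient_id")
    in_ascvd = set(ascvd["patient_id"])

    crps = store.labs[(store.labs["analyte"] == "crp")
                      & store.labs["patient_id"].isin(in_ascvd)].copy()
    # Study-window restriction on raw CRP measurements.
    crps = crps[(crps["date"] >= pd.Timestamp(cfg.study_start))
                & (crps["date"] <= pd.Timestamp(cfg.study_end))]

    rx = store.prescriptions
    infection_rx = rx[lists["antibiotic_antiviral"].match_series(rx["atc_code"])]
    immuno_rx = rx[lists["immunosuppressant"].match_series(rx["atc_code"])]
    dx = store.diagnoses
    malignancy = lists["malignancy"].match_series(dx["icd9_code"])
    nmsc = lists["non_melanoma_skin_cancer"].match_series(dx["icd9_code"])
    malignancy_dx = dx[malignancy & ~nmsc]

    first_dates = ascvd.set_index("patient_id")["first_ascvd_date"]
    grouped, exclusion_log = run_eligibility(
        crps[["patient_id", "date", "value"]], first_dates,
        infection_rx, immuno_rx, malignancy_dx, cfg,
    )

    index_seed = assign_index(grouped, cfg.thresholds.crp_si)
    records = index_seed.merge(ascvd, on="patient_id", how="inner")
    records["age_at_index"] = age_at(
        records["index_date"], records["patient_id"].map(demo["birth_date"])
    )
    # Age eligibility is anchored at the index date.
    records = records[records["age_at_index"] >= 18].reset_index(drop=True)

    records["sex"] = records["patient_id"].map(demo["sex"])
    low_ses = derive_low_ses(store.patients)
    low_ses.index = store.patients["patient_id"]
    records["low_ses"] = records["patient_id"].map(low_ses)

    renal = classify_ckd(
        store.patients, store.labs, store.diagnoses,
        records.rename(columns={"index_date": "reference_date"})[
            ["patient_id", "reference_date"]],
        lists["ckd_stage3_plus"], cfg,
    )
    records = records.merge(
        renal[["patient_id", "ckd_status", "ckd_stage", "latest_egfr",
               "latest_uacr"]],
        on="patient_id", how="left",
    )

    included = set(records["patient_id"])
    grouped = grouped[grouped["patient_id"].isin(included)].reset_index(drop=True)

    with_any_crp = len(set(crps["patient_id"]))
    flow = FlowchartCounts(
        ascvd_identified=n_identified,
        after_patient_exclusions=len(ascvd),
        with_any_crp=with_any_crp,
        with_eligible_crp=len(records),
    )
    return records, grouped, exclusion_log, flow
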