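"""Synthetic primary-care event-table generator with exported ground truth.

The generator emulates the longitudinal structure the analysis assumes —
not a clinically faithful population.  Per patient it draws:

* demographics (age about 71 ± 12 at first ASCVD, 57% male), SES fields and
  a smoking observation;
* a first ASCVD diagnosis date in the study window with one or two subtype
  codes, and an annual-hazard mortality process;
* sparse irregular CRP testing after the first ASCVD diagnosis, with
  baseline values log-normal per CKD stratum, truncated at 20 mg/L (values
  above the active-infection cap arise only from infection episodes);
* infection episodes that jointly emit an antibiotic prescription and
  inflate every CRP test falling in the episode's eligibility window to
  above 20 mg/L (so the exclusion engine can be scored against truth flags);
* a CKD stratum induced mechanistically through creatinine and UACR
  trajectories (inverting the CKD-EPI 2021 equation), with a configurable
  fraction of patients carrying no renal data at all;
* immunosuppressant users, cancer and non-melanoma-skin-cancer diagnoses,
  chronic-infection carriers, comorbidity diagnoses, drug-class
  dispensations, and baseline lab/vital panels.

Ground truth records each patient's true CKD stratum, the generator's own
first-eligible SI indicator (computed from the un-inflated post-ASCVD CRP
values with the same 90-day geometric-mean bookkeeping, independently coded
here), and per-CRP flags marking infection-inflated and pre-ASCVD values.

Everything derives from one ``numpy.random.default_rng(seed)`` stream, so a
fixed seed reproduces the tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .codes import REPRESENTATIVE_CODES
from .config import GeneratorConfig, RunConfig
from .model import EventStore
from .renal import creatinine_for_egfr

_EPOCH = pd.Timestamp("1970-01-01")

_STAGES = ("stage3", "stage4", "stage5", "stage1/2")
#: target-eGFR bands per true stage, with margin from the 15/30/60 edges so
#: that the +-1.5% measurement noise cannot flip the classification
_EGFR_BANDS = {
    "stage3": (32.0, 57.0),
    "stage4": (16.0, 28.0),
    "stage5": (6.0, 13.0),
    "stage1/2": (65.0, 105.0),
    "none": (65.0, 110.0),
}


def _day(date) -> int:
    return (pd.Timestamp(date) - _EPOCH).days


@dataclass
class GroundTruth:
    """Per-patient truth plus per-CRP-event flags."""

    patients: pd.DataFrame
    crp_flags: pd.DataFrame


def _truncated_lognormal(rng: np.random.Generator, mu: np.ndarray,
                         sigma: np.ndarray, upper: float) -> np.ndarray:
    """Exact draws from a log-normal conditioned on being <= upper."""
    z_cap = (np.log(upper) - mu) / sigma
    u = rng.random(mu.shape) * ndtr(z_cap)
    # guard the open interval for ndtri
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return np.exp(mu + sigma * ndtri(u))


def _group_first_gmean(days: np.ndarray, values: np.ndarray,
                       window: int) -> float:
    """Geometric mean of the first greedy 90-day group (truth bookkeeping;
    intentionally coded independently of the eligibility engine)."""
    order = np.argsort(days, kind="stable")
    d = days[order]
    v = values[order]
    members = [v[0]]
    for i in range(1, len(d)):
        if d[i] - d[0] <= window:
            members.append(v[i])
        else:
            break
    return float(np.exp(np.mean(np.log(members))))


def generate(config: RunConfig | GeneratorConfig | None = None,
             ) -> tuple[EventStore, GroundTruth]:
    """Generate the five event tables and the ground truth.

    Accepts a full :class:`RunConfig` (study window taken from it) or a bare
    :class:`GeneratorConfig` (study defaults).
    """
    if config is None:
        config = RunConfig()
    if isinstance(config, GeneratorConfig):
        cfg = RunConfig(generator=config)
    else:
        cfg = config
    g = cfg.generator
    rng = np.random.default_rng(g.seed)
    n = g.n_patients

    start = _day(cfg.study_start)
    end = _day(cfg.study_end)
    span = end - start

    pid = np.array([f"P{i:06d}" for i in range(n)])
    male = rng.random(n) < g.p_male
    sex = np.where(male, "male", "female")

    ascvd_day = start + rng.integers(0, max(1, int(span * 0.7)), n)
    age_at_ascvd = np.clip(rng.normal(g.age_mean, g.age_sd, n), 20.0, 100.0)
    birth_day = ascvd_day - np.round(age_at_ascvd * 365.25).astype(int)

    # mortality: exponential with the hazard implied by the annual risk
    if g.annual_mortality > 0:
        hazard = -np.log1p(-g.annual_mortality)
        ttd = rng.exponential(1.0 / hazard, n) * 365.25
    else:
        ttd = np.full(n, np.inf)
    death_day = ascvd_day + ttd
    died = death_day <= end
    fu_end = np.where(died, death_day, end).astype(int)
    fu_years = np.maximum((fu_end - ascvd_day) / 365.25, 0.0)

    # --- diagnoses ---------------------------------------------------------
    dx_pid: list[np.ndarray] = []
    dx_day: list[np.ndarray] = []
    dx_code: list[np.ndarray] = []

    def emit_dx(mask_or_rows, days, code):
        rows = np.flatnonzero(mask_or_rows) if mask_or_rows.dtype == bool \
            else mask_or_rows
        if len(rows) == 0:
            return
        dx_pid.append(pid[rows])
        dx_day.append(np.asarray(days, dtype=int))
        dx_code.append(np.full(len(rows), code))

    subtype_names = ("ascvd_coronary", "ascvd_cerebrovascular",
                     "ascvd_pad", "ascvd_other")
    primary = rng.choice(4, n, p=[0.50, 0.35, 0.06, 0.09])
    for k, concept in enumerate(subtype_names):
        emit_dx(primary == k, ascvd_day[primary == k],
                REPRESENTATIVE_CODES[concept])
    extra = rng.random(n) < 0.25
    extra_sub = rng.choice(4, n, p=[0.35, 0.35, 0.15, 0.15])
    extra_day = ascvd_day + rng.integers(0, 731, n)
    extra &= extra_day <= fu_end
    for k, concept in enumerate(subtype_names):
        m = extra & (extra_sub == k)
        emit_dx(m, extra_day[m], REPRESENTATIVE_CODES[concept])

    chronic_inf = rng.random(n) < g.p_chronic_infection
    emit_dx(chronic_inf, ascvd_day[chronic_inf] - rng.integers(0, 1826, int(chronic_inf.sum())),
            REPRESENTATIVE_CODES["chronic_infection"])

    has_cancer = rng.random(n) < g.p_cancer
    cancer_day = ascvd_day + rng.integers(-730, 731, n)
    emit_dx(has_cancer, cancer_day[has_cancer], REPRESENTATIVE_CODES["malignancy"])
    has_nmsc = rng.random(n) < g.p_nmsc
    emit_dx(has_nmsc, (ascvd_day + rng.integers(-730, 731, n))[has_nmsc],
            REPRESENTATIVE_CODES["non_melanoma_skin_cancer"])

    for concept, prev in g.comorbidity_prevalence.items():
        m = rng.random(n) < prev
        emit_dx(m, (ascvd_day - rng.integers(1, 1826, n))[m],
                REPRESENTATIVE_CODES[concept])

    # --- renal trajectories ------------------------------------------------
    true_ckd = rng.random(n) < g.p_ckd
    stage_idx = rng.choice(4, n, p=list(g.stage_mix))
    true_stage = np.where(true_ckd, np.array(_STAGES)[stage_idx], "none")
    renal_missing = rng.random(n) < g.p_renal_data_missing

    lo = np.array([_EGFR_BANDS[s][0] for s in true_stage])
    hi = np.array([_EGFR_BANDS[s][1] for s in true_stage])
    target_egfr = rng.uniform(lo, hi)

    lab_pid: list[np.ndarray] = []
    lab_day: list[np.ndarray] = []
    lab_analyte: list[np.ndarray] = []
    lab_value: list[np.ndarray] = []

    def emit_lab(rows, days, analyte, values):
        rows = np.asarray(rows)
        if len(rows) == 0:
            return
        lab_pid.append(pid[rows])
        lab_day.append(np.asarray(days, dtype=int))
        lab_analyte.append(np.full(len(rows), analyte))
        lab_value.append(np.asarray(values, dtype=float))

    renal_rows = np.flatnonzero(~renal_missing)
    for offset_lo, offset_hi, sign in ((30, 181, -1), (60, 400, +1)):
        days = ascvd_day[renal_rows] + sign * rng.integers(
            offset_lo, offset_hi, len(renal_rows))
        noise = 1.0 + rng.uniform(-0.015, 0.015, len(renal_rows))
        age_m = (days - birth_day[renal_rows]) / 365.25
        scr = creatinine_for_egfr(target_egfr[renal_rows] * noise, age_m,
                                  sex[renal_rows])
        emit_lab(renal_rows, days, "serum_creatinine", np.round(scr, 3))

    # UACR: stage 1/2 always >= 30 (it defines the stratum); advanced stages
    # half the time; non-CKD always < 30 when measured.
    s12 = np.flatnonzero((true_stage == "stage1/2") & ~renal_missing)
    uacr_day = ascvd_day - rng.integers(30, 181, n)
    emit_lab(s12, uacr_day[s12], "uacr",
             np.round(rng.uniform(35.0, 200.0, len(s12)), 1))
    adv = np.flatnonzero(np.isin(true_stage, ("stage3", "stage4", "stage5"))
                         & ~renal_missing & (rng.random(n) < 0.5))
    emit_lab(adv, uacr_day[adv], "uacr",
             np.round(rng.uniform(20.0, 300.0, len(adv)), 1))
    nonckd_meas = np.flatnonzero(~true_ckd & ~renal_missing
                                 & (rng.random(n) < g.p_uacr_measured))
    emit_lab(nonckd_meas, uacr_day[nonckd_meas], "uacr",
             np.round(rng.uniform(3.0, 25.0, len(nonckd_meas)), 1))

    ckd_coded = (np.isin(true_stage, ("stage3", "stage4", "stage5"))
                 & ~renal_missing & (rng.random(n) < g.p_ckd_diagnosis_coded))
    emit_dx(ckd_coded, (ascvd_day - rng.integers(0, 366, n))[ckd_coded],
            REPRESENTATIVE_CODES["ckd_stage3_plus"])

    # --- prescriptions -----------------------------------------------------
    rx_pid: list[np.ndarray] = []
    rx_day: list[np.ndarray] = []
    rx_code: list[np.ndarray] = []

    def emit_rx(rows, days, code):
        rows = np.asarray(rows)
        if len(rows) == 0:
            return
        rx_pid.append(pid[rows])
        rx_day.append(np.asarray(days, dtype=int))
        rx_code.append(np.full(len(rows), code))

    immuno_user = rng.random(n) < g.p_immunosuppressant_user
    n_immuno_rx = np.where(immuno_user, rng.integers(1, 4, n), 0)
    rows = np.repeat(np.arange(n), n_immuno_rx)
    if len(rows):
        days = ascvd_day[rows] - 180 + rng.integers(
            0, np.maximum(fu_end[rows] - ascvd_day[rows] + 181, 1))
        emit_rx(rows, days, REPRESENTATIVE_CODES["immunosuppressant"])

    # --- CRP process -------------------------------------------------------
    mu_group = np.where(true_ckd, np.log(g.crp_median_ckd),
                        np.log(g.crp_median_nonckd))
    intercept_sd = min(g.crp_patient_log_sd, g.crp_log_sigma)
    sigma_within = float(np.sqrt(max(g.crp_log_sigma ** 2 - intercept_sd ** 2,
                                     1e-4)))
    patient_mu = mu_group + rng.normal(0.0, intercept_sd, n)

    n_tests = rng.poisson(g.crp_tests_per_year * fu_years)
    rows = np.repeat(np.arange(n), n_tests)
    test_day = np.empty(0, dtype=int)
    if len(rows):
        width = np.maximum(fu_end[rows] - ascvd_day[rows] + 1, 1)
        test_day = ascvd_day[rows] + (rng.random(len(rows)) * width).astype(int)
    test_rows = rows
    test_val = _truncated_lognormal(
        rng, patient_mu[test_rows], np.full(len(test_rows), sigma_within),
        cfg.thresholds.crp_infection_max,
    ) if len(test_rows) else np.empty(0)
    pre_flag = np.zeros(len(test_rows), dtype=bool)

    # pre-ASCVD CRP tests (excluded downstream by rule i)
    pre_mask = (rng.random(n) < g.p_pre_ascvd_crp) & (ascvd_day > start + 1)
    pre_rows = np.flatnonzero(pre_mask)
    if len(pre_rows):
        pre_day = start + (rng.random(len(pre_rows))
                           * (ascvd_day[pre_rows] - start - 1)).astype(int)
        pre_val = _truncated_lognormal(
            rng, patient_mu[pre_rows], np.full(len(pre_rows), sigma_within),
            cfg.thresholds.crp_infection_max,
        )
        test_rows = np.concatenate([test_rows, pre_rows])
        test_day = np.concatenate([test_day, pre_day])
        test_val = np.concatenate([test_val, pre_val])
        pre_flag = np.concatenate([pre_flag, np.ones(len(pre_rows), dtype=bool)])

    # infection episodes: antibiotic rx + inflated CRP
    n_episodes = rng.poisson(g.infection_episodes_per_year * fu_years)
    ep_rows = np.repeat(np.arange(n), n_episodes)
    inf_flag = np.zeros(len(test_rows), dtype=bool)
    if len(ep_rows):
        width = np.maximum(fu_end[ep_rows] - ascvd_day[ep_rows] + 1, 1)
        ep_day = ascvd_day[ep_rows] + (rng.random(len(ep_rows)) * width).astype(int)
        emit_rx(ep_rows, ep_day, REPRESENTATIVE_CODES["antibiotics"])

        # optional CRP test inside the episode, always above the cap
        with_test = rng.random(len(ep_rows)) < g.p_crp_test_in_episode
        et_rows = ep_rows[with_test]
        if len(et_rows):
            et_day = ep_day[with_test] + rng.integers(0, 15, len(et_rows))
            et_val = (cfg.thresholds.crp_infection_max
                      + rng.gamma(2.0, 15.0, len(et_rows)))
            test_rows = np.concatenate([test_rows, et_rows])
            test_day = np.concatenate([test_day, et_day])
            test_val = np.concatenate([test_val, et_val])
            pre_flag = np.concatenate([pre_flag,
                                       np.zeros(len(et_rows), dtype=bool)])
            inf_flag = np.concatenate([inf_flag,
                                       np.ones(len(et_rows), dtype=bool)])

        # any other CRP test inside an episode's eligibility window
        # (rx day p excludes CRP at t whenever p - 7 <= t <= p + 60)
        ep_by_patient: dict[int, np.ndarray] = {}
        for r, d in zip(ep_rows, ep_day):
            ep_by_patient.setdefault(int(r), []).append(int(d))
        for r in ep_by_patient:
            ep_by_patient[r] = np.sort(np.asarray(ep_by_patient[r]))
        for i in range(len(test_rows)):
            if inf_flag[i]:
                continue
            eps = ep_by_patient.get(int(test_rows[i]))
            if eps is None:
                continue
            t = test_day[i]
            j = np.searchsorted(eps, t - cfg.windows.infection_after_rx,
                                side="left")
            k = np.searchsorted(eps, t + cfg.windows.infection_before_rx,
                                side="right")
            if k > j:
                test_val[i] = (cfg.thresholds.crp_infection_max
                               + rng.gamma(2.0, 15.0))
                inf_flag[i] = True

    # round once so the emitted table, the truth flags and the truth SI
    # bookkeeping all see identical values
    test_val = np.round(test_val, 2)
    if len(test_rows):
        emit_lab(test_rows, test_day, "crp", test_val)

    # --- drug-class dispensations ------------------------------------------
    # anchored near each patient's first post-ASCVD CRP so that pre-index
    # exposure windows are populated
    first_crp_day = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    routine = ~pre_flag & ~inf_flag
    if routine.any():
        np.minimum.at(first_crp_day, test_rows[routine], test_day[routine])
    anchor = np.where(first_crp_day < np.iinfo(np.int64).max,
                      first_crp_day, ascvd_day + 180)
    for concept, prev in g.drug_prevalence.items():
        m = np.flatnonzero(rng.random(n) < prev)
        if len(m):
            days = anchor[m] - rng.integers(1, 365, len(m))
            emit_rx(m, days, REPRESENTATIVE_CODES[concept])

    # --- baseline labs and vitals ------------------------------------------
    panel_specs = (
        ("haemoglobin", 13.4, 2.2, 5.0, 20.0),
        ("total_cholesterol", 174.0, 43.0, 60.0, 400.0),
        ("hdl_c", 47.6, 13.0, 15.0, 120.0),
        ("ldl_c", 99.5, 36.0, 20.0, 300.0),
        ("triglycerides", 135.0, 70.0, 30.0, 600.0),
    )
    p_panel = min(1.0, g.lab_panels_per_year)
    panel_rows = np.flatnonzero(rng.random(n) < p_panel)
    panel_day = anchor - rng.integers(1, 500, n)
    for analyte, mean, sd, lo_c, hi_c in panel_specs:
        vals = np.clip(rng.normal(mean, sd, len(panel_rows)), lo_c, hi_c)
        emit_lab(panel_rows, panel_day[panel_rows], analyte, np.round(vals, 1))

    vital_specs = (("bmi", 29.4, 5.3, 15.0, 60.0),
                   ("sbp", 136.0, 25.0, 70.0, 250.0),
                   ("dbp", 79.0, 12.0, 40.0, 150.0))
    p_vital = min(1.0, g.vital_sets_per_year)
    vital_rows = np.flatnonzero(rng.random(n) < p_vital)
    vital_day = anchor - rng.integers(1, 500, n)
    vit_pid, vit_day_l, vit_kind, vit_val = [], [], [], []
    for kind, mean, sd, lo_c, hi_c in vital_specs:
        vals = np.clip(rng.normal(mean, sd, len(vital_rows)), lo_c, hi_c)
        vit_pid.append(pid[vital_rows])
        vit_day_l.append(vital_day[vital_rows])
        vit_kind.append(np.full(len(vital_rows), kind))
        vit_val.append(np.round(vals, 1))

    # --- patients table ----------------------------------------------------
    smoking = rng.choice(["current", "former", "never", "unknown"], n,
                         p=[0.22, 0.25, 0.48, 0.05])
    minimum_earnings = rng.random(n) < 0.05
    retired = np.where(age_at_ascvd >= 65, rng.random(n) < 0.85,
                       rng.random(n) < 0.15)
    reimb = rng.choice([40.0, 50.0, 60.0, 90.0, 100.0], n,
                       p=[0.30, 0.30, 0.20, 0.12, 0.08])

    def to_dates(days):
        return pd.to_datetime(np.asarray(days, dtype="int64"), unit="D")

    patients = pd.DataFrame({
        "patient_id": pid,
        "sex": sex,
        "birth_date": to_dates(birth_day),
        "death_date": pd.Series(pd.NaT, index=range(n),
                                dtype="datetime64[ns]").mask(
            died, to_dates(np.where(died, fu_end, 0))),
        "reimbursement_rate_pct": reimb,
        "retired": retired,
        "minimum_earnings": minimum_earnings,
        "smoking_status": smoking,
        "smoking_date": to_dates(ascvd_day),
    })

    def assemble(pids, days, cols: dict) -> pd.DataFrame:
        if not pids:
            return pd.DataFrame({"patient_id": [], "date": [], **{
                k: [] for k in cols}})
        df = pd.DataFrame({
            "patient_id": np.concatenate(pids),
            "date": to_dates(np.concatenate(days)),
            **{k: np.concatenate(v) for k, v in cols.items()},
        })
        return (df.sort_values(["patient_id", "date"] + list(cols), kind="mergesort")
                .reset_index(drop=True))

    diagnoses = assemble(dx_pid, dx_day, {"icd9_code": dx_code})
    prescriptions = assemble(rx_pid, rx_day, {"atc_code": rx_code})
    labs = assemble(lab_pid, lab_day, {"analyte": lab_analyte,
                                       "value": lab_value})
    vitals = assemble(vit_pid, vit_day_l, {"kind": vit_kind, "value": vit_val})
    store = EventStore(patients, diagnoses, prescriptions, labs, vitals)

    # --- ground truth ------------------------------------------------------
    clean = routine  # post-ASCVD, never inflated
    true_si = np.full(n, np.nan)
    order = np.argsort(test_rows[clean], kind="stable")
    cr = test_rows[clean][order]
    cd = test_day[clean][order]
    cv = test_val[clean][order]
    boundaries = np.flatnonzero(np.diff(cr)) + 1
    for chunk_rows, chunk_days, chunk_vals in zip(
            np.split(cr, boundaries), np.split(cd, boundaries),
            np.split(cv, boundaries)):
        if len(chunk_rows) == 0:
            continue
        r = int(chunk_rows[0])
        first = _group_first_gmean(chunk_days, chunk_vals,
                                   cfg.windows.crp_grouping)
        true_si[r] = float(first >= cfg.thresholds.crp_si)

    gt_patients = pd.DataFrame({
        "patient_id": pid,
        "true_ckd": true_ckd,
        "true_ckd_stage": true_stage,
        "renal_data_missing": renal_missing,
        "immunosuppressant_user": immuno_user,
        "has_cancer": has_cancer,
        "has_chronic_infection": chronic_inf,
        "true_si_first": true_si,  # NaN when no clean post-ASCVD CRP exists
        "first_ascvd_date": to_dates(ascvd_day),
    })
    crp_flags = pd.DataFrame({
        "patient_id": pid[test_rows],
        "date": to_dates(test_day),
        "value": np.round(test_val, 2),
        "infection_inflated": inf_flag,
        "pre_ascvd": pre_flag,
    }).sort_values(["patient_id", "date", "value"],
                   kind="mergesort").reset_index(drop=True)
    return store, GroundTruth(gt_patients, crp_flags)


def truth_summary(ground_truth: GroundTruth) -> pd.DataFrame:
    """True stratum prevalences and true SI proportions, as a tidy table."""
    gt = ground_truth.patients
    if gt.empty:
        raise ValueError("empty ground truth")
    n = len(gt)
    rows = [("true_ckd_prevalence", float(gt["true_ckd"].mean()), n)]
    for stage in _STAGES:
        rows.append((f"true_stage_{stage}",
                     float((gt["true_ckd_stage"] == stage).mean()), n))
    defined = gt["true_si_first"].notna()
    if defined.any():
        rows.append(("true_si_at_first_eligible",
                     float(gt.loc[defined, "true_si_first"].mean()),
                     int(defined.sum())))
        for label, mask in (("ckd", gt["true_ckd"]), ("nonckd", ~gt["true_ckd"])):
            sel = defined & mask
            if sel.any():
                rows.append((f"true_si_at_first_eligible_{label}",
                             float(gt.loc[sel, "true_si_first"].mean()),
                             int(sel.sum())))
    return pd.DataFrame(rows, columns=["quantity", "proportion", "denominator"])
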