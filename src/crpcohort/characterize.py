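"""Baseline characteristics and drug-utilization tables by SI status.

Baseline labs and vitals take the most recent value dated within 18 months
strictly before the index date (a measurement on the index day itself is
outside the window).  Comorbidity history is any matching diagnosis strictly
before index; the "cancer" comorbidity additionally requires the code more
than 3 years before index (more recent malignancies make the CRP itself
ineligible).  Drug exposure is any matching dispensation in
``[index - 365 d, index)`` pre-index or ``(index, index + 365 d]``
post-index; the index day belongs to neither window.

Two-group comparisons follow the conventional Table-1 defaults: chi-squared
for categorical variables, Welch two-sample t-test for approximately normal
continuous variables, Wilcoxon rank-sum for skewed ones (CRP, UACR,
triglycerides).  No multiple-testing correction is applied; p-values are
descriptive.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .codes import COMORBIDITY_CONCEPTS, UTILIZATION_CLASSES
from .config import RunConfig
from .model import CodeList
from .renal import egfr_ckd_epi_2021

#: baseline variable -> (source table, key, summary kind)
BASELINE_VARIABLES: dict[str, tuple[str, str, str]] = {
    "crp": ("index", "index_crp", "skewed"),
    "egfr": ("derived", "egfr", "normal"),
    "uacr": ("labs", "uacr", "skewed"),
    "haemoglobin": ("labs", "haemoglobin", "normal"),
    "total_cholesterol": ("labs", "total_cholesterol", "normal"),
    "hdl_c": ("labs", "hdl_c", "normal"),
    "ldl_c": ("labs", "ldl_c", "normal"),
    "triglycerides": ("labs", "triglycerides", "skewed"),
    "bmi": ("vitals", "bmi", "normal"),
    "sbp": ("vitals", "sbp", "normal"),
    "dbp": ("vitals", "dbp", "normal"),
}


def _most_recent_in_window(events: pd.DataFrame, kind_col: str, kind: str,
                           records: pd.DataFrame, lookback: int) -> pd.Series:
    """Most recent value of *kind* in [index - lookback, index) per patient."""
    sub = events[events[kind_col] == kind]
    if sub.empty:
        return pd.Series(dtype=float)
    merged = sub.merge(records[["patient_id", "index_date"]], on="patient_id")
    lo = merged["index_date"] - pd.Timedelta(days=lookback)
    in_win = (merged["date"] >= lo) & (merged["date"] < merged["index_date"])
    merged = merged[in_win].sort_values(["patient_id", "date"], kind="mergesort")
    last = merged.groupby("patient_id", sort=False).tail(1)
    return pd.Series(last["value"].to_numpy(), index=last["patient_id"])


def extract_baseline(records: pd.DataFrame, store, config: RunConfig | None = None,
                     ) -> pd.DataFrame:
    """Per-patient baseline values at index (wide, one row per patient).

    eGFR is derived from the most recent in-window creatinine via the 2021
    CKD-EPI equation; CRP at baseline is the grouped index value itself.
    Smoking status is the most recent observation on or before index.
    """
    cfg = config or RunConfig()
    lookback = cfg.windows.lab_lookback
    rec = records.reset_index(drop=True)
    out = rec[["patient_id", "si_at_index", "age_at_index", "sex",
               "low_ses"]].copy()
    out["crp"] = rec["index_crp"].to_numpy()

    for var, (table, key, _) in BASELINE_VARIABLES.items():
        if table == "labs":
            vals = _most_recent_in_window(store.labs, "analyte", key, rec, lookback)
            out[var] = out["patient_id"].map(vals)
        elif table == "vitals":
            vals = _most_recent_in_window(store.vitals, "kind", key, rec, lookback)
            out[var] = out["patient_id"].map(vals)

    creat = _most_recent_in_window(store.labs, "analyte", "serum_creatinine",
                                   rec, lookback)
    demo = store.patients.set_index("patient_id")
    egfr = pd.Series(np.nan, index=out.index)
    have = out["patient_id"].isin(creat.index)
    if have.any():
        pids = out.loc[have, "patient_id"]
        scr = pids.map(creat).to_numpy(dtype=float)
        sex = pids.map(demo["sex"]).to_numpy()
        age = out.loc[have, "age_at_index"].to_numpy(dtype=float)
        egfr[have.to_numpy()] = egfr_ckd_epi_2021(scr, age, sex)
    out["egfr"] = egfr

    smoke = demo[["smoking_status", "smoking_date"]]
    status = out["patient_id"].map(smoke["smoking_status"])
    when = out["patient_id"].map(smoke["smoking_date"])
    usable = when.notna() & (when <= rec["index_date"])
    out["smoking_status"] = status.where(usable)
    out["current_smoker"] = (out["smoking_status"] == "current")
    return out


def comorbidity_history(records: pd.DataFrame, diagnoses: pd.DataFrame,
                        code_lists: Mapping[str, CodeList],
                        config: RunConfig | None = None) -> pd.DataFrame:
    """Boolean comorbidity flags: any matching code strictly before index.

    The ``cancer`` flag requires a malignancy code (non-melanoma skin cancer
    excluded) more than ``windows.cancer_comorbidity`` days before index.
    """
    cfg = config or RunConfig()
    rec = records.reset_index(drop=True)
    out = rec[["patient_id"]].copy()
    merged = diagnoses.merge(rec[["patient_id", "index_date"]], on="patient_id")
    prior = merged[merged["date"] < merged["index_date"]]
    for concept in COMORBIDITY_CONCEPTS:
        mask = code_lists[concept].match_series(prior["icd9_code"])
        flagged = set(prior.loc[mask, "patient_id"])
        out[concept] = out["patient_id"].isin(flagged)
    # cancer: malignancy (excl. NMSC) coded > 3 years before index
    mal = code_lists["malignancy"].match_series(prior["icd9_code"])
    nmsc = code_lists["non_melanoma_skin_cancer"].match_series(prior["icd9_code"])
    old_enough = (prior["index_date"] - prior["date"]).dt.days > \
        cfg.windows.cancer_comorbidity
    flagged = set(prior.loc[mal & ~nmsc & old_enough, "patient_id"])
    out["cancer"] = out["patient_id"].isin(flagged)
    return out


def drug_utilization(records: pd.DataFrame, prescriptions: pd.DataFrame,
                     code_lists: Mapping[str, CodeList], window: str = "pre",
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Per-patient drug-class exposure flags for the pre- or post-index year."""
    if window not in ("pre", "post"):
        raise ValueError("window must be 'pre' or 'post'")
    cfg = config or RunConfig()
    days = cfg.windows.drug_window
    rec = records.reset_index(drop=True)
    out = rec[["patient_id"]].copy()
    merged = prescriptions.merge(rec[["patient_id", "index_date"]],
                                 on="patient_id")
    if window == "pre":
        in_win = (merged["date"] >= merged["index_date"] - pd.Timedelta(days=days)) \
            & (merged["date"] < merged["index_date"])
    else:
        in_win = (merged["date"] > merged["index_date"]) \
            & (merged["date"] <= merged["index_date"] + pd.Timedelta(days=days))
    windowed = merged[in_win]
    for concept in UTILIZATION_CLASSES:
        mask = code_lists[concept].match_series(windowed["atc_code"])
        flagged = set(windowed.loc[mask, "patient_id"])
        out[concept] = out["patient_id"].isin(flagged)
    return out


def compare_groups(group_a: pd.Series, group_b: pd.Series, kind: str) -> float:
    """Two-group p-value; NaN when the comparison is degenerate.

    kind: "categorical" (chi-squared on the 2xk contingency table),
    "normal" (Welch t-test), "skewed" (Wilcoxon rank-sum).
    """
    a = pd.Series(group_a).dropna()
    b = pd.Series(group_b).dropna()
    if a.empty or b.empty:
        return float("nan")
    if kind == "categorical":
        table = pd.crosstab(
            np.concatenate([np.zeros(len(a)), np.ones(len(b))]),
            pd.concat([a, b], ignore_index=True),
        )
        if table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
            return float("nan")
        return float(stats.chi2_contingency(table.to_numpy())[1])
    if a.nunique() <= 1 and b.nunique() <= 1:
        return float("nan")
    if kind == "normal":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if kind == "skewed":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown variable kind {kind!r}")


def _summary(values: pd.Series, kind: str) -> str:
    v = values.dropna()
    if v.empty:
        return "-"
    if kind == "normal":
        return f"{v.mean():.2f} ± {v.std():.2f}"
    q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
    return f"{med:.1f} [{q1:.1f}, {q3:.1f}]"


def baseline_table(baseline: pd.DataFrame, comorbidities: pd.DataFrame,
                   records: pd.DataFrame) -> pd.DataFrame:
    """Tidy Table-1-style rows: variable x (overall, SI, non-SI, p)."""
    rec = records.reset_index(drop=True)
    si = baseline["si_at_index"].astype(bool)
    rows = []

    def add(variable, overall, a, b, p, missing=0):
        rows.append({"variable": variable, "overall": overall,
                     "si": a, "non_si": b, "p_value": p,
                     "n_missing": int(missing)})

    add("n", str(len(baseline)), str(int(si.sum())), str(int((~si).sum())),
        float("nan"))
    age = baseline["age_at_index"]
    add("age_years", _summary(age, "normal"), _summary(age[si], "normal"),
        _summary(age[~si], "normal"),
        compare_groups(age[si], age[~si], "normal"))

    def pct(mask_series):
        m = mask_series.dropna().astype(bool)
        return f"{100 * m.mean():.1f}%" if len(m) else "-"

    for name, series, in (
        ("female_sex", baseline["sex"] == "female"),
        ("current_smoker", baseline["current_smoker"]),
        ("low_ses", baseline["low_ses"]),
    ):
        add(name, pct(series), pct(series[si]), pct(series[~si]),
            compare_groups(series[si], series[~si], "categorical"))

    for var, (_, _, kind) in BASELINE_VARIABLES.items():
        v = baseline[var]
        add(var, _summary(v, kind), _summary(v[si], kind),
            _summary(v[~si], kind), compare_groups(v[si], v[~si], kind),
            missing=v.isna().sum())

    for sub in ("coronary", "cerebrovascular", "pad", "other"):
        v = rec[sub]
        add(f"ascvd_{sub}", pct(v), pct(v[si]), pct(v[~si]),
            compare_groups(v[si], v[~si], "categorical"))

    ckd = rec["ckd_status"] == "CKD"
    add("ckd", pct(ckd), pct(ckd[si]), pct(ckd[~si]),
        compare_groups(ckd[si], ckd[~si], "categorical"))
    for concept in comorbidities.columns.drop("patient_id"):
        v = comorbidities[concept]
        add(concept, pct(v), pct(v[si]), pct(v[~si]),
            compare_groups(v[si], v[~si], "categorical"))
    return pd.DataFrame(rows)


def utilization_table(util: pd.DataFrame, records: pd.DataFrame,
                      window: str) -> pd.DataFrame:
    """Tidy drug-utilization rows: % exposed per class, by SI status."""
    si = records.reset_index(drop=True)["si_at_index"].astype(bool)
    rows = []
    for concept in UTILIZATION_CLASSES:
        v = util[concept].astype(bool)
        rows.append({
            "drug_class": concept,
            "window": window,
            "pct_overall": 100 * v.mean() if len(v) else float("nan"),
            "pct_si": 100 * v[si].mean() if si.any() else float("nan"),
            "pct_non_si": 100 * v[~si].mean() if (~si).any() else float("nan"),
            "p_value": compare_groups(v[si], v[~si], "categorical"),
        })
    return pd.DataFrame(rows)


def render_baseline_text(table: pd.DataFrame) -> str:
    """Plain-text Table-1 rendering with the no-correction footnote."""
    lines = [f"{'variable':<28}{'overall':>18}{'SI':>18}{'non-SI':>18}{'p':>10}"]
    for _, r in table.iterrows():
        p = "" if pd.isna(r["p_value"]) else f"{r['p_value']:.3g}"
        lines.append(f"{r['variable']:<28}{r['overall']:>18}{r['si']:>18}"
                     f"{r['non_si']:>18}{p:>10}")
    lines.append("")
    lines.append("p-values: chi-squared / Welch t / rank-sum as configured; "
                 "no multiple-testing correction applied.")
    return "\n".join(lines)
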