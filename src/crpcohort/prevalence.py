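"""The three systemic-inflammation prevalence estimands, stratified.

(i)   **at_first_crp** — patients whose first grouped eligible CRP is
      >= 2 mg/L, over all included patients;
(ii)  **point_at_cutoff** — among patients alive at the data cutoff with at
      least one grouped eligible CRP anchored in the prior 18 months
      (548 days), those whose most recent such CRP is >= 2 mg/L;
(iii) **period** — patients with any grouped eligible CRP >= 2 mg/L during
      the study, over all included patients.

Strata: overall, CKD status (CKD / no-CKD / unknown as a third stratum),
CKD stage, sex, and age band (<65, 65-74, >=75 at index).  Stratum
numerators and denominators always sum to the parent's.  Zero-denominator
strata are reported as undefined (omitted), never as zero.

Confidence intervals are Wilson score intervals: the source analysis prints
none, but downstream consumers of a reusable estimator should get one, and
Wilson behaves well near 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .config import RunConfig
from .model import CodeList

ESTIMANDS = ("at_first_crp", "point_at_cutoff", "period")
AGE_BANDS = ("<65", "65-74", ">=75")

STRATIFIERS = {
    "overall": None,
    "ckd_status": "ckd_status",
    "ckd_stage": "ckd_stage",
    "sex": "sex",
    "age_band": "age_band",
}


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A numerator/denominator proportion with its Wilson 95% CI."""

    estimand: str
    stratifier: str
    stratum: str
    numerator: int
    denominator: int
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError(
                f"invalid counts {self.numerator}/{self.denominator}")
        if self.denominator == 0:
            raise ValueError("undefined estimate: zero denominator")
        lo, hi = proportion_confint(self.numerator, self.denominator,
                                    alpha=0.05, method="wilson")
        object.__setattr__(self, "ci_low", float(lo))
        object.__setattr__(self, "ci_high", float(hi))

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


def age_band(ages: pd.Series) -> pd.Series:
    return pd.cut(ages, bins=[-np.inf, 64, 74, np.inf],
                  labels=list(AGE_BANDS)).astype(str)


def _with_age_band(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["age_band"] = age_band(out["age_at_index"])
    out["ckd_status"] = out["ckd_status"].fillna("unknown")
    return out


def _stratified(records: pd.DataFrame, flags: pd.Series, estimand: str,
                ) -> list[PrevalenceEstimate]:
    """Overall + per-stratifier estimates from per-patient boolean flags."""
    records = _with_age_band(records)
    flags = flags.astype(bool)
    out: list[PrevalenceEstimate] = []
    if len(records) == 0:
        return out  # undefined, not zero
    out.append(PrevalenceEstimate(estimand, "overall", "overall",
                                  int(flags.sum()), len(records)))
    for name, col in STRATIFIERS.items():
        if col is None:
            continue
        series = records[col]
        if col == "ckd_stage":
            series = series.where(records["ckd_status"] == "CKD")
        for stratum, idx in records.groupby(series, dropna=True).groups.items():
            mask = records.index.isin(idx)
            denom = int(mask.sum())
            if denom == 0:
                continue  # undefined stratum: omitted, never reported as 0
            out.append(PrevalenceEstimate(
                estimand, name, str(stratum),
                int(flags[mask].sum()), denom,
            ))
    return out


def prevalence_at_first_crp(records: pd.DataFrame) -> list[PrevalenceEstimate]:
    """Estimand (i): SI at the first grouped eligible CRP measurement."""
    return _stratified(records.reset_index(drop=True),
                       records["si_at_index"].reset_index(drop=True),
                       "at_first_crp")


def point_prevalence_at_cutoff(
    records: pd.DataFrame,
    grouped: pd.DataFrame,
    patients: pd.DataFrame,
    config: RunConfig | None = None,
) -> list[PrevalenceEstimate]:
    """Estimand (ii): SI among patients alive at the cutoff with a recent
    eligible CRP.

    The denominator keeps patients with no death date or one after the
    cutoff, and at least one grouped eligible CRP anchored within the
    18-month lookback ending at the cutoff.  SI is judged on the most recent
    such grouped CRP (or, with the ``point_any_in_window`` switch, on any).
    """
    cfg = config or RunConfig()
    cutoff = pd.Timestamp(cfg.cutoff_date)
    if not (pd.Timestamp(cfg.study_start) <= cutoff <= pd.Timestamp(cfg.study_end)):
        raise ValueError("cutoff date outside the study window")
    lookback_start = cutoff - pd.Timedelta(days=cfg.windows.point_lookback)

    death = patients.set_index("patient_id")["death_date"]
    rec = records.reset_index(drop=True)
    dd = rec["patient_id"].map(death)
    alive = dd.isna() | (dd > cutoff)

    g = grouped[(grouped["anchor_date"] >= lookback_start)
                & (grouped["anchor_date"] <= cutoff)]
    g = g.sort_values(["patient_id", "anchor_date"], kind="mergesort")
    if cfg.switches.point_any_in_window:
        si_window = (g.assign(si=g["value"] >= cfg.thresholds.crp_si)
                     .groupby("patient_id")["si"].any())
    else:
        last = g.groupby("patient_id", sort=False).tail(1)
        si_window = pd.Series(
            (last["value"] >= cfg.thresholds.crp_si).to_numpy(),
            index=last["patient_id"],
        )
    in_denominator = alive & rec["patient_id"].isin(si_window.index)
    sub = rec[in_denominator].reset_index(drop=True)
    flags = sub["patient_id"].map(si_window)
    return _stratified(sub, flags, "point_at_cutoff")


def period_prevalence(records: pd.DataFrame, grouped: pd.DataFrame,
                      config: RunConfig | None = None,
                      ) -> list[PrevalenceEstimate]:
    """Estimand (iii): any grouped eligible CRP >= 2 mg/L during the study."""
    cfg = config or RunConfig()
    any_si = (grouped.assign(si=grouped["value"] >= cfg.thresholds.crp_si)
              .groupby("patient_id")["si"].any())
    rec = records.reset_index(drop=True)
    flags = rec["patient_id"].map(any_si).fillna(False)
    return _stratified(rec, flags, "period")


def sensitivity_exclude_inflammatory(
    records: pd.DataFrame,
    grouped: pd.DataFrame,
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    concept: CodeList,
    config: RunConfig | None = None,
) -> dict[str, list[PrevalenceEstimate]]:
    """All three estimands on the subcohort free of inflammatory/rheumatoid
    diagnoses before the index date."""
    cfg = config or RunConfig()
    matched = diagnoses[concept.match_series(diagnoses["icd9_code"])]
    merged = matched.merge(records[["patient_id", "index_date"]],
                           on="patient_id", how="inner")
    flagged = set(merged[merged["date"] < merged["index_date"]]["patient_id"])
    sub = records[~records["patient_id"].isin(flagged)].reset_index(drop=True)
    sub_grouped = grouped[grouped["patient_id"].isin(set(sub["patient_id"]))]
    return {
        "at_first_crp": prevalence_at_first_crp(sub),
        "point_at_cutoff": point_prevalence_at_cutoff(sub, sub_grouped,
                                                      patients, cfg),
        "period": period_prevalence(sub, sub_grouped, cfg),
    }


def estimates_table(estimates: list[PrevalenceEstimate]) -> pd.DataFrame:
    """Tidy long-format table: estimand x stratifier x stratum."""
    return pd.DataFrame([{
        "estimand": e.estimand,
        "stratifier": e.stratifier,
        "stratum": e.stratum,
        "numerator": e.numerator,
        "denominator": e.denominator,
        "proportion": e.proportion,
        "percent": e.percent,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
    } for e in estimates])
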