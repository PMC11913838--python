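"""CRP eligibility rules, geometric-mean grouping, and index assignment.

A raw C-reactive protein measurement taken at time *t* is ineligible for the
systemic-inflammation phenotype if any of four rules fires:

(i)   **pre-ASCVD** — *t* precedes the patient's first ASCVD diagnosis
      (strictly; a CRP on the diagnosis day is retained);
(ii)  **active infection** — the value exceeds 20 mg/L, or an
      antibiotic/antiviral prescription at *p* satisfies
      ``t - 60 <= p <= t + 7`` (the CRP falls within two months after, or
      seven days before, the prescription);
(iii) **immunosuppressant** — an immunosuppressant prescription at *p*
      satisfies ``0 <= t - p < 90`` (less than three months after);
(iv)  **active cancer** — a malignancy diagnosis (non-melanoma skin cancer
      excepted) at *d* satisfies ``0 <= t - d < 1095`` (less than three
      years after).

Rules are evaluated in this order for labelling; retention is their
conjunction, so the order cannot change the retained set.  Surviving
measurements within 90 days of each other are grouped greedily from the
earliest (the anchor) and averaged with a geometric mean; the anchor date is
carried as the grouped record's date.  A patient's index date is the anchor
of their first grouped record, and systemic inflammation at index means that
record's value is >= 2 mg/L.

All date arithmetic is in whole days (epoch day numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .model import day_number

#: Exclusion labels, in rule order; each raw CRP gets exactly one.
RULE_LABELS = (
    "pre-ascvd",
    "value>20",
    "infection-window",
    "immunosuppressant-window",
    "cancer-window",
    "none",
)


def _event_days_by_patient(events: pd.DataFrame) -> dict[str, np.ndarray]:
    """patient_id -> sorted array of event day numbers."""
    if events.empty:
        return {}
    df = pd.DataFrame({
        "patient_id": events["patient_id"].to_numpy(),
        "day": day_number(events["date"]).to_numpy(),
    }).sort_values(["patient_id", "day"])
    return {pid: g["day"].to_numpy() for pid, g in df.groupby("patient_id", sort=False)}


def _in_window(days: np.ndarray, events: np.ndarray,
               lo_off: int, hi_off: int) -> np.ndarray:
    """For each day t, does any event fall in [t + lo_off, t + hi_off]?"""
    lo = np.searchsorted(events, days + lo_off, side="left")
    hi = np.searchsorted(events, days + hi_off, side="right")
    return hi > lo


def label_exclusions(
    crps: pd.DataFrame,
    first_ascvd: pd.Series,
    infection_rx: pd.DataFrame,
    immunosuppressant_rx: pd.DataFrame,
    malignancy_dx: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Label every raw CRP with the first eligibility rule it violates.

    Parameters
    ----------
    crps
        raw CRP measurements (``patient_id``, ``date``, ``value`` in mg/L).
    first_ascvd
        per-patient first ASCVD diagnosis date, indexed by patient_id.
        Patients absent from the index have no ASCVD record: every one of
        their CRPs is labelled ``pre-ascvd``.
    infection_rx / immunosuppressant_rx / malignancy_dx
        dated trigger events, already restricted to the relevant concepts
        (malignancy with non-melanoma skin cancer removed by the caller).

    Returns a copy of *crps* with a ``rule`` column drawn from
    :data:`RULE_LABELS`; ``none`` marks an eligible measurement.
    """
    cfg = config or RunConfig()
    w = cfg.windows
    out = crps.copy().reset_index(drop=True)
    n = len(out)
    if n == 0:
        out["rule"] = pd.Series([], dtype=str)
        return out

    days = day_number(out["date"]).to_numpy()
    values = out["value"].to_numpy(dtype=float)
    pids = out["patient_id"].to_numpy()

    ascvd_days = day_number(
        pd.Series(pd.to_datetime(first_ascvd.values), index=first_ascvd.index)
    )
    mapped = pd.Series(pids).map(ascvd_days)
    pre_ascvd = mapped.isna().to_numpy() | (days < mapped.to_numpy(dtype=float))

    over_cap = values > cfg.thresholds.crp_infection_max

    inf_by_pid = _event_days_by_patient(infection_rx)
    imm_by_pid = _event_days_by_patient(immunosuppressant_rx)
    can_by_pid = _event_days_by_patient(malignancy_dx)

    infection_win = np.zeros(n, dtype=bool)
    immuno_win = np.zeros(n, dtype=bool)
    cancer_win = np.zeros(n, dtype=bool)
    order = pd.Series(range(n)).groupby(pids, sort=False)
    for pid, idx in order.groups.items():
        ix = np.asarray(idx)
        d = days[ix]
        ev = inf_by_pid.get(pid)
        if ev is not None:
            # prescription p in [t - after, t + before]
            infection_win[ix] = _in_window(
                d, ev, -w.infection_after_rx, w.infection_before_rx
            )
        ev = imm_by_pid.get(pid)
        if ev is not None:
            # 0 <= t - p < 90  <=>  p in [t - 89, t]
            immuno_win[ix] = _in_window(d, ev, -(w.immunosuppressant - 1), 0)
        ev = can_by_pid.get(pid)
        if ev is not None:
            cancer_win[ix] = _in_window(d, ev, -(w.cancer - 1), 0)

    rule = np.full(n, "none", dtype=object)
    rule[cancer_win] = "cancer-window"
    rule[immuno_win] = "immunosuppressant-window"
    rule[infection_win] = "infection-window"
    rule[over_cap] = "value>20"
    rule[pre_ascvd] = "pre-ascvd"
    out["rule"] = rule
    return out


def filter_pre_ascvd(crps: pd.DataFrame, first_ascvd_date) -> pd.DataFrame:
    """Retain CRPs on/after the first ASCVD diagnosis date (rule i)."""
    if crps.empty:
        return crps.copy()
    return crps[crps["date"] >= pd.Timestamp(first_ascvd_date)].copy()


def filter_infection(crps: pd.DataFrame, rx_dates: pd.Series,
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Drop CRPs >20 mg/L or within the antibiotic/antiviral window (rule ii)."""
    cfg = config or RunConfig()
    if crps.empty:
        return crps.copy()
    days = day_number(crps["date"]).to_numpy()
    ev = np.sort(day_number(pd.Series(pd.to_datetime(rx_dates))).to_numpy()) \
        if len(rx_dates) else np.array([], dtype=int)
    hit = crps["value"].to_numpy(dtype=float) > cfg.thresholds.crp_infection_max
    if ev.size:
        hit |= _in_window(days, ev, -cfg.windows.infection_after_rx,
                          cfg.windows.infection_before_rx)
    return crps[~hit].copy()


def filter_immunosuppressant(crps: pd.DataFrame, rx_dates: pd.Series,
                             config: RunConfig | None = None) -> pd.DataFrame:
    """Drop CRPs less than 3 months after an immunosuppressant rx (rule iii)."""
    cfg = config or RunConfig()
    if crps.empty or not len(rx_dates):
        return crps.copy()
    days = day_number(crps["date"]).to_numpy()
    ev = np.sort(day_number(pd.Series(pd.to_datetime(rx_dates))).to_numpy())
    hit = _in_window(days, ev, -(cfg.windows.immunosuppressant - 1), 0)
    return crps[~hit].copy()


def filter_cancer(crps: pd.DataFrame, dx_dates: pd.Series,
                  config: RunConfig | None = None) -> pd.DataFrame:
    """Drop CRPs less than 3 years after a malignancy diagnosis (rule iv).

    *dx_dates* must already exclude non-melanoma skin cancer codes.
    """
    cfg = config or RunConfig()
    if crps.empty or not len(dx_dates):
        return crps.copy()
    days = day_number(crps["date"]).to_numpy()
    ev = np.sort(day_number(pd.Series(pd.to_datetime(dx_dates))).to_numpy())
    hit = _in_window(days, ev, -(cfg.windows.cancer - 1), 0)
    return crps[~hit].copy()


@dataclass(frozen=True)
class EligibleCrpRecord:
    """A grouped eligible CRP observation: the unit of SI classification."""

    patient_id: str
    anchor_date: pd.Timestamp
    value: float  # geometric mean of members, mg/L
    member_dates: tuple
    member_values: tuple


def group_geometric(eligible: pd.DataFrame, window_days: int = 90) -> pd.DataFrame:
    """Group eligible CRPs within *window_days* of a greedy anchor.

    Measurements are sorted per patient; the earliest ungrouped measurement
    anchors a group absorbing every measurement dated within
    ``[anchor, anchor + window_days]``.  The grouped value is the geometric
    mean of the members and the record is dated at the anchor, so the output
    is invariant to input order and consecutive anchors are more than
    *window_days* apart.

    Returns columns ``patient_id, anchor_date, value, n_members,
    member_dates, member_values`` (the last two hold tuples).
    """
    cols = ["patient_id", "anchor_date", "value", "n_members",
            "member_dates", "member_values"]
    if eligible.empty:
        return pd.DataFrame(columns=cols)
    if (eligible["value"] <= 0).any():
        raise ValueError("geometric mean undefined for non-positive CRP values")
    df = eligible.sort_values(["patient_id", "date"], kind="mergesort")
    rows = []
    for pid, g in df.groupby("patient_id", sort=False):
        days = day_number(g["date"]).to_numpy()
        dates = g["date"].to_numpy()
        vals = g["value"].to_numpy(dtype=float)
        i, m = 0, len(g)
        while i < m:
            j = int(np.searchsorted(days, days[i] + window_days, side="right"))
            member_vals = vals[i:j]
            rows.append((
                pid,
                pd.Timestamp(dates[i]),
                float(np.exp(np.mean(np.log(member_vals)))),
                j - i,
                tuple(pd.Timestamp(d) for d in dates[i:j]),
                tuple(float(v) for v in member_vals),
            ))
            i = j
    return pd.DataFrame(rows, columns=cols)


def assign_index(grouped: pd.DataFrame, si_threshold: float = 2.0) -> pd.DataFrame:
    """Per-patient index record seed from the first grouped eligible CRP.

    The index date is the anchor of the patient's earliest grouped record and
    systemic inflammation at index is ``value >= si_threshold``.  Patients
    with no grouped record simply do not appear (they are excluded from the
    cohort, not an error).
    """
    if grouped.empty:
        return pd.DataFrame(columns=["patient_id", "index_date", "index_crp",
                                     "si_at_index"])
    first = (grouped.sort_values(["patient_id", "anchor_date"], kind="mergesort")
             .groupby("patient_id", sort=False).head(1))
    return pd.DataFrame({
        "patient_id": first["patient_id"].to_numpy(),
        "index_date": first["anchor_date"].to_numpy(),
        "index_crp": first["value"].to_numpy(),
        "si_at_index": (first["value"] >= si_threshold).to_numpy(),
    })


def run_eligibility(
    crps: pd.DataFrame,
    first_ascvd: pd.Series,
    infection_rx: pd.DataFrame,
    immunosuppressant_rx: pd.DataFrame,
    malignancy_dx: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full engine: label raw CRPs, group survivors, return (grouped, log)."""
    cfg = config or RunConfig()
    labelled = label_exclusions(crps, first_ascvd, infection_rx,
                                immunosuppressant_rx, malignancy_dx, cfg)
    retained = labelled[labelled["rule"] == "none"][["patient_id", "date", "value"]]
    grouped = group_geometric(retained, cfg.windows.crp_grouping)
    return grouped, labelled
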