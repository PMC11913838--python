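"""Independent brute-force oracles used only by the tests.

Everything here is written against the rules directly — plain Python loops
over all (measurement, event) pairs and a scalar transcription of the 2021
CKD-EPI constants — with no imports from the package's implementation
modules, so a defect in the vectorised engine cannot hide in its oracle.
"""

from __future__ import annotations

import pandas as pd


def brute_force_rule(t: pd.Timestamp, value: float, first_ascvd,
                     infection_rx_dates, immuno_rx_dates,
                     cancer_dx_dates) -> str:
    """First-firing eligibility rule for one raw CRP, by exhaustive check."""
    if first_ascvd is None or t < first_ascvd:
        return "pre-ascvd"
    if value > 20.0:
        return "value>20"
    for p in infection_rx_dates:
        # prescription within 2 months before or 7 days after the test
        if t - pd.Timedelta(days=60) <= p <= t + pd.Timedelta(days=7):
            return "infection-window"
    for p in immuno_rx_dates:
        delta = (t - p).days
        if 0 <= delta < 90:
            return "immunosuppressant-window"
    for d in cancer_dx_dates:
        delta = (t - d).days
        if 0 <= delta < 1095:
            return "cancer-window"
    return "none"


def brute_force_labels(crps: pd.DataFrame, first_ascvd: pd.Series,
                       infection_rx: pd.DataFrame,
                       immuno_rx: pd.DataFrame,
                       cancer_dx: pd.DataFrame) -> list[str]:
    """Per-row rule labels via the O(n*m) pairwise scan."""
    by_pid = {
        "inf": {p: list(g["date"]) for p, g in infection_rx.groupby("patient_id")},
        "imm": {p: list(g["date"]) for p, g in immuno_rx.groupby("patient_id")},
        "can": {p: list(g["date"]) for p, g in cancer_dx.groupby("patient_id")},
    }
    labels = []
    for _, row in crps.iterrows():
        pid = row["patient_id"]
        labels.append(brute_force_rule(
            row["date"], row["value"],
            first_ascvd.get(pid),
            by_pid["inf"].get(pid, ()),
            by_pid["imm"].get(pid, ()),
            by_pid["can"].get(pid, ()),
        ))
    return labels


def egfr_oracle(scr: float, age: float, sex: str) -> float:
    """Scalar 2021 CKD-EPI creatinine equation, coded independently."""
    if sex == "female":
        kappa, alpha, mult = 0.7, -0.241, 1.012
    else:
        kappa, alpha, mult = 0.9, -0.302, 1.0
    r = scr / kappa
    value = 142.0
    value *= min(r, 1.0) ** alpha
    value *= max(r, 1.0) ** (-1.200)
    value *= 0.9938 ** age
    value *= mult
    return value
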