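"""Prevalence estimands, stratification conservation, sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from conftest import d, event_df

from crpcohort.codes import DEFAULT_CODE_LISTS
from crpcohort.config import RunConfig
from crpcohort.prevalence import (PrevalenceEstimate, estimates_table,
                                  period_prevalence,
                                  point_prevalence_at_cutoff,
                                  prevalence_at_first_crp,
                                  sensitivity_exclude_inflammatory)


def _records(rows):
    """rows: (pid, index_day, index_crp, si, ckd_status, stage, sex, age)."""
    return pd.DataFrame({
        "patient_id": [r[0] for r in rows],
        "index_date": [d(r[1]) for r in rows],
        "index_crp": [r[2] for r in rows],
        "si_at_index": [r[3] for r in rows],
        "ckd_status": [r[4] for r in rows],
        "ckd_stage": [r[5] for r in rows],
        "sex": [r[6] for r in rows],
        "age_at_index": [r[7] for r in rows],
    })


def _grouped(rows):
    """rows: (pid, anchor_day, value)."""
    return pd.DataFrame({
        "patient_id": [r[0] for r in rows],
        "anchor_date": [d(r[1]) for r in rows],
        "value": [r[2] for r in rows],
    })


TOY = _records([
    ("P1", 0, 1.0, False, "no-CKD", None, "male", 60),
    ("P2", 0, 2.0, True, "CKD", "stage3", "female", 70),
    ("P3", 0, 3.5, True, "CKD", "stage4", "male", 80),
    ("P4", 0, 19.0, True, "unknown", None, "female", 66),
])


class TestEstimateType:
    def test_proportion_and_ci_bounds(self):
        e = PrevalenceEstimate("at_first_crp", "overall", "overall", 3, 4)
        assert e.proportion == 0.75
        assert 0 <= e.ci_low < e.proportion < e.ci_high <= 1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            PrevalenceEstimate("at_first_crp", "overall", "overall", 5, 4)

    def test_zero_denominator_is_undefined_not_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            PrevalenceEstimate("at_first_crp", "overall", "overall", 0, 0)


class TestAtFirstCrp:
    def test_toy_cohort_three_of_four(self):
        overall = [e for e in prevalence_at_first_crp(TOY)
                   if e.stratum == "overall"][0]
        assert (overall.numerator, overall.denominator) == (3, 4)
        assert overall.percent == pytest.approx(75.0)

    def test_stratum_counts_sum_to_parent(self):
        ests = prevalence_at_first_crp(TOY)
        overall = [e for e in ests if e.stratum == "overall"][0]
        for strat in ("ckd_status", "sex", "age_band"):
            nums = sum(e.numerator for e in ests if e.stratifier == strat)
            dens = sum(e.denominator for e in ests if e.stratifier == strat)
            assert (nums, dens) == (overall.numerator, overall.denominator)

    def test_ckd_stage_strata_sum_to_ckd_stratum(self):
        ests = prevalence_at_first_crp(TOY)
        ckd = [e for e in ests if e.stratifier == "ckd_status"
               and e.stratum == "CKD"][0]
        stage_dens = sum(e.denominator for e in ests
                         if e.stratifier == "ckd_stage")
        assert stage_dens == ckd.denominator


class TestPointPrevalence:
    CFG = RunConfig()
    CUTOFF_DAY = (pd.Timestamp(CFG.cutoff_date) - d(0)).days

    def _patients(self, death_days):
        return pd.DataFrame({
            "patient_id": list(death_days),
            "death_date": [pd.NaT if v is None else d(v)
                           for v in death_days.values()],
        })

    def test_dead_before_cutoff_excluded_from_denominator(self):
        rec = TOY.head(2)
        grouped = _grouped([("P1", self.CUTOFF_DAY - 10, 3.0),
                            ("P2", self.CUTOFF_DAY - 10, 3.0)])
        patients = self._patients({"P1": self.CUTOFF_DAY - 5, "P2": None,
                                   "P3": None, "P4": None})
        overall = [e for e in point_prevalence_at_cutoff(
            rec, grouped, patients, self.CFG) if e.stratum == "overall"][0]
        assert overall.denominator == 1

    def test_crp_older_than_lookback_excluded(self):
        rec = TOY.head(2)
        grouped = _grouped([("P1", self.CUTOFF_DAY - 549, 3.0),
                            ("P2", self.CUTOFF_DAY - 548, 3.0)])
        patients = self._patients({"P1": None, "P2": None})
        overall = [e for e in point_prevalence_at_cutoff(
            rec, grouped, patients, self.CFG) if e.stratum == "overall"][0]
        assert overall.denominator == 1  # only P2's CRP is recent enough

    def test_most_recent_in_window_decides_si(self):
        rec = TOY.head(1)
        grouped = _grouped([("P1", self.CUTOFF_DAY - 300, 1.5),
                            ("P1", self.CUTOFF_DAY - 100, 3.0)])
        patients = self._patients({"P1": None})
        overall = [e for e in point_prevalence_at_cutoff(
            rec, grouped, patients, self.CFG) if e.stratum == "overall"][0]
        assert (overall.numerator, overall.denominator) == (1, 1)

    def test_cutoff_outside_study_window_errors(self):
        cfg = RunConfig()
        cfg = cfg.model_copy(update={"cutoff_date": cfg.study_end.replace(
            year=cfg.study_end.year + 1)})
        with pytest.raises(ValueError, match="cutoff"):
            point_prevalence_at_cutoff(TOY, _grouped([]),
                                       self._patients({}), cfg)


class TestPeriodPrevalence:
    def test_later_si_counts_even_if_non_si_at_index(self):
        rec = TOY.head(1)  # P1 non-SI at index
        grouped = _grouped([("P1", 0, 1.0), ("P1", 200, 4.1)])
        overall = [e for e in period_prevalence(rec, grouped)
                   if e.stratum == "overall"][0]
        assert (overall.numerator, overall.denominator) == (1, 1)

    def test_period_dominates_index_prevalence_on_random_cohorts(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            rows, grows = [], []
            for i in range(n):
                pid = f"P{i}"
                k = int(rng.integers(1, 4))
                days = np.sort(rng.integers(0, 2000, k))
                vals = rng.uniform(0.3, 19.0, k)
                rows.append((pid, int(days[0]), float(vals[0]),
                             vals[0] >= 2.0, "no-CKD", None, "male", 70))
                grows += [(pid, int(dd), float(vv))
                          for dd, vv in zip(days, vals)]
            rec, grouped = _records(rows), _grouped(grows)
            first = [e for e in prevalence_at_first_crp(rec)
                     if e.stratum == "overall"][0]
            period = [e for e in period_prevalence(rec, grouped)
                      if e.stratum == "overall"][0]
            assert period.numerator >= first.numerator
            assert period.denominator == first.denominator


class TestSensitivity:
    PATIENTS = pd.DataFrame({"patient_id": [r for r in TOY["patient_id"]],
                             "death_date": [pd.NaT] * 4})

    def _grouped_all(self):
        return _grouped([(pid, 0, crp) for pid, crp in
                         zip(TOY["patient_id"], TOY["index_crp"])])

    def test_no_inflammatory_codes_is_a_noop(self):
        dx = event_df([("P1", -10, "250.00")], "icd9_code")
        sens = sensitivity_exclude_inflammatory(
            TOY, self._grouped_all(), self.PATIENTS, dx,
            DEFAULT_CODE_LISTS["inflammatory_rheumatoid"])
        main = prevalence_at_first_crp(TOY)
        assert estimates_table(sens["at_first_crp"]).equals(
            estimates_table(main))

    def test_all_si_patients_rheumatoid_gives_zero_prevalence(self):
        dx = event_df([(pid, -10, "714.0") for pid in ("P2", "P3", "P4")],
                      "icd9_code")
        sens = sensitivity_exclude_inflammatory(
            TOY, self._grouped_all(), self.PATIENTS, dx,
            DEFAULT_CODE_LISTS["inflammatory_rheumatoid"])
        overall = [e for e in sens["at_first_crp"]
                   if e.stratum == "overall"][0]
        assert (overall.numerator, overall.denominator) == (0, 1)

    def test_matches_brute_force_recount_on_random_cohort(self, small_run):
        cfg, store, _ = small_run
        from crpcohort.cohort import build_cohort
        records, grouped, _, _ = build_cohort(store, cfg)
        concept = DEFAULT_CODE_LISTS["inflammatory_rheumatoid"]
        sens = sensitivity_exclude_inflammatory(
            records, grouped, store.patients, store.diagnoses, concept, cfg)
        # brute-force: which patients carry a matching code before index?
        keep = []
        idx_dates = records.set_index("patient_id")["index_date"]
        dx_by_pid = dict(list(store.diagnoses.groupby("patient_id")))
        for pid in records["patient_id"]:
            g = dx_by_pid.get(pid)
            flagged = False
            if g is not None:
                for _, row in g.iterrows():
                    if row["date"] < idx_dates[pid] and \
                            concept.match(row["icd9_code"]):
                        flagged = True
                        break
            if not flagged:
                keep.append(pid)
        overall = [e for e in sens["at_first_crp"]
                   if e.stratum == "overall"][0]
        expected_num = int(records.set_index("patient_id").loc[
            keep, "si_at_index"].sum())
        assert overall.denominator == len(keep)
        assert overall.numerator == expected_num
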