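"""CRP eligibility rules, geometric-mean grouping, and index assignment."""

import numpy as np
import pandas as pd
import pytest

from conftest import crp_df, d, empty_events, event_df
from oracles import brute_force_labels

from crpcohort.eligibility import (assign_index, filter_cancer,
                                   filter_immunosuppressant,
                                   filter_infection, filter_pre_ascvd,
                                   group_geometric, label_exclusions,
                                   run_eligibility)

E_RX = empty_events("atc_code")
E_DX = empty_events("icd9_code")


class TestRuleBoundaries:
    def test_crp_day_before_first_ascvd_excluded(self):
        crps = crp_df([("P1", 99, 3.0)])
        assert len(filter_pre_ascvd(crps, d(100))) == 0

    def test_crp_on_first_ascvd_day_retained(self):
        crps = crp_df([("P1", 100, 3.0)])
        assert len(filter_pre_ascvd(crps, d(100))) == 1

    def test_empty_crp_list_passes_through(self):
        assert len(filter_pre_ascvd(crp_df([]), d(0))) == 0

    def test_crp_above_20_excluded_without_any_prescription(self):
        assert len(filter_infection(crp_df([("P1", 0, 25.0)]),
                                    pd.Series([], dtype="datetime64[ns]"))) == 0

    def test_crp_exactly_20_retained(self):
        assert len(filter_infection(crp_df([("P1", 0, 20.0)]),
                                    pd.Series([], dtype="datetime64[ns]"))) == 1

    @pytest.mark.parametrize("rx_offset, retained", [
        (-30, False),   # test 30 days after the prescription: within 2 months
        (-60, False),   # exactly 60 days after: still within
        (-61, True),    # 61 days after: outside
        (7, False),     # test 7 days before the prescription: within
        (8, True),      # 8 days before: outside
    ])
    def test_infection_window_boundaries(self, rx_offset, retained):
        crps = crp_df([("P1", 100, 5.0)])
        rx = pd.Series([d(100 + rx_offset)])
        assert (len(filter_infection(crps, rx)) == 1) is retained

    @pytest.mark.parametrize("crp_offset, retained", [
        (89, False),   # less than 3 months after the immunosuppressant
        (90, True),    # exactly 3 months: outside a strict "less than"
        (-10, True),   # before the prescription: one-sided rule
    ])
    def test_immunosuppressant_window_boundaries(self, crp_offset, retained):
        crps = crp_df([("P1", 100 + crp_offset, 5.0)])
        rx = pd.Series([d(100)])
        assert (len(filter_immunosuppressant(crps, rx)) == 1) is retained

    @pytest.mark.parametrize("crp_offset, retained", [
        (730, False),    # 2 years after a malignancy code
        (1094, False),
        (1095, True),    # exactly 3 years: outside
    ])
    def test_cancer_window_boundaries(self, crp_offset, retained):
        crps = crp_df([("P1", crp_offset, 5.0)])
        dx = pd.Series([d(0)])
        assert (len(filter_cancer(crps, dx)) == 1) is retained

    def test_nmsc_only_patient_not_excluded(self):
        # caller passes malignancy dates already excluding NMSC codes: an
        # NMSC-only patient contributes no dates, so nothing is excluded
        crps = crp_df([("P1", 730, 5.0)])
        assert len(filter_cancer(crps, pd.Series([], dtype="datetime64[ns]"))) == 1


class TestGrouping:
    def test_two_values_within_window_geometric_mean(self):
        g = group_geometric(crp_df([("P1", 0, 2.0), ("P1", 30, 8.0)]))
        assert len(g) == 1
        assert g["value"].iloc[0] == pytest.approx(4.0)
        assert g["anchor_date"].iloc[0] == d(0)
        assert g["n_members"].iloc[0] == 2

    def test_single_measurement_passes_through(self):
        g = group_geometric(crp_df([("P1", 5, 3.3)]))
        assert len(g) == 1
        assert g["value"].iloc[0] == pytest.approx(3.3)
        assert g["member_values"].iloc[0] == (3.3,)

    def test_greedy_windows_hand_enumeration(self):
        # days 0, 80, 100 -> groups {0, 80} and {100}
        g = group_geometric(crp_df([("P1", 0, 1.0), ("P1", 80, 4.0),
                                    ("P1", 100, 9.0)]))
        assert list(g["n_members"]) == [2, 1]
        assert list(g["anchor_date"]) == [d(0), d(100)]
        assert g["value"].iloc[0] == pytest.approx(2.0)

    def test_day_90_joins_day_91_starts_new_group(self):
        g = group_geometric(crp_df([("P1", 0, 1.0), ("P1", 90, 1.0),
                                    ("P2", 0, 1.0), ("P2", 91, 1.0)]))
        assert list(g.groupby("patient_id")["n_members"].apply(list)["P1"]) == [2]
        assert list(g.groupby("patient_id")["n_members"].apply(list)["P2"]) == [1, 1]

    def test_non_positive_value_raises(self):
        with pytest.raises(ValueError, match="geometric"):
            group_geometric(crp_df([("P1", 0, 0.0)]))

    def test_grouping_invariant_to_input_permutation(self):
        rng = np.random.default_rng(5)
        rows = [("P%d" % (i % 7), int(rng.integers(0, 1000)),
                 float(rng.uniform(0.5, 19))) for i in range(60)]
        base = group_geometric(crp_df(rows)).reset_index(drop=True)
        for seed in (1, 2):
            perm = list(np.random.default_rng(seed).permutation(len(rows)))
            shuffled = group_geometric(crp_df([rows[i] for i in perm]))
            pd.testing.assert_frame_equal(
                base, shuffled.reset_index(drop=True))


class TestIndexAssignment:
    @pytest.mark.parametrize("value, si", [(2.0, True), (1.99, False)])
    def test_si_threshold_is_inclusive(self, value, si):
        g = group_geometric(crp_df([("P1", 0, value)]))
        idx = assign_index(g)
        assert bool(idx["si_at_index"].iloc[0]) is si

    def test_geometric_mean_crossing_threshold(self):
        # sqrt(1.5 * 3.0) = 2.1213 >= 2 even though one member is below
        g = group_geometric(crp_df([("P1", 0, 1.5), ("P1", 10, 3.0)]))
        idx = assign_index(g)
        assert idx["index_crp"].iloc[0] == pytest.approx(np.sqrt(4.5))
        assert bool(idx["si_at_index"].iloc[0])

    def test_patient_without_eligible_records_simply_absent(self):
        idx = assign_index(group_geometric(crp_df([])))
        assert len(idx) == 0


class TestLabelling:
    def _label(self, crps, **kw):
        first = kw.get("first_ascvd", pd.Series({"P1": d(0)}))
        return label_exclusions(crps, first,
                                kw.get("infection_rx", E_RX),
                                kw.get("immuno_rx", E_RX),
                                kw.get("cancer_dx", E_DX))

    def test_each_crp_gets_exactly_one_label_and_counts_conserve(self):
        crps = crp_df([("P1", -5, 3.0), ("P1", 10, 25.0), ("P1", 50, 3.0),
                       ("P1", 200, 1.0)])
        rx = event_df([("P1", 45)], "atc_code")
        out = self._label(crps, infection_rx=rx)
        assert len(out) == len(crps)
        assert list(out["rule"]) == ["pre-ascvd", "value>20",
                                     "infection-window", "none"]

    def test_first_firing_rule_in_documented_order_wins(self):
        # a pre-ASCVD CRP that is also >20 and inside every window
        crps = crp_df([("P1", -5, 99.0)])
        rx = event_df([("P1", -6)], "atc_code")
        dx = event_df([("P1", -100)], "icd9_code")
        out = self._label(crps, infection_rx=rx, immuno_rx=rx, cancer_dx=dx)
        assert out["rule"].iloc[0] == "pre-ascvd"

    def test_patient_with_no_ascvd_record_labelled_pre_ascvd(self):
        out = label_exclusions(crp_df([("PX", 10, 3.0)]),
                               pd.Series(dtype="datetime64[ns]"),
                               E_RX, E_RX, E_DX)
        assert out["rule"].iloc[0] == "pre-ascvd"


def test_engine_matches_brute_force_oracle_on_random_cohort():
    """Vectorised windows vs the O(n*m) pairwise scan, record for record."""
    rng = np.random.default_rng(42)
    n_pat = 60
    pids = [f"P{i}" for i in range(n_pat)]
    first = pd.Series({p: d(int(rng.integers(0, 400))) for p in pids})
    crps = crp_df([(pids[int(rng.integers(0, n_pat))],
                    int(rng.integers(-200, 2000)),
                    float(rng.uniform(0.2, 40))) for _ in range(800)])
    inf_rx = event_df([(pids[int(rng.integers(0, n_pat))],
                        int(rng.integers(-200, 2000))) for _ in range(300)],
                      "atc_code")
    imm_rx = event_df([(pids[int(rng.integers(0, n_pat))],
                        int(rng.integers(-200, 2000))) for _ in range(150)],
                      "atc_code")
    can_dx = event_df([(pids[int(rng.integers(0, n_pat))],
                        int(rng.integers(-2000, 2000))) for _ in range(100)],
                      "icd9_code")
    out = label_exclusions(crps, first, inf_rx, imm_rx, can_dx)
    expected = brute_force_labels(crps, first, inf_rx, imm_rx, can_dx)
    assert list(out["rule"]) == expected


def test_run_eligibility_groups_only_retained_measurements():
    crps = crp_df([("P1", 10, 4.0), ("P1", 20, 25.0), ("P1", 40, 1.0)])
    grouped, log = run_eligibility(crps, pd.Series({"P1": d(0)}),
                                   E_RX, E_RX, E_DX)
    assert (log["rule"] == "none").sum() == 2
    assert len(grouped) == 1
    assert grouped["value"].iloc[0] == pytest.approx(2.0)  # sqrt(4*1)
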