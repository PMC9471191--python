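import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from adpatterns import reporting_stats as rs

from .oracles import exact_trend_tail


class TestCochranArmitage:
    def test_reconstructed_yearly_table(self):
        # (successes, totals) reconstructed from printed per-year counts and
        # proportions; totals were verified to sum to the cohort size.
        res = rs.cochran_armitage([4225, 5847, 7002], [5003, 6813, 8139])
        assert res.abs_Z == pytest.approx(2.372, abs=0.005)
        assert res.p == pytest.approx(0.018, abs=0.002)

    def test_equal_proportions_zero(self):
        res = rs.cochran_armitage([10, 20, 30], [100, 200, 300])
        assert res.Z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_all_success_undefined(self):
        with pytest.raises(ValueError):
            rs.cochran_armitage([10, 10], [10, 10])

    def test_count_bounds_checked(self):
        with pytest.raises(ValueError):
            rs.cochran_armitage([11, 5], [10, 10])

    def test_matches_exact_permutation_moments(self):
        counts, totals = (2, 3, 5), (10, 10, 10)
        mean, var, tail = exact_trend_tail(counts, totals)
        res = rs.cochran_armitage(counts, totals)
        N = sum(totals)
        # permutation distribution of T: mean 0, variance N/(N-1) x formula
        assert mean == pytest.approx(0.0, abs=1e-9)
        x = np.array(counts); n = np.array(totals); s = np.array([1.0, 2.0, 3.0])
        pbar = x.sum() / N
        var_formula = pbar * (1 - pbar) * ((n * s**2).sum() - (n * s).sum() ** 2 / N)
        assert var == pytest.approx(var_formula * N / (N - 1), rel=1e-9)
        # the normal p approximates the exact enumeration tail on this
        # small discrete table
        assert res.p == pytest.approx(tail, abs=0.1)

    @given(
        st.lists(st.tuples(st.integers(0, 30), st.integers(1, 30)), min_size=3, max_size=5),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    def test_score_affine_invariance(self, groups, a, b):
        counts = [min(c, t) for c, t in groups]
        totals = [t for _, t in groups]
        if sum(counts) in (0, sum(totals)):
            return
        k = len(counts)
        base = rs.cochran_armitage(counts, totals)
        scaled = rs.cochran_armitage(
            counts, totals, scores=[a * (i + 1) + b for i in range(k)]
        )
        assert abs(scaled.Z) == pytest.approx(abs(base.Z), rel=1e-9)


class TestProportionTable:
    def test_printed_pairs(self):
        table = rs.proportion_from_counts(
            {
                "overall": (17074, 19955),
                "first_line": (19240, 19955),
                "optimized": (811, 2977),
            }
        )
        got = dict(zip(table["family"], table["percent"]))
        assert got["overall"] == pytest.approx(85.56, abs=0.01)
        assert got["first_line"] == pytest.approx(96.42, abs=0.01)
        assert got["optimized"] == pytest.approx(27.24, abs=0.01)

    def test_zero_concordant(self):
        table = rs.proportion_from_counts({"overall": (0, 100)})
        assert table["percent"].iloc[0] == 0.0

    def test_pipeline_proportions(self, clean_pipeline):
        table = rs.proportion_table(
            clean_pipeline["concordance"], clean_pipeline["cohort"]
        )
        allrows = table[table["stratum"] == "all"].set_index("family")
        n_eligible = (clean_pipeline["cohort"]["exclusion_reason"] == "none").sum()
        assert allrows.loc["overall", "denominator"] == n_eligible
        assert allrows.loc["first_line", "denominator"] == n_eligible
        # optimized denominator: first-line initiators who moved beyond level 1
        conc = clean_pipeline["concordance"]
        expected = (
            (conc["level1_flag"] == "concordant") & (conc["optimized"] == 1)
        ).sum()
        assert allrows.loc["optimized", "denominator"] == expected

    def test_yearly_strata_partition(self, clean_pipeline):
        table = rs.proportion_table(
            clean_pipeline["concordance"], clean_pipeline["cohort"]
        )
        overall = table[table["family"] == "overall"]
        whole = overall[overall["stratum"] == "all"]["denominator"].iloc[0]
        years = overall[overall["stratum"] != "all"]["denominator"].sum()
        assert years == whole


class TestDurationTable:
    def test_uniform_durations(self):
        levels = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(10)],
                "level_index": [1] * 10,
                "duration_days": [28] * 10,
                "duration_bin": ["w4_6"] * 10,
            }
        )
        table = rs.duration_table(levels)
        total = table[(table["level"] == 1) & (table["subgroup"] == "total")].iloc[0]
        assert total["median"] == 28
        assert total["pct_w4_6"] == 100.0

    def test_subgroups_partition_total(self, clean_pipeline):
        table = rs.duration_table(clean_pipeline["levels"])
        for level in table["level"].unique():
            sub = table[table["level"] == level].set_index("subgroup")
            parts = sum(
                int(sub.loc[g, "n"]) for g in ("stopped_here", "changed_again")
                if g in sub.index
            )
            assert parts == int(sub.loc["total", "n"])

    def test_bin_percentages_sum_to_100(self, clean_pipeline):
        from adpatterns.pattern_engine import DURATION_BINS

        table = rs.duration_table(clean_pipeline["levels"])
        for _, row in table.iterrows():
            assert sum(row[f"pct_{b}"] for b in DURATION_BINS) == pytest.approx(100, abs=0.1)

    def test_level1_median_recovers_configured_model(self, clean_pipeline):
        config = clean_pipeline["config"]
        table = rs.duration_table(clean_pipeline["levels"])
        total = table[(table["level"] == 1) & (table["subgroup"] == "total")].iloc[0]
        median_cfg = config.level_duration_model[1][0]
        assert abs(total["median"] - median_cfg) <= 5


class TestPatternTable:
    def test_subsequent_patterns(self):
        rows = []
        # 3 switch-then-unchanged, 1 switch-then-switch
        for i in range(3):
            rows.append({"patient_id": f"s{i}", "event_index": 0, "kind": "switch",
                         "new_drugs": "venlafaxine", "multi_drug": 0})
        rows.append({"patient_id": "s3", "event_index": 0, "kind": "switch",
                     "new_drugs": "venlafaxine", "multi_drug": 0})
        rows.append({"patient_id": "s3", "event_index": 1, "kind": "switch",
                     "new_drugs": "sertraline", "multi_drug": 0})
        transitions = pd.DataFrame(rows)
        cohort = pd.DataFrame(
            {"patient_id": [f"s{i}" for i in range(4)], "exclusion_reason": ["none"] * 4}
        )
        table = rs.pattern_table(transitions, cohort).set_index("item")
        assert table.loc["pattern_1a_switch_unchanged", "n"] == 3
        assert table.loc["pattern_1b_switch_switch", "n"] == 1
        assert table.loc["pattern_1c_switch_addon", "n"] == 0

    def test_denominators(self, clean_pipeline):
        table = rs.pattern_table(
            clean_pipeline["transitions"], clean_pipeline["cohort"]
        ).set_index("item")
        n_cohort = table.loc["cohort", "n"]
        n_switch = table.loc["first_switch", "n"]
        n_addon = table.loc["first_add_on", "n"]
        assert table.loc["first_switch", "denominator"] == n_cohort
        # subsequent patterns partition the first-transition counts
        assert (
            table.loc["pattern_1a_switch_unchanged", "n"]
            + table.loc["pattern_1b_switch_switch", "n"]
            + table.loc["pattern_1c_switch_addon", "n"]
            == n_switch
        )
        assert (
            table.loc["pattern_2a_add_on_unchanged", "n"]
            + table.loc["pattern_2b_add_on_switch", "n"]
            + table.loc["pattern_2c_add_on_addon", "n"]
            == n_addon
        )

    def test_ground_truth_tabulation_matches(self, clean_pipeline):
        truths = clean_pipeline["truths"]
        table = rs.pattern_table(
            clean_pipeline["transitions"], clean_pipeline["cohort"]
        ).set_index("item")
        first_kinds = [
            t.intended_levels[1][1]
            for t in truths
            if t.eligible and len(t.intended_levels) >= 2
        ]
        assert table.loc["first_switch", "n"] == sum(k == "switch" for k in first_kinds)
        assert table.loc["first_add_on", "n"] == sum(k == "add_on" for k in first_kinds)


class TestDiscordanceFlow:
    def test_printed_pairs(self):
        table = rs.discordance_flow_from_counts(
            {"switch_discordant": (447, 1528), "add_on_discordant": (390, 1301)}
        ).set_index("item")
        assert table.loc["switch_discordant", "percent"] == pytest.approx(29.25, abs=0.01)
        assert table.loc["add_on_discordant", "percent"] == pytest.approx(29.98, abs=0.01)

    def test_zero_discordant(self, tiers):
        conc = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "level1_flag": ["concordant", "concordant"],
                "level2_flag": ["concordant", ""],
                "level3_flag": ["", ""],
                "overall": [1, 1],
                "optimized": [1, 0],
                "first_transition_kind": ["switch", ""],
                "first_transition_multi": [0, 0],
            }
        )
        table = rs.discordance_flow(conc).set_index("item")
        assert table.loc["switch_discordant", "n"] == 0
        assert table.loc["switch_discordant", "percent"] == 0.0

    def test_flow_sums(self, clean_pipeline):
        table = rs.discordance_flow(clean_pipeline["concordance"]).set_index("item")
        assert (
            table.loc["switch_strategy", "n"] + table.loc["add_on_strategy", "n"]
            == table.loc["optimized_after_first_line", "n"]
        )
        assert table.loc["switch_discordant", "n"] <= table.loc["switch_strategy", "n"]


class TestUtilization:
    def test_simple_rate(self):
        cohort = pd.DataFrame(
            {
                "patient_id": ["a", "b"],
                "exclusion_reason": ["none", "none"],
                "index_date": ["2016-01-01", "2016-01-01"],
                "follow_up_end": ["2016-06-30", "2016-06-30"],
            }
        )
        fu_days = (pd.Timestamp("2016-06-30") - pd.Timestamp("2016-01-01")).days + 1
        visits = pd.DataFrame(
            {
                "patient_id": ["a"] * 7 + ["b"] * 6,
                "date": [f"2016-0{m}-15" for m in range(1, 7)] + ["2016-01-20"]
                + [f"2016-0{m}-10" for m in range(1, 7)],
                "setting": ["outpatient"] * 13,
                "admission_date": [""] * 13,
                "discharge_date": [""] * 13,
            }
        )
        util = rs.utilization_summary(cohort, visits)
        person_years = 2 * fu_days / 365.25
        assert util.person_years == pytest.approx(person_years)
        assert util.visits_per_person_year == pytest.approx(13 / person_years)

    def test_visit_interval_recovery(self, clean_pipeline):
        config = clean_pipeline["config"]
        util = rs.utilization_summary(
            clean_pipeline["cohort"], clean_pipeline["tables"]["visits"]
        )
        shape, scale = config.visit_interval_model
        assert util.visit_interval_median_q1_q3 is not None
        median = util.visit_interval_median_q1_q3[0]
        # gamma(4, 7): median ~ 25.7 days; generated intervals are rounded
        assert 0.6 * shape * scale <= median <= 1.2 * shape * scale

    def test_stratified_rows(self, clean_pipeline):
        conc = clean_pipeline["concordance"]
        for flag in (0, 1):
            ids = conc.loc[conc["overall"] == flag, "patient_id"]
            util = rs.utilization_summary(
                clean_pipeline["cohort"], clean_pipeline["tables"]["visits"], ids
            )
            assert util.n_patients == len(ids)
            assert util.person_years > 0
            assert util.follow_up_median_q1_q3[0] > 0
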