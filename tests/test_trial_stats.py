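"""Category summaries, sequential two-way ANOVA, and Tukey HSD."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from roadvib.displacement import TrialResult
from roadvib.trial_stats import (
    category_summary,
    significance_stars,
    single_factor_view,
    study_report,
    tukey_hsd,
    two_way_anova,
)


def _trial(surface, speed, dbar, lo=None, hi=None):
    lo = dbar if lo is None else lo
    hi = dbar if hi is None else hi
    return TrialResult(surface, float(speed), float(dbar), min(lo, dbar), max(hi, dbar), 60.0)


class TestCategorySummary:
    def test_constant_category(self):
        trials = [_trial("A", 30, 1.0) for _ in range(3)]
        (summ,) = category_summary(trials)
        assert (summ.mean_dbar, summ.sd_dbar, summ.cv_pct) == (1.0, 0.0, 0.0)

    def test_two_trial_hand_computation(self):
        trials = [_trial("A", 30, 1.0), _trial("A", 30, 3.0)]
        (summ,) = category_summary(trials)
        assert summ.mean_dbar == pytest.approx(2.0)
        assert summ.sd_dbar == pytest.approx(math.sqrt(2))  # n-1 denominator
        assert summ.cv_pct == pytest.approx(70.7107, abs=1e-3)

    def test_pooled_extremes_and_single_trial_flag(self):
        trials = [_trial("B", 60, 0.8, lo=0.3, hi=2.0), _trial("B", 60, 0.9, lo=0.5, hi=3.36)]
        (summ,) = category_summary(trials)
        assert (summ.min_di, summ.max_di) == (0.3, 3.36)
        (single,) = category_summary([_trial("C", 30, 3.6)])
        assert single.single_trial and single.sd_dbar == 0.0

    def test_reference_design_flags_b30_as_highest_cv(self, reference_trials):
        summaries = category_summary(reference_trials)
        top = max(summaries, key=lambda s: s.cv_pct)
        assert (top.surface, top.speed) == ("B", 30.0)
        assert top.cv_pct == pytest.approx(26.8, abs=0.1)


class TestTwoWayAnova:
    def test_design_determined_degrees_of_freedom(self, reference_trials):
        table = two_way_anova(reference_trials)
        df = {r.term: r.df for r in table.rows}
        assert df == {"speed": 4, "road_surface": 3, "speed:road_surface": 4, "residual": 108}
        assert sum(df.values()) == len(reference_trials) - 1

    def test_sum_of_squares_conserved(self, reference_trials):
        table = two_way_anova(reference_trials)
        y = np.array([t.dbar for t in reference_trials])
        total = float(((y - y.mean()) ** 2).sum())
        assert sum(r.sum_sq for r in table.rows) == pytest.approx(total, rel=1e-9)
        assert all(r.sum_sq >= 0 for r in table.rows)

    def test_balanced_2x2_matches_closed_form(self):
        # textbook cell means: effects enter additively plus interaction
        data = {("A", 30): [1.0, 1.2], ("A", 60): [2.0, 2.2], ("B", 30): [1.6, 1.8], ("B", 60): [3.4, 3.6]}
        trials = [_trial(s, v, x) for (s, v), xs in data.items() for x in xs]
        table = two_way_anova(trials)
        y = np.array([t.dbar for t in trials])
        grand = y.mean()
        # closed-form balanced decomposition from marginal means
        m_speed = {v: np.mean([x for (s, vv), xs in data.items() if vv == v for x in xs]) for v in (30, 60)}
        m_surf = {s: np.mean([x for (ss, v), xs in data.items() if ss == s for x in xs]) for s in "AB"}
        ss_speed = 4 * sum((m - grand) ** 2 for m in m_speed.values())
        ss_surf = 4 * sum((m - grand) ** 2 for m in m_surf.values())
        cell_means = {k: np.mean(v) for k, v in data.items()}
        ss_inter = 2 * sum(
            (cell_means[(s, v)] - m_surf[s] - m_speed[v] + grand) ** 2
            for s in "AB"
            for v in (30, 60)
        )
        got = {r.term: r.sum_sq for r in table.rows}
        assert got["speed"] == pytest.approx(ss_speed, rel=1e-9)
        assert got["road_surface"] == pytest.approx(ss_surf, rel=1e-9)
        assert got["speed:road_surface"] == pytest.approx(ss_inter, rel=1e-9)

    def test_all_equal_observations_reported_not_applicable(self):
        trials = [_trial(s, v, 1.0) for s in "AB" for v in (30, 60) for _ in range(2)]
        table = two_way_anova(trials)
        assert table["speed"].sum_sq == pytest.approx(0.0)
        assert table["speed"].f_value is None and table["speed"].p_value is None

    def test_requires_replication(self):
        with pytest.raises(ValueError):
            two_way_anova([_trial("A", 30, 1.0), _trial("A", 60, 2.0)])


class TestTukey:
    def test_reference_mean_differences(self, reference_trials):
        comps = {(c.group_i, c.group_ii): c for c in tukey_hsd(reference_trials)}
        assert comps[("C-30", "C-60")].mean_diff == pytest.approx(-0.84, abs=1e-9)
        assert comps[("A-30", "C-30")].mean_diff == pytest.approx(-3.24, abs=1e-9)
        assert comps[("C-30", "D-30")].mean_diff == pytest.approx(1.46, abs=1e-9)
        assert comps[("B-60", "C-60")].mean_diff == pytest.approx(-3.64, abs=1e-9)
        for c in comps.values():
            assert c.ci_lower <= c.mean_diff <= c.ci_upper
            assert 0.0 <= c.p_adj <= 1.0

    def test_two_group_case_equals_pooled_t_test(self):
        a = [0.9, 1.1, 1.0, 1.2, 0.8]
        b = [1.5, 1.7, 1.6, 1.4, 1.8]
        trials = [_trial("A", 30, x) for x in a] + [_trial("A", 60, x) for x in b]
        (comp,) = tukey_hsd(trials)
        t, p = stats.ttest_ind(a, b)  # pooled-variance two-sample t
        assert comp.p_adj == pytest.approx(p, rel=1e-6)
        assert comp.mean_diff == pytest.approx(np.mean(a) - np.mean(b))

    def test_identical_groups_not_significant(self):
        trials = [_trial("A", 30, x) for x in (1.0, 1.1, 0.9)] + [
            _trial("A", 60, x) for x in (1.0, 1.1, 0.9)
        ]
        (comp,) = tukey_hsd(trials)
        assert comp.mean_diff == pytest.approx(0.0)
        assert comp.p_adj == pytest.approx(1.0, abs=1e-6)

    def test_zero_residual_variance_degenerate(self):
        trials = [_trial("A", 30, 1.0), _trial("A", 30, 1.0), _trial("A", 60, 2.0), _trial("A", 60, 2.0)]
        (comp,) = tukey_hsd(trials)
        assert comp.p_adj == 0.0 and comp.mean_diff == pytest.approx(-1.0)

    def test_independent_studentized_range_oracle(self, reference_trials):
        """Adjusted p-values match a direct studentized-range computation."""
        comps = tukey_hsd(reference_trials)
        y = np.array([t.dbar for t in reference_trials])
        labels = np.array([f"{t.surface}-{int(t.speed)}" for t in reference_trials])
        uniq = sorted(set(labels))
        k = len(uniq)
        means = {g: y[labels == g].mean() for g in uniq}
        sse = sum(((y[labels == g] - means[g]) ** 2).sum() for g in uniq)
        df = len(y) - k
        mse = sse / df
        for c in comps[:10]:
            n_i = (labels == c.group_i).sum()
            n_j = (labels == c.group_ii).sum()
            q = abs(means[c.group_i] - means[c.group_ii]) / math.sqrt(
                mse / 2 * (1 / n_i + 1 / n_j)
            )
            p = stats.studentized_range.sf(q, k, df)
            assert c.p_adj == pytest.approx(p, abs=1e-6)


class TestSingleFactorView:
    def test_counts_match_pair_enumeration(self, reference_trials):
        comps = tukey_hsd(reference_trials)
        assert len(comps) == 66  # all pairs of the 12 cells
        view = single_factor_view(comps)
        cells = sorted({(t.surface, int(t.speed)) for t in reference_trials})
        speed_pairs = sum(
            1 for a, b in itertools.combinations(cells, 2) if a[0] == b[0] and a[1] != b[1]
        )
        surface_pairs = sum(
            1 for a, b in itertools.combinations(cells, 2) if a[0] != b[0] and a[1] == b[1]
        )
        assert len(view["speed"]) == speed_pairs == 17
        assert len(view["road_surface"]) == surface_pairs == 11
        # both-factor-differing pairs are excluded
        shown = {(c.group_i, c.group_ii) for comps_ in view.values() for c in comps_}
        assert ("A-30", "B-60") not in shown and ("A-30", "A-60") in shown


def test_significance_stars():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.01) == "*"
    assert significance_stars(0.2) == ""
    with pytest.raises(ValueError):
        significance_stars(1.5)


def test_study_report_shape(reference_trials):
    report = study_report(reference_trials)
    assert report["n_trials"] == 120
    assert len(report["categories"]) == 12
    assert {r["source"] for r in report["anova"]} == {
        "speed",
        "road_surface",
        "speed:road_surface",
        "residual",
    }
    assert set(report["tukey"]) == {"speed", "road_surface"}
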