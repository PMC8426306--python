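"""Longitudinal statistics: progression scores, fold changes, group tests."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fibropet.stats import (AnimalTimeline, build_report, compare_groups,
                            delta_ct, group_fold_change, nominal_day,
                            predictive_correlation, significance_stars)


def exact_mannwhitney_p(a, b):
    """Independent oracle: two-sided exact p by enumerating all rank splits."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 if x > y else (0.5 if x == y else 0.0)
                   for x in group_a for y in group_b)

    observed = u_stat(a, b)
    mu = len(a) * len(b) / 2.0
    count = total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_stat(ga, gb) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


class TestDeltaCT:
    def test_signed_difference(self):
        tl = AnimalTimeline("m1", "BLM", [0, 9, 16, 23], [-600, -530, -470, -440])
        s = delta_ct(tl)
        assert s.delta_ct_hu == pytest.approx(90.0)   # -440 - (-530)

    def test_flat_timeline_is_zero(self):
        tl = AnimalTimeline("m2", "NaCl", [9, 23], [-600.0, -600.0])
        assert delta_ct(tl).delta_ct_hu == 0.0

    def test_nearest_day_within_one_accepted(self):
        # day-8 imaging stands in for the nominal day-9 session
        tl = AnimalTimeline("m3", "BLM", [8, 23], [-550.0, -450.0])
        assert delta_ct(tl, start_day=9).delta_ct_hu == pytest.approx(100.0)

    def test_missing_timepoint_names_animal(self):
        tl = AnimalTimeline("m4", "BLM", [0, 23], [-600.0, -450.0])
        with pytest.raises(KeyError, match="m4"):
            delta_ct(tl, start_day=9)

    @given(st.lists(st.floats(-800, 0), min_size=3, max_size=3))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_additivity(self, mlds):
        tl = AnimalTimeline("m", "BLM", [9, 16, 23], mlds)
        part = (delta_ct(tl, 9, 16).delta_ct_hu + delta_ct(tl, 16, 23).delta_ct_hu)
        whole = delta_ct(tl, 9, 23).delta_ct_hu
        assert part == pytest.approx(whole, abs=1e-9)


class TestFoldChange:
    def test_linear_ratio(self):
        assert group_fold_change([3.2, 3.2], [1.0, 1.0]) == pytest.approx(3.2)

    def test_hu_plus_1000_scale(self):
        # MLD -440 vs -600 -> 560/400 = 1.4 on the density-proxy scale
        assert group_fold_change([-440.0], [-600.0], scale="HU+1000") == pytest.approx(1.4)

    def test_identical_groups_unity(self, rng):
        v = rng.random(6).tolist()
        assert group_fold_change(v, v) == pytest.approx(1.0)

    @given(st.lists(st.floats(0.1, 50), min_size=2, max_size=8),
           st.lists(st.floats(0.1, 50), min_size=2, max_size=8))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_antisymmetry(self, a, b):
        fc = group_fold_change(a, b)
        assert fc * group_fold_change(b, a) == pytest.approx(1.0, rel=1e-9)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            group_fold_change([1.0], [0.0])
        with pytest.raises(ValueError):
            group_fold_change([], [1.0])


class TestPredictiveCorrelation:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        r, p, n = predictive_correlation(x, [2 * v for v in x])
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            predictive_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [2.0, 4.0, 6.0, 8.0]
        r, p, n = predictive_correlation(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            predictive_correlation([1.0, 2.0], [1.0, 2.0])


class TestCompareGroups:
    def test_textbook_separated_triples(self):
        p, stars = compare_groups([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert stars == ""

    def test_identical_samples_p_one(self):
        p, _ = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_three_identical_groups(self):
        p, _ = compare_groups([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [])

    def test_matches_exhaustive_enumeration(self, rng):
        # exact Mann-Whitney equals brute-force enumeration for n <= 5
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (5, 5), (3, 5)]:
            for _ in range(3):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2) + rng.normal()
                p, _ = compare_groups(a, b)
                assert p == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-12)

    def test_kruskal_path_for_three_groups(self, rng):
        a, b, c = rng.normal(size=5), rng.normal(size=5) + 3, rng.normal(size=5)
        p, _ = compare_groups(a, b, c)
        from scipy.stats import kruskal
        assert p == pytest.approx(kruskal(a, b, c).pvalue)

    def test_star_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""


class TestNominalDays:
    def test_tracer_pair_merging(self):
        assert [nominal_day(d) for d in (0, 8, 9, 15, 16, 22, 23)] == [0, 9, 9, 16, 16, 23, 23]


def _toy_metrics():
    """Hand-built tidy metrics table: 2 groups x 2 animals x 2 sessions."""
    rows = []
    for g, animals, mld9, mld23 in [("NaCl", ["n1", "n2"], -600, -598),
                                    ("BLM", ["b1", "b2"], -550, -440)]:
        for i, a in enumerate(animals):
            for day, mld in [(9, mld9 + i), (23, mld23 + i)]:
                rows.append(dict(animal_id=a, group=g, day=day, nominal_day=day,
                                 tracer="CT", mld_hu=float(mld), aerated_pct=90.0,
                                 high_density_pct=10.0, lung_volume_ml=1.0))
                for tr, pid in [("FDG", 1.0 + (2.0 if g == "BLM" and day == 23 else 0)),
                                ("FMISO", 0.5 + (1.0 if g == "BLM" else 0))]:
                    rows.append(dict(animal_id=a, group=g, day=day - (1 if tr == "FDG" else 0),
                                     nominal_day=day, tracer=tr, pid_lung=pid + 0.01 * i,
                                     suv_mean=pid / 5, suv_max=pid / 2, ltbr=pid))
    return pd.DataFrame(rows)


class TestReport:
    def test_full_study_report_complete(self, tmp_path):
        rep = build_report(_toy_metrics(), tmp_path, make_plots=False)
        assert rep["n_warnings"] == 0
        assert len(rep["fold_changes"]) == 3   # MLD, FDG, FMISO vs NaCl
        assert (tmp_path / "per_scan_metrics.csv").exists()
        assert (tmp_path / "group_summary.csv").exists()

    def test_missing_scan_flagged_not_fatal(self, tmp_path):
        m = _toy_metrics()
        m = m[~((m.tracer == "FMISO") & (m.nominal_day == 23) & (m.group == "BLM"))]
        rep = build_report(m, tmp_path, make_plots=False)   # run succeeds
        assert any("missing" in w for w in rep["warnings"])
        assert rep["n_warnings"] > 0

    def test_rerun_byte_identical(self, tmp_path):
        m = _toy_metrics()
        build_report(m, tmp_path / "a", make_plots=False)
        build_report(m, tmp_path / "b", make_plots=False)
        for name in ("per_scan_metrics.csv", "group_summary.csv", "fold_changes.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
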