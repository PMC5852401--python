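import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
import yaml
from importlib import resources

from mapdist import (
    CohortTable,
    DistanceSet,
    ValidationError,
    box_whisker_summary,
    compare_groups,
    detect_artifacts,
    distance_histogram,
    evaluate_metrics,
    ks_two_sample,
    mann_whitney_u,
    pairwise_distances,
    remove_companions,
    run_comparison_suite,
)
from mapdist.distance_metrics import get_metric
from mapdist.map_histograms import HistogramSpec, MapHistogram
from mapdist.synthetic_fixtures import generate_cohort


def _dset(values, label="g", metric="hellinger"):
    values = np.asarray(values, dtype=float)
    pairs = [(f"a{i}", f"b{i}") for i in range(len(values))]
    return DistanceSet(metric=get_metric(metric), values=values, pairs=pairs,
                       group_label=label)


def _hist(probs, sid, spec=None):
    spec = spec or HistogramSpec(n_bins=len(probs), range_min=0, range_max=1)
    counts = (np.asarray(probs, dtype=float) * 10000).astype(int)
    return MapHistogram(spec=spec, counts=counts, n_binned=int(counts.sum()),
                        n_excluded_low=0, n_excluded_high=0, subject_id=sid)


class TestBoxWhiskerSummary:
    def test_constant_sample(self):
        b = box_whisker_summary([0.3] * 10)
        assert b.median == 0.3 and b.iqr == 0.0 and b.spread == 0.0
        assert b.outlier_values.size == 0

    def test_hand_evaluated_quartiles(self):
        b = box_whisker_summary([1, 2, 3, 4, 5, 6, 7, 100])
        assert (b.q1, b.median, b.q3) == (2.75, 4.5, 6.25)
        assert b.upper_limit == 11.5 and b.spread == 7.0
        assert list(b.outlier_values) == [100]

    def test_agrees_with_independent_quantile_routine(self):
        rng = np.random.default_rng(0)
        v = rng.lognormal(size=200)
        b = box_whisker_summary(v)
        q1, med, q3 = sps.scoreatpercentile(v, [25, 50, 75])
        assert b.q1 == pytest.approx(q1) and b.q3 == pytest.approx(q3)
        assert b.median == pytest.approx(med)

    def test_spread_translation_invariant(self):
        rng = np.random.default_rng(1)
        v = rng.random(50)
        assert box_whisker_summary(v + 10).spread == pytest.approx(
            box_whisker_summary(v).spread)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            box_whisker_summary([])


def _enumerate_u_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(len(pooled)) if i not in set(idx)]]
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_of(range(nx))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), nx)]
    us = np.asarray(us)
    lo = (us <= u_obs + 1e-9).mean()
    hi = (us >= u_obs - 1e-9).mean()
    return u_obs, min(1.0, 2 * min(lo, hi))


class TestMannWhitneyU:
    def test_fully_separated_small_samples(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r["U"] == 0.0
        assert r["p_two_sided"] == pytest.approx(1 / 3)

    def test_identical_samples_all_ties(self):
        x = [1.0, 2.0, 3.0]
        r = mann_whitney_u(x, x)
        assert r["U"] == pytest.approx(len(x) ** 2 / 2)

    def test_complementarity(self):
        rng = np.random.default_rng(2)
        x, y = rng.integers(0, 5, 8).astype(float), rng.integers(0, 5, 6).astype(float)
        assert mann_whitney_u(x, y)["U"] + mann_whitney_u(y, x)["U"] == \
            pytest.approx(len(x) * len(y))

    def test_exact_p_matches_full_enumeration_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            nx, ny = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            x = rng.integers(0, 4, nx).astype(float)
            y = rng.integers(0, 4, ny).astype(float)
            u_obs, p_exact = _enumerate_u_pvalue(x, y)
            r = mann_whitney_u(x, y)
            assert r["U"] == pytest.approx(u_obs)
            assert r["p_two_sided"] == pytest.approx(p_exact, abs=1e-12)

    def test_u_statistic_matches_scipy_convention(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=30), rng.normal(size=25)
        r = mann_whitney_u(x, y)
        assert r["U"] == pytest.approx(
            sps.mannwhitneyu(x, y).statistic)

    def test_large_sample_p_close_to_scipy_normal_approximation(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(0.8, 1, size=35)
        r = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert r["p_two_sided"] == pytest.approx(ref, rel=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestKsTwoSample:
    def test_disjoint_supports(self):
        assert ks_two_sample([1, 2, 3], [4, 5, 6])["D"] == 1.0

    def test_identical_samples(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3])["D"] == 0.0

    def test_interleaved_samples(self):
        assert ks_two_sample([1, 3], [2, 4])["D"] == 0.5

    def test_matches_brute_force_ecdf_difference(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            x = rng.normal(size=rng.integers(3, 20))
            y = rng.normal(0.3, 1.2, size=rng.integers(3, 20))
            grid = np.concatenate([x, y])
            fx = (x[:, None] <= grid[None, :]).mean(axis=0)
            fy = (y[:, None] <= grid[None, :]).mean(axis=0)
            d_brute = np.abs(fx - fy).max()
            assert ks_two_sample(x, y)["D"] == pytest.approx(d_brute, abs=1e-12)

    def test_binned_mode_on_shared_spec(self):
        spec = HistogramSpec(n_bins=10, range_min=0, range_max=1)
        x = np.full(50, 0.25)
        y = np.full(60, 0.75)
        r = ks_two_sample(x, y, mode="binned", spec=spec)
        assert r["D"] == 1.0
        assert r["p"] < 1e-6

    def test_binned_requires_spec(self):
        with pytest.raises(ValidationError):
            ks_two_sample([1.0], [2.0], mode="binned")


class TestDistanceHistogram:
    def test_degenerate_sample_single_bin(self):
        h = distance_histogram(_dset([0.2] * 12), n_bins=10)
        assert (h.density > 0).sum() == 1
        assert h.density.max() == pytest.approx(1.0 / h.bin_width)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(7)
        h = distance_histogram(_dset(rng.random(200)), n_bins=25)
        assert (h.density * h.bin_width).sum() == pytest.approx(1.0)

    def test_cumulative_monotone_ending_at_one(self):
        rng = np.random.default_rng(8)
        h = distance_histogram(_dset(rng.lognormal(size=100)))
        assert np.all(np.diff(h.cumulative) >= -1e-12)
        assert h.cumulative[-1] == pytest.approx(1.0)


class TestCompareGroups:
    def test_identical_sets(self):
        rng = np.random.default_rng(9)
        v = rng.random(40)
        r = compare_groups(_dset(v, "a"), _dset(v, "b"))
        assert r.ks_D == 0.0
        assert r.U == pytest.approx(len(v) ** 2 / 2)
        assert r.box_a.spread == pytest.approx(r.box_b.spread)

    def test_disjoint_shift_gives_maximal_ks(self):
        rng = np.random.default_rng(10)
        v = rng.random(30)
        r = compare_groups(_dset(v, "a"), _dset(v + 10.0, "b"))
        assert r.ks_D == 1.0
        assert r.p_ks < 1e-10

    def test_metric_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(_dset([0.1], metric="hellinger"),
                           _dset([0.1], metric="canberra"))


class TestDetectArtifacts:
    def test_identical_histograms_converge_without_flags(self):
        hists = [_hist([0.25] * 4, f"s{i}") for i in range(8)]
        rep = detect_artifacts(hists)
        assert rep.converged and not rep.flagged_ids
        assert len(rep.iterations) == 1

    def test_single_gross_outlier_flagged(self):
        rng = np.random.default_rng(11)
        spec = HistogramSpec(n_bins=6, range_min=0, range_max=1)
        base = np.array([0.3, 0.3, 0.2, 0.1, 0.05, 0.05])
        hists = []
        for i in range(12):
            w = base + rng.uniform(-0.01, 0.01, 6)
            hists.append(_hist(w / w.sum(), f"s{i}", spec))
        hists.append(_hist([0.0, 0.0, 0.0, 0.0, 0.1, 0.9], "bad", spec))
        rep = detect_artifacts(hists)
        assert rep.flagged_ids == ["bad"]
        assert rep.converged

    def test_too_few_histograms_rejected(self):
        hists = [_hist([0.5, 0.5], f"s{i}") for i in range(3)]
        with pytest.raises(ValidationError):
            detect_artifacts(hists)


class TestRemoveCompanions:
    def _cohort(self, n=10):
        import pandas as pd
        frame = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "fa_path": ["fa.nii"] * n, "md_path": ["md.nii"] * n,
            "vendor": ["GE"] * n, "field_strength": [1.5] * n,
            "b_value": [1000.0] * n, "n_directions": [6] * n,
        })
        return CohortTable(frame=frame)

    def test_flag_removes_both_modalities(self):
        cohort = remove_companions(["s1", "s5"], self._cohort())
        assert len(cohort) == 8
        assert "s1" not in cohort.subject_ids

    def test_empty_flag_list_is_identity(self):
        cohort = self._cohort()
        assert remove_companions([], cohort).subject_ids == cohort.subject_ids

    def test_unknown_id_rejected(self):
        with pytest.raises(ValidationError):
            remove_companions(["ghost"], self._cohort())


class TestEvaluateMetrics:
    def test_degenerate_normal_set(self):
        normal = [_hist([0.25] * 4, f"s{i}") for i in range(4)]
        artifact = [_hist([0.7, 0.1, 0.1, 0.1], "bad")]
        table = evaluate_metrics(normal, artifact)
        assert (table["dynamic_range"] == 0).all()
        finite_pos = table["separation_score"] == math.inf
        assert finite_pos.all()

    def test_gross_artifact_scores_above_one_for_true_metrics(self):
        rng = np.random.default_rng(12)
        spec = HistogramSpec(n_bins=6, range_min=0, range_max=1)
        normal = []
        for i in range(10):
            w = np.array([0.3, 0.3, 0.2, 0.1, 0.05, 0.05]) + rng.uniform(
                -0.02, 0.02, 6)
            normal.append(_hist(w / w.sum(), f"s{i}", spec))
        artifact = [_hist([0.0, 0.0, 0.0, 0.1, 0.2, 0.7], "bad", spec)]
        table = evaluate_metrics(normal, artifact).set_index("metric")
        for name in ("hellinger", "city_block", "euclidean", "jensen_shannon"):
            assert table.loc[name, "separation_score"] > 1

    def test_ranking_sorted_by_separation(self):
        rng = np.random.default_rng(13)
        spec = HistogramSpec(n_bins=5, range_min=0, range_max=1)
        normal = [_hist(rng.dirichlet([5] * 5), f"s{i}", spec) for i in range(6)]
        artifact = [_hist([0.9, 0.05, 0.02, 0.02, 0.01], "bad", spec)]
        scores = evaluate_metrics(normal, artifact)["separation_score"]
        assert list(scores) == sorted(scores, reverse=True)


class TestComparisonSuite:
    def test_default_suite_has_nine_entries(self):
        text = resources.files("mapdist.data").joinpath(
            "nine_comparisons.yaml").read_text()
        suite = yaml.safe_load(text)
        assert len(suite) == 9
        assert all({"name", "criteria_a", "criteria_b"} <= set(e) for e in suite)

    def test_identical_groups_show_no_difference(self, tmp_path):
        specs = [
            {"metadata": {"vendor": "GE", "field_strength": 1.5,
                          "b_value": 1000, "n_directions": 6}, "n": 5},
            {"metadata": {"vendor": "SIEMENS", "field_strength": 1.5,
                          "b_value": 1000, "n_directions": 6}, "n": 5},
        ]
        cohort, _, _ = generate_cohort(specs, tmp_path, seed=21,
                                       shape=(12, 12, 12))
        suite = [{"name": "vendors",
                  "criteria_a": {"vendor": "GE"},
                  "criteria_b": {"vendor": "SIEMENS"}}]
        res = run_comparison_suite(cohort, suite, "hellinger")
        assert len(res) == 2  # FA and MD rows
        assert (res["ks_D"] < 0.5).all()
        assert (res["p_ks"] > 0.01).all()

    def test_end_to_end_deterministic(self, tmp_path):
        specs = [{"metadata": {"vendor": "GE", "field_strength": 1.5,
                               "b_value": 1000, "n_directions": 6}, "n": 4},
                 {"metadata": {"vendor": "GE", "field_strength": 3.0,
                               "b_value": 1000, "n_directions": 6}, "n": 4}]
        cohort, _, _ = generate_cohort(specs, tmp_path, seed=5,
                                       shape=(10, 10, 10))
        suite = [{"name": "fields",
                  "criteria_a": {"field_strength": 1.5},
                  "criteria_b": {"field_strength": 3.0}}]
        r1 = run_comparison_suite(cohort, suite, "hellinger")
        r2 = run_comparison_suite(cohort, suite, "hellinger")
        assert r1.equals(r2)

    def test_undersized_group_skipped(self, tmp_path):
        specs = [{"metadata": {"vendor": "GE", "field_strength": 1.5,
                               "b_value": 1000, "n_directions": 6}, "n": 4}]
        cohort, _, _ = generate_cohort(specs, tmp_path, seed=6,
                                       shape=(10, 10, 10))
        suite = [{"name": "ghost",
                  "criteria_a": {"vendor": "GE"},
                  "criteria_b": {"vendor": "SIEMENS"}}]
        res = run_comparison_suite(cohort, suite, "hellinger")
        assert res.empty
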