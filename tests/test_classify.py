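"""Decision tree, scoring and benchmark harness."""

import numpy as np
import pytest

from chondrotrace.classify import (
    BackendUnavailableError,
    BehaviorCategory,
    ClassificationResult,
    TreeParams,
    benchmark_backends,
    classify_all,
    classify_cell,
    score,
)
from chondrotrace.features import (
    Changepoint,
    ChangepointSet,
    FeatureFingerprint,
    Peak,
    PeakSet,
    TraceStats,
    fingerprint,
)
from chondrotrace.intensity import IntensityTrace, smooth
from chondrotrace.synth import trace_template


def make_fp(
    cell_id=0,
    blue_max=2.0,
    blue_argmax=150,
    blue_range=1.0,
    blue_range_after_max=0.5,
    red_mean_after_50=30.0,
    red_blue_diff=0.0,
    blue_cps=(),
    green_cps=(),
    blue_peaks=(),
    green_peaks=(),
):
    """Hand-built fingerprint touching only the statistics the tree reads."""

    def stats(mx, amax, rng_, after, ram):
        return TraceStats(min=0.0, max=mx, argmax=amax, mean=mx / 2,
                          variance=1.0, range=rng_, mean_after={50: after},
                          range_after_argmax=ram)

    return FeatureFingerprint(
        cell_id=cell_id,
        stats={
            "blue": stats(blue_max, blue_argmax, blue_range, 1.0,
                          blue_range_after_max),
            "green": stats(1.0, 0, 0.5, 1.0, 0.5),
            "red": stats(30.0, 0, 1.0, red_mean_after_50, 0.5),
        },
        peaks={
            "blue": PeakSet([Peak(loc, 5.0, 4.0, 8.0) for loc in blue_peaks]),
            "green": PeakSet([Peak(loc, 5.0, 4.0, 8.0) for loc in green_peaks]),
        },
        changepoints={
            "blue": ChangepointSet([Changepoint(i, 0.0, 1.0) for i in blue_cps]),
            "green": ChangepointSet([Changepoint(i, 0.0, 1.0) for i in green_cps]),
        },
        red_blue_mean_diff=red_blue_diff,
    )


class TestClassifyCell:
    def test_elevated_start_is_a(self):
        cat, path = classify_cell(make_fp(blue_max=9.0, blue_argmax=3))
        assert cat is BehaviorCategory.A
        assert any("argmax" in step for step in path)

    def test_many_changepoints_is_multilevel(self):
        cat, _ = classify_cell(make_fp(blue_cps=(20, 60, 100, 140, 180)))
        assert cat is BehaviorCategory.L

    def test_no_changepoints_green_peak_is_transient_only(self):
        cat, _ = classify_cell(make_fp(green_peaks=(80,)))
        assert cat is BehaviorCategory.I

    def test_quiet_cell_high_red_is_normal(self):
        cat, _ = classify_cell(make_fp(blue_range=4.0, red_mean_after_50=30.0))
        assert cat is BehaviorCategory.J

    def test_quiet_cell_low_red_is_all_low(self):
        cat, _ = classify_cell(make_fp(blue_range=4.0, red_mean_after_50=2.0))
        assert cat is BehaviorCategory.K

    def test_polarized_red_with_step_is_e(self):
        cat, _ = classify_cell(make_fp(blue_cps=(60,), red_blue_diff=25.0))
        assert cat is BehaviorCategory.E

    def test_peak_before_step_is_h_after_is_g(self):
        cat, _ = classify_cell(make_fp(blue_cps=(100,), green_peaks=(50,)))
        assert cat is BehaviorCategory.H
        cat, _ = classify_cell(make_fp(blue_cps=(60,), green_peaks=(150,)))
        assert cat is BehaviorCategory.G

    def test_late_step_with_green_changepoint_is_f_else_d(self):
        late = dict(blue_cps=(150,), blue_argmax=200)
        cat, _ = classify_cell(make_fp(green_cps=(120,), **late))
        assert cat is BehaviorCategory.F
        cat, _ = classify_cell(make_fp(**late))
        assert cat is BehaviorCategory.D

    def test_immediate_step_with_blue_peak_is_c(self):
        cat, _ = classify_cell(make_fp(blue_cps=(60,), blue_argmax=90,
                                       blue_peaks=(90,)))
        assert cat is BehaviorCategory.C

    def test_immediate_step_plateau_is_b(self):
        cat, _ = classify_cell(make_fp(blue_cps=(60,), blue_argmax=90,
                                       blue_range_after_max=1.0))
        assert cat is BehaviorCategory.B

    def test_immediate_step_large_tail_range_is_a_fallback(self):
        cat, path = classify_cell(make_fp(blue_cps=(60,), blue_argmax=90,
                                          blue_range_after_max=12.0))
        assert cat is BehaviorCategory.A
        assert "remaining in changepoint branch" in path

    def test_strict_inequalities_at_thresholds(self):
        # exactly at the threshold: "greater than" excludes equality
        cat, _ = classify_cell(make_fp(blue_max=7.0, blue_argmax=3))
        assert cat is not BehaviorCategory.A
        cat, _ = classify_cell(make_fp(blue_range=10.0, red_mean_after_50=30.0))
        assert cat is BehaviorCategory.J

    def test_missing_statistic_errors(self):
        fp = make_fp()
        fp.stats["red"].mean_after = {}
        with pytest.raises(ValueError, match="mean-after"):
            classify_cell(fp)

    def test_decision_path_replays_to_same_label(self):
        for kw in (dict(), dict(blue_cps=(60,), green_peaks=(150,)),
                   dict(blue_max=9.0, blue_argmax=2)):
            fp = make_fp(**kw)
            cat1, path1 = classify_cell(fp)
            cat2, path2 = classify_cell(fp)
            assert cat1 == cat2 and path1 == path2
            assert path1[-1] == f"-> {cat1.value}"


class TestClassifyAll:
    def _template_fps(self, noise=0.0, seed=0):
        fps = []
        for i, cat in enumerate(BehaviorCategory):
            traces = trace_template(cat, 300, noise, seed + i)
            b, g, r = (smooth(traces[k], 20) for k in range(3))
            tr = IntensityTrace(i, np.arange(300), b, g, r, smoothed=True,
                                background_subtracted=True)
            fps.append(fingerprint(tr, after_frames=[50]))
        return fps

    def test_twelve_templates_twelve_correct_labels(self):
        result = classify_all(self._template_fps())
        assert result.categories == list(BehaviorCategory)

    def test_order_independence(self):
        fps = self._template_fps()
        forward = classify_all(fps).as_mapping()
        backward = classify_all(fps[::-1]).as_mapping()
        assert forward == backward

    def test_empty_input(self):
        result = classify_all([])
        assert len(result) == 0
        assert sum(result.counts.values()) == 0

    def test_counts_sum_to_cells(self):
        result = classify_all(self._template_fps())
        assert sum(result.counts.values()) == 12

    def test_threshold_monotonicity_of_blue_rise_range(self):
        """Raising blue_rise_range can move cells from B to J/K, never the
        reverse."""
        rng = np.random.default_rng(6)
        fps = [make_fp(cell_id=i, blue_range=float(rng.uniform(0, 30)),
                       red_mean_after_50=float(rng.uniform(0, 30)))
               for i in range(60)]
        prev_b = None
        for thr in (5.0, 10.0, 15.0, 20.0):
            result = classify_all(fps, TreeParams(blue_rise_range=thr))
            b_cells = {cid for cid, cat in result.as_mapping().items()
                       if cat is BehaviorCategory.B}
            others = {cid for cid, cat in result.as_mapping().items()
                      if cat in (BehaviorCategory.J, BehaviorCategory.K)}
            if prev_b is not None:
                assert b_cells <= prev_b  # B can only shrink
                assert prev_others <= others
            prev_b, prev_others = b_cells, others


class TestScore:
    def test_perfect_predictions(self):
        result = ClassificationResult([1, 2], [BehaviorCategory.I,
                                               BehaviorCategory.J], [(), ()])
        per_cat, total = score(result, {1: "I", 2: "J"})
        assert total == 1.0
        assert per_cat[BehaviorCategory.I] == 1.0

    def test_category_accuracy_is_tp_over_truth_count(self):
        n = 100
        preds = [BehaviorCategory.I] * 85 + [BehaviorCategory.J] * 15
        result = ClassificationResult(list(range(n)), preds, [()] * n)
        per_cat, _ = score(result, {i: "I" for i in range(n)})
        assert per_cat[BehaviorCategory.I] == pytest.approx(0.85)

    def test_total_accuracy(self):
        preds = [BehaviorCategory.J] * 16 + [BehaviorCategory.K] * 4
        result = ClassificationResult(list(range(20)), preds, [()] * 20)
        _, total = score(result, {i: "J" for i in range(20)})
        assert total == pytest.approx(0.8)

    def test_absent_category_undefined_not_zero(self):
        result = ClassificationResult([0], [BehaviorCategory.J], [()])
        per_cat, _ = score(result, {0: "J"})
        assert per_cat[BehaviorCategory.L] is None

    def test_mismatched_ids_error(self):
        result = ClassificationResult([0], [BehaviorCategory.J], [()])
        with pytest.raises(ValueError, match="cell_id"):
            score(result, {1: "J"})


@pytest.fixture(scope="module")
def separable_dataset():
    rng = np.random.default_rng(12)
    X, y = [], []
    for cat in ("J", "B"):
        for _ in range(40):
            X.append(trace_template(cat, 200, 1.0, int(rng.integers(2**31 - 1))))
            y.append(cat)
    return np.stack(X), y


class TestBenchmarkBackends:
    def test_well_separated_categories_high_accuracy(self, separable_dataset):
        X, y = separable_dataset
        results = benchmark_backends(X, y, backends=["stats-forest"],
                                     split_seed=0)
        assert results["stats-forest"] >= 0.95

    def test_same_seed_identical_results(self, separable_dataset):
        X, y = separable_dataset
        a = benchmark_backends(X, y, backends=["stats-forest"], split_seed=7)
        b = benchmark_backends(X, y, backends=["stats-forest"], split_seed=7)
        assert a == b

    def test_no_backends_is_capability_error(self, separable_dataset):
        X, y = separable_dataset
        with pytest.raises(BackendUnavailableError):
            benchmark_backends(X, y, backends=[], registry={})
        with pytest.raises(BackendUnavailableError, match="not available"):
            benchmark_backends(X, y, backends=["no-such-backend"])

    def test_transient_split_mode_runs(self, separable_dataset):
        X, y = separable_dataset
        results = benchmark_backends(X, y, backends=["flat-ridge"],
                                     split_seed=0, split_transients=True)
        assert 0.0 <= results["flat-ridge"] <= 1.0
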