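import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppsn.inference import ContingencyTable
from ppsn.roc import (
    HIGH_ABNORMAL,
    LOW_ABNORMAL,
    CutoffSpec,
    DegenerateRocWarning,
    RocError,
    build_roc,
    auc,
    diagnostic_metrics,
    truncate2,
    youden_cutoff,
)


def pairwise_auc(values, labels, direction):
    """U-statistic oracle: fraction of (event, non-event) pairs correctly
    ordered toward the abnormal side, ties counted one half."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    pos, neg = v[y], v[~y]
    if direction == HIGH_ABNORMAL:
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    else:
        wins = sum((p < q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_force_youden(values, labels, roc):
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    best = -2.0
    for t in roc.thresholds:
        ab = v >= t if roc.direction == HIGH_ABNORMAL else v <= t
        se = (ab & y).sum() / y.sum()
        sp = (~ab & ~y).sum() / (~y).sum()
        best = max(best, se + sp - 1.0)
    return best


class TestBuildRoc:
    def test_perfect_separation_reaches_corner(self):
        roc = build_roc([1, 2, 3, 4], [False, False, True, True], HIGH_ABNORMAL)
        assert any(f == 0.0 and s == 1.0 for f, s in zip(roc.fpr, roc.tpr))
        assert auc(roc)[0] == 1.0

    def test_single_class_raises(self):
        with pytest.raises(RocError):
            build_roc([1, 2, 3], [True, True, True])

    def test_identical_values_degenerate(self):
        with pytest.warns(DegenerateRocWarning):
            roc = build_roc([5.0] * 6, [True] * 3 + [False] * 3, HIGH_ABNORMAL)
        assert auc(roc) == (0.5, 1.0)

    def test_curve_monotone_with_endpoints(self, rng):
        v = rng.normal(size=25)
        y = rng.uniform(size=25) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        for d in (HIGH_ABNORMAL, LOW_ABNORMAL):
            roc = build_roc(v, y, d)
            assert np.all(np.diff(roc.tpr) <= 0) and np.all(np.diff(roc.fpr) <= 0)
            assert roc.tpr[0] == roc.fpr[0] == 1.0
            assert roc.tpr[-1] == roc.fpr[-1] == 0.0

    def test_auto_orientation_never_below_half(self, rng):
        for _ in range(25):
            v = rng.integers(0, 6, size=20).astype(float)
            y = rng.uniform(size=20) < 0.5
            if y.all() or not y.any():
                continue
            roc = build_roc(v, y, "auto")
            assert auc(roc)[0] >= 0.5


class TestAucOracle:
    def test_trapezoid_equals_pairwise_counting(self, rng):
        """Trapezoid AUC == Mann-Whitney U / (n_pos * n_neg), ties 1/2."""
        for _ in range(300):
            n = int(rng.integers(5, 25))
            v = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            y = rng.uniform(size=n) < 0.5
            if y.all() or not y.any():
                continue
            for d in (HIGH_ABNORMAL, LOW_ABNORMAL):
                roc = build_roc(v, y, d)
                assert auc(roc)[0] == pytest.approx(pairwise_auc(v, y, d), abs=1e-12)

    def test_direction_flip_mirrors_auc(self, rng):
        v = rng.normal(size=40)
        y = rng.uniform(size=40) < 0.5
        hi = auc(build_roc(v, y, HIGH_ABNORMAL))[0]
        lo = auc(build_roc(v, y, LOW_ABNORMAL))[0]
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_null_marker_auc_near_half(self, rng):
        v = rng.normal(size=4000)
        y = rng.uniform(size=4000) < 0.5
        assert auc(build_roc(v, y, HIGH_ABNORMAL))[0] == pytest.approx(0.5, abs=0.05)


class TestYouden:
    def test_separable_midpoint(self):
        roc = build_roc([1, 2, 3, 5, 6, 7], [0, 0, 0, 1, 1, 1], HIGH_ABNORMAL)
        spec = youden_cutoff(roc)
        assert spec.cutoff == 4.0
        assert spec.youden_j == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 12), st.booleans()), min_size=4, max_size=30
        ).filter(lambda d: 0 < sum(b for _, b in d) < len(d))
    )
    def test_equals_exhaustive_scan(self, data):
        """Youden maximization agrees with brute force on every instance."""
        v = [float(x) for x, _ in data]
        y = [b for _, b in data]
        for d in (HIGH_ABNORMAL, LOW_ABNORMAL):
            roc = build_roc(v, y, d)
            spec = youden_cutoff(roc)
            assert spec.youden_j == pytest.approx(brute_force_youden(v, y, roc), abs=1e-12)

    def test_tie_broken_toward_fewer_abnormal(self):
        # J ties at several thresholds; the most specific rule must win
        v = [1.0, 2.0, 3.0, 4.0]
        y = [False, True, False, True]
        roc = build_roc(v, y, HIGH_ABNORMAL)
        spec = youden_cutoff(roc)
        n_abn = sum(x >= spec.cutoff for x in v)
        js = roc.tpr - roc.fpr
        for t, j in zip(roc.thresholds, js):
            if j == pytest.approx(spec.youden_j, abs=1e-12):
                assert sum(x >= t for x in v) >= n_abn


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "tp, fp, fn, tn, se, sp, ppv, npv",
        [
            (40, 14, 4, 14, 0.909, 0.500, 74.07, 77.77),
            (24, 7, 20, 21, 0.545, 0.750, 77.41, 51.21),
        ],
    )
    def test_published_post_treatment_rows(self, tp, fp, fn, tn, se, sp, ppv, npv):
        """Counts reconstructed from the published post-chemotherapy rows
        reproduce the printed Se/Sp (3 dp, rounded) and PPV/NPV (2 dp,
        truncated)."""
        values = [1.0] * (tp + fp) + [0.0] * (fn + tn)
        labels = [True] * tp + [False] * fp + [True] * fn + [False] * tn
        spec = CutoffSpec(
            marker="m", timepoint="post", cutoff=0.5, direction=HIGH_ABNORMAL,
            youden_j=0.0, auc=0.5, auc_p=1.0,
        )
        m = diagnostic_metrics(values, labels, spec)
        assert m.table == ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)
        assert round(m.sensitivity, 3) == se
        assert round(m.specificity, 3) == sp
        assert truncate2(m.ppv) == ppv
        assert truncate2(m.npv) == npv

    def test_bayes_identity_exact(self, rng):
        """PPV == Se*pi / (Se*pi + (1-Sp)(1-pi)) with pi the prevalence."""
        for _ in range(50):
            v = rng.normal(size=30)
            y = rng.uniform(size=30) < 0.5
            if y.all() or not y.any():
                continue
            roc = build_roc(v, y, HIGH_ABNORMAL)
            spec = youden_cutoff(roc)
            m = diagnostic_metrics(v, y, spec)
            if m.ppv is None:
                continue
            pi = y.mean()
            se, sp = m.sensitivity, m.specificity
            expected = 100.0 * se * pi / (se * pi + (1 - sp) * (1 - pi))
            assert m.ppv == pytest.approx(expected, abs=1e-9)

    def test_perfect_classifier(self):
        spec = CutoffSpec(
            marker="m", timepoint="pre", cutoff=5.0, direction=HIGH_ABNORMAL,
            youden_j=1.0, auc=1.0, auc_p=0.0,
        )
        m = diagnostic_metrics([1, 2, 8, 9], [False, False, True, True], spec)
        assert m.sensitivity == m.specificity == 1.0
        assert m.ppv == m.npv == 100.0


class TestTruncate2:
    @pytest.mark.parametrize(
        "x, expected",
        [
            (27 / 33 * 100, 81.81),   # rounding would print 81.82
            (14 / 18 * 100, 77.77),
            (50.0, 50.0),
            (352 / 168, 2.09),
            (10.0, 10.0),
        ],
    )
    def test_truncates_toward_zero(self, x, expected):
        assert truncate2(x) == expected
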