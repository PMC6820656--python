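import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netvuln import km_logrank, roc_auc
from netvuln.evaluation import km_curve, _logrank
from netvuln.errors import ParameterError


def series(scores, labels):
    idx = [f"s{i}" for i in range(len(scores))]
    return (pd.Series(scores, index=idx, name="m"),
            pd.Series(labels, index=idx))


LAB = {"S": "sensitive", "R": "resistant"}


class TestROC:
    def test_perfect_separation(self):
        s, g = series([1, 2, 3, 4], [LAB[c] for c in "SSRR"])
        assert roc_auc(s, g).auc == pytest.approx(1.0)

    def test_one_discordant_pair(self):
        s, g = series([1, 3, 2, 4], [LAB[c] for c in "SSRR"])
        assert roc_auc(s, g).auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        s, g = series([5, 5, 5, 5], [LAB[c] for c in "SSRR"])
        assert roc_auc(s, g).auc == pytest.approx(0.5)

    def test_auc_equals_pair_enumeration(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 5, size=30).astype(float)  # forces ties
        labels = [LAB["R"] if rng.random() < 0.5 else LAB["S"] for _ in range(30)]
        if LAB["R"] not in labels:
            labels[0] = LAB["R"]
        if LAB["S"] not in labels:
            labels[1] = LAB["S"]
        s, g = series(scores, labels)
        pos = scores[np.array(labels) == LAB["R"]]
        neg = scores[np.array(labels) == LAB["S"]]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0) for p in pos for n in neg]
        assert roc_auc(s, g).auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        s, g = series(rng.normal(size=20), [LAB["SR"[i % 2]] for i in range(20)])
        r = roc_auc(s, g)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_one_class_absent_is_error(self):
        s, g = series([1, 2], [LAB["R"], LAB["R"]])
        with pytest.raises(Exception):
            roc_auc(s, g)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(-5, 5), min_size=4, max_size=20))
    def test_sign_flip_complements_auc(self, raw):
        scores = [float(v) for v in raw]
        labels = [LAB["SR"[i % 2]] for i in range(len(scores))]
        s, g = series(scores, labels)
        s_neg, _ = series([-v for v in scores], labels)
        assert roc_auc(s, g).auc + roc_auc(s_neg, g).auc == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(-30, 30), min_size=4, max_size=20))
    def test_monotone_transform_invariance(self, raw):
        # grid-valued scores so float exp() stays strictly monotone
        raw = [v / 10.0 for v in raw]
        labels = [LAB["SR"[i % 2]] for i in range(len(raw))]
        s, g = series(raw, labels)
        s_exp, _ = series(list(np.exp(raw)), labels)
        assert roc_auc(s, g).auc == pytest.approx(roc_auc(s_exp, g).auc, abs=1e-12)


class TestKM:
    def test_no_censoring_equals_empirical_survival(self):
        times = [3.0, 1.0, 4.0, 1.0, 5.0]
        tab = km_curve(times, [1, 1, 1, 1, 1])
        arr = np.array(times)
        for _, row in tab.iterrows():
            assert row["survival"] == pytest.approx((arr > row["time"]).mean())

    def test_survival_starts_below_one_and_never_increases(self):
        tab = km_curve([1, 2, 2, 3, 8, 9], [1, 1, 0, 1, 0, 1])
        s = tab["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)
        assert s[0] <= 1.0

    def test_censored_at_event_time_counted_at_risk(self):
        # at t=2: subjects {2(event), 2(censored), 3} at risk -> d/n = 1/3
        tab = km_curve([1, 2, 2, 3], [1, 1, 0, 1])
        row = tab[tab["time"] == 2.0].iloc[0]
        assert row["at_risk"] == 3
        assert row["survival"] == pytest.approx((1 - 1 / 4) * (1 - 1 / 3))


class TestLogrank:
    def test_hand_computed_six_subject_example(self):
        # groups A: 1,2,3 (all events); B: 2,3,4 (all events)
        # O = 3, E = 1/2 + 4/5 + 2/3, V = 1/4 + 9/25 + 2/9
        expected = (3 - (1 / 2 + 4 / 5 + 2 / 3)) ** 2 / (1 / 4 + 9 / 25 + 2 / 9)
        chi2, p = _logrank(
            np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]),
            np.array([2.0, 3.0, 4.0]), np.array([1, 1, 1]),
        )
        assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_twelve_subject_fixture_matches_direct_computation(self):
        t1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e1 = np.array([1, 1, 1, 0, 1, 0])
        t2 = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        e2 = np.array([1, 1, 1, 0, 1, 0])
        # independent direct computation of O, E, V over the event table
        O = E = V = 0.0
        for t in sorted(set(t1[e1 == 1]) | set(t2[e2 == 1])):
            n1 = (t1 >= t).sum()
            n2 = (t2 >= t).sum()
            d1 = ((t1 == t) & (e1 == 1)).sum()
            d2 = ((t2 == t) & (e2 == 1)).sum()
            n, d = n1 + n2, d1 + d2
            if n < 2 or d == 0:
                continue
            O += d1
            E += d * n1 / n
            V += d * n1 * n2 * (n - d) / (n * n * (n - 1))
        expected = (O - E) ** 2 / V
        chi2, _ = _logrank(t1, e1, t2, e2)
        assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        t1 = rng.exponential(10, size=15).round(1)
        e1 = rng.integers(0, 2, size=15)
        t2 = rng.exponential(6, size=12).round(1)
        e2 = rng.integers(0, 2, size=12)
        chi2, p = _logrank(t1, e1, t2, e2)
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_identical_groups_chi2_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        chi2, p = _logrank(t, e, t.copy(), e.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        t1 = rng.exponential(5, 10)
        t2 = rng.exponential(9, 10)
        e = np.ones(10, dtype=int)
        a = _logrank(t1, e, t2, e)
        b = _logrank(t2, e, t1, e)
        assert a[0] == pytest.approx(b[0], abs=1e-10)


class TestKMLogrankSplit:
    def _data(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        expr = pd.Series(rng.normal(8, 1, n), index=idx, name="m")
        clin = pd.DataFrame({
            "pfs_time": rng.exponential(10, n),
            "pfs_event": rng.integers(0, 2, n),
            "os_time": rng.exponential(15, n),
            "os_event": np.ones(n, dtype=int),
        }, index=idx)
        return expr, clin

    def test_upper_quartile_split_sizes(self):
        expr, clin = self._data()
        fit = km_logrank(expr, clin, endpoint="OS", quartile=0.75)
        assert fit.n_high + fit.n_low == 40
        assert fit.n_high == (expr > fit.split_threshold).sum()
        assert fit.n_high <= 10  # strictly-above rule at the 75th percentile

    def test_degenerate_split_names_threshold(self):
        idx = [f"s{i}" for i in range(10)]
        expr = pd.Series(np.ones(10), index=idx)  # constant -> empty high group
        clin = self._data(10)[1]
        with pytest.raises(ParameterError, match="threshold"):
            km_logrank(expr, clin, endpoint="OS")

    def test_bad_endpoint_rejected(self):
        expr, clin = self._data()
        with pytest.raises(ParameterError):
            km_logrank(expr, clin, endpoint="DFS")
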