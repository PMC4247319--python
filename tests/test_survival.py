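import itertools

import numpy as np
import pandas as pd
import pytest

from plsde.errors import DataError, DegenerateStatisticError
from plsde.survival import km_curve, kmeans_split_1d, logrank_test, survival_screen

from conftest import make_matrix


def wcss_of(x, labels):
    x = np.asarray(x, dtype=float)
    total = 0.0
    for g in np.unique(labels):
        v = x[labels == g]
        total += np.sum((v - v.mean()) ** 2)
    return total


def brute_force_wcss_min(x):
    """Global 2-cluster WCSS minimum over every bipartition (n <= ~14)."""
    n = len(x)
    best = np.inf
    for bits in range(1, 2 ** n - 1):
        mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
        best = min(best, wcss_of(x, mask))
    return best


class TestKmeansSplit:
    def test_separated_clusters(self):
        labels = kmeans_split_1d([0.0, 0.0, 0.0, 10.0, 10.0])
        assert list(labels) == ["low", "low", "low", "high", "high"]

    def test_two_points(self):
        assert list(kmeans_split_1d([1.0, 2.0])) == ["low", "high"]

    def test_constant_values_error(self):
        with pytest.raises(DataError, match="constant"):
            kmeans_split_1d([3.0, 3.0, 3.0])

    def test_matches_exhaustive_wcss_minimum(self, rng):
        for _ in range(20):
            x = rng.normal(size=8)
            labels = kmeans_split_1d(x)
            assert wcss_of(x, labels) == pytest.approx(brute_force_wcss_min(x))

    def test_boundary_ties_go_low(self):
        labels = kmeans_split_1d([1.0, 1.0, 1.0, 1.0, 9.0, 1.0])
        assert list(labels) == ["low"] * 4 + ["high", "low"]


class TestKMCurve:
    def test_all_censored_survival_stays_one(self):
        c = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert c.event_times.size == 0

    def test_no_censoring_matches_empirical_survivor(self):
        c = km_curve([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(c.at_risk, [3, 2, 1])

    def test_censoring_shrinks_risk_set_only(self):
        # hand product-limit: S(1) = 2/3; censor at 2 leaves 1 at risk, so
        # S(3) = 2/3 * (1 - 1/1) = 0
        c = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        np.testing.assert_array_equal(c.event_times, [1.0, 3.0])
        np.testing.assert_allclose(c.survival, [2 / 3, 0.0])

    def test_monotone_and_bounded(self, rng):
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        c = km_curve(t, e)
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert np.all((c.survival >= 0) & (c.survival <= 1))


def hand_logrank(times, events, strata):
    """Independent O-E tabulation over pooled event times (oracle)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(strata) == "g1"
    U = V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n, n1 = at_risk.sum(), (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        U += d1 - n1 * d / n
        if n > 1:
            V += n1 * (n - n1) * d * (n - d) / (n ** 2 * (n - 1))
    return U * U / V


class TestLogrank:
    def test_matches_hand_tabulation(self):
        times = [1.0, 3.0, 2.0, 4.0]
        events = [1, 1, 1, 1]
        strata = ["g1", "g1", "g2", "g2"]
        stat, p = logrank_test(times, events, strata)
        assert stat == pytest.approx(hand_logrank(times, events, strata), abs=1e-12)
        assert 0.0 <= p <= 1.0

    def test_identical_groups_give_null_statistic(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        strata = ["g1"] * 3 + ["g2"] * 3
        stat, p = logrank_test(times, events, strata)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_group_label_swap_invariance(self, rng):
        times = rng.exponential(5, size=20)
        events = rng.integers(0, 2, size=20)
        events[:2] = 1
        strata = np.array(["g1"] * 10 + ["g2"] * 10)
        s1, p1 = logrank_test(times, events, strata)
        swapped = np.where(strata == "g1", "g2", "g1")
        s2, p2 = logrank_test(times, events, swapped)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_monotone_time_transform_invariance(self, rng):
        times = rng.exponential(5, size=16) + 0.1
        events = rng.integers(0, 2, size=16)
        events[:2] = 1
        strata = np.array(["g1"] * 8 + ["g2"] * 8)
        s1, _ = logrank_test(times, events, strata)
        s2, _ = logrank_test(np.log1p(times), events, strata)
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_no_events_is_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            logrank_test([1.0, 2.0], [0, 0], ["g1", "g2"])


class TestSurvivalScreen:
    def _phenotype(self, m, times, events):
        return pd.DataFrame({"sample": m.sample_ids,
                             "class": m.class_labels.to_numpy(),
                             "time": times, "event": events})

    def test_empty_feature_set(self, two_class_matrix, rng):
        pheno = self._phenotype(two_class_matrix,
                                rng.exponential(5, 10) + 0.1,
                                np.ones(10, dtype=int))
        out = survival_screen(two_class_matrix, [], pheno)
        assert out.empty

    def test_constant_feature_recorded_not_fatal(self, rng):
        x = rng.normal(size=(2, 6))
        x[1] = 5.0
        m = make_matrix(x, ["a"] * 3 + ["b"] * 3)
        pheno = self._phenotype(m, rng.exponential(5, 6) + 0.1, np.ones(6, int))
        out = survival_screen(m, ["f1", "f2"], pheno)
        assert out.loc[out["feature"] == "f2", "note"].iloc[0] != ""
        assert not out.loc[out["feature"] == "f2", "significant"].iloc[0]

    def test_prognostic_feature_has_smallest_p(self, rng):
        # feature f1 defines two strata with hazards 0.05 vs 0.5
        n = 40
        x = rng.normal(size=(6, n))
        x[0, : n // 2] -= 4.0
        m = make_matrix(x, ["a"] * (n // 2) + ["b"] * (n // 2))
        hazard = np.where(x[0] > np.median(x[0]), 0.5, 0.05)
        times = rng.exponential(1 / hazard)
        pheno = self._phenotype(m, times, np.ones(n, int))
        out = survival_screen(m, m.feature_ids, pheno)
        assert out.nsmallest(1, "p")["feature"].iloc[0] == "f1"
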