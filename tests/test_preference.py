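import numpy as np
import pytest

from sleepspike.core import NREM, REM, WAKE
from sleepspike.preference import (classify_preference, classify_unit,
                                   preference_correlation,
                                   rem_preference_index, state_bins,
                                   state_rates, triplet_profile,
                                   bootstrap_correlation_compare)
from conftest import make_hypnogram


class TestIndex:
    @pytest.mark.parametrize("fr_r, fr_n, expected", [
        (2.0, 0.0, 1.0),
        (0.0, 2.0, -1.0),
        (3.0, 3.0, 0.0),
        (1.0, 3.0, -0.5),
    ])
    def test_formula(self, fr_r, fr_n, expected):
        assert rem_preference_index(fr_r, fr_n) == pytest.approx(expected)

    def test_undefined_for_silent_unit(self):
        assert np.isnan(rem_preference_index(0.0, 0.0))

    def test_antisymmetric(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 10, 2)
            assert rem_preference_index(a, b) == pytest.approx(
                -rem_preference_index(b, a))


class TestStateRates:
    def test_homogeneous_train_equal_rates(self, rng):
        hyp = make_hypnogram([(NREM, 400), (REM, 200), (NREM, 400)])
        t = np.sort(rng.uniform(0, 1000, 2000))
        fr_r, fr_n = state_rates(np.unique(t), hyp)
        assert fr_r == pytest.approx(2.0, rel=0.15)
        assert fr_n == pytest.approx(2.0, rel=0.15)

    def test_empty_train_gives_zero(self):
        hyp = make_hypnogram([(NREM, 100), (REM, 100)])
        assert state_rates(np.empty(0), hyp) == (0.0, 0.0)

    def test_whole_second_epochs_match_count_oracle(self, rng):
        hyp = make_hypnogram([(NREM, 120), (REM, 80), (WAKE, 60), (NREM, 90)])
        t = np.unique(np.sort(rng.uniform(0, 350, 700)))
        fr_r, fr_n = state_rates(t, hyp)
        n_rem = np.count_nonzero((t >= 120) & (t < 200))
        n_nrem = np.count_nonzero(t < 120) + np.count_nonzero(
            (t >= 260) & (t < 350))
        assert fr_r == pytest.approx(n_rem / 80)
        assert fr_n == pytest.approx(n_nrem / 210)

    def test_short_epochs_are_excluded(self, rng):
        hyp = make_hypnogram([(NREM, 100), (REM, 40), (NREM, 100)])
        hyp.usable = np.array([True, False, True])
        starts, labels = state_bins(hyp)
        assert not np.any(labels == REM)


class TestClassify:
    def test_identical_bins_are_ns(self):
        counts = np.full(200, 3)
        labels = np.array([REM] * 100 + [NREM] * 100, dtype=object)
        res = classify_preference(counts, labels, rng=np.random.default_rng(0))
        assert res.index == 0.0
        assert res.label == "NS"

    def test_seeded_runs_identical(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=400)
        labels = np.array([REM, NREM] * 200, dtype=object)
        r1 = classify_preference(counts, labels, rng=np.random.default_rng(42))
        r2 = classify_preference(counts, labels, rng=np.random.default_rng(42))
        assert (r1.null_lo, r1.null_hi, r1.label) == \
            (r2.null_lo, r2.null_hi, r2.label)

    def test_strong_preference_detected(self, rng):
        counts = np.concatenate([rng.poisson(4.0, 300), rng.poisson(1.0, 300)])
        labels = np.array([REM] * 300 + [NREM] * 300, dtype=object)
        res = classify_preference(counts, labels, rng=rng)
        assert res.label == REM
        assert res.index > res.null_hi

    def test_label_order_exchangeable(self, rng):
        counts = rng.poisson(2.0, 400)
        labels = np.array([REM] * 200 + [NREM] * 200, dtype=object)
        perm = rng.permutation(400)
        r1 = classify_preference(counts, labels, rng=np.random.default_rng(7))
        r2 = classify_preference(counts[perm], labels[perm],
                                 rng=np.random.default_rng(7))
        assert r1.index == pytest.approx(r2.index)
        assert r1.label == r2.label

    def test_all_zero_counts_flagged_ns(self):
        labels = np.array([REM] * 50 + [NREM] * 50, dtype=object)
        res = classify_preference(np.zeros(100), labels,
                                  rng=np.random.default_rng(0))
        assert res.label == "NS"
        assert res.flag


class TestTripletProfile:
    def _triplets(self):
        return [((0.0, 90.0), (90.0, 150.0), (150.0, 240.0))]

    def test_constant_rate_profile_has_no_state_structure(self, rng):
        t = np.unique(np.sort(rng.uniform(0, 240, 2000)))
        p = triplet_profile(t, self._triplets())
        # raw thirds stay near the overall rate; z-scored profile is
        # centered (the z-scale itself is noise-normalized by construction)
        assert np.all(np.abs(p.thirds / p.thirds.mean() - 1) < 0.25)
        assert p.z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_rem_only_unit_orders_thirds(self, rng):
        t = np.unique(np.sort(rng.uniform(90, 150, 500)))
        p = triplet_profile(t, self._triplets())
        rem = p.z[3:6]
        nrem = np.concatenate([p.z[:3], p.z[6:]])
        assert rem.min() > nrem.max()

    def test_matches_interval_count_oracle(self, rng):
        t = np.unique(np.sort(rng.uniform(0, 240, 1000)))
        p = triplet_profile(t, self._triplets())
        raw = []
        for (lo, hi) in self._triplets()[0]:
            edges = np.linspace(lo, hi, 4)
            for a, b in zip(edges[:-1], edges[1:]):
                raw.append(np.count_nonzero((t >= a) & (t < b)) / (b - a))
        raw = np.array(raw)
        np.testing.assert_allclose(p.thirds, raw)
        np.testing.assert_allclose(p.z, (raw - raw.mean()) / raw.std())


class TestCorrelation:
    def test_identical_vectors_rho_one(self):
        idx = {f"u{i}": v for i, v in enumerate([0.1, -0.5, 0.3, 0.9, -0.2])}
        rho = preference_correlation({"hc0": idx, "hc1": dict(idx)})
        assert rho["hc0"]["hc1"] == pytest.approx(1.0)

    def test_reversed_ranks_rho_minus_one(self):
        a = {f"u{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 4.0])}
        b = {f"u{i}": v for i, v in enumerate([4.0, 3.0, 2.0, 1.0])}
        rho = preference_correlation({"hc0": a, "hc1": b})
        assert rho["hc0"]["hc1"] == pytest.approx(-1.0)

    def test_too_few_shared_units_undefined(self):
        a = {"u0": 0.1, "u1": 0.2}
        b = {"u0": 0.3, "u1": 0.1}
        rho = preference_correlation({"hc0": a, "hc1": b})
        assert np.isnan(rho["hc0"]["hc1"])


class TestBootstrap:
    def _region(self, rng, n=40, noise=0.1):
        base = rng.uniform(-1, 1, n)
        return {
            "hc0": {f"u{i}": base[i] + rng.normal(0, noise) for i in range(n)},
            "hc1": {f"u{i}": base[i] + rng.normal(0, noise) for i in range(n)},
        }

    def test_identical_regions_difference_ci_covers_zero(self, rng):
        regA = self._region(rng)
        regB = {s: dict(v) for s, v in regA.items()}
        out = bootstrap_correlation_compare({"A": regA, "B": regB},
                                            n_resample=40, n_boot=300,
                                            rng=np.random.default_rng(1))
        ci = out["region_diff"][(("hc0", "hc1"), "A", "B")]["ci"]
        assert ci[0] <= 0 <= ci[1]

    def test_stable_population_rho_significant(self, rng):
        reg = self._region(rng, noise=0.05)
        out = bootstrap_correlation_compare({"A": reg}, n_resample=40,
                                            n_boot=300,
                                            rng=np.random.default_rng(2))
        stats = out["rho"][("A", ("hc0", "hc1"))]
        assert stats["mean"] > 0.8
        assert stats["p_le_0"] == 0.0

    def test_seeded_runs_reproducible(self, rng):
        reg = self._region(rng)
        o1 = bootstrap_correlation_compare({"A": reg}, n_resample=30,
                                           n_boot=200,
                                           rng=np.random.default_rng(9))
        o2 = bootstrap_correlation_compare({"A": reg}, n_resample=30,
                                           n_boot=200,
                                           rng=np.random.default_rng(9))
        k = ("A", ("hc0", "hc1"))
        assert o1["rho"][k] == o2["rho"][k]


def test_classify_unit_recovers_strong_rem_preference(rng):
    layout = [(NREM, 120), (REM, 100)] * 8
    hyp = make_hypnogram(layout)
    rates = {NREM: 0.5, REM: 1.5}
    t = []
    for lo, hi, st in zip(hyp.starts, hyp.ends, hyp.states):
        n = rng.poisson(rates[st] * (hi - lo))
        t.append(rng.uniform(lo, hi, n))
    t = np.unique(np.sort(np.concatenate(t)))
    res = classify_unit(t, hyp, rng=rng)
    assert res.label == REM
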