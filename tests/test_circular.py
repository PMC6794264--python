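"""Phase bins, circular means, and homogeneity tests on the 24-h circle."""

import itertools

import numpy as np
import pytest

from dieltx.circular import (
    CircularSample,
    PhaseBin,
    _uniform_scores_statistic,
    bin_peak_time,
    cascade_test,
    category_taxon_homogeneity,
    circular_mean,
    hours_to_radians,
    pooled_circular_mean,
    watson_wheeler,
    watson_williams,
)
from dieltx.synthetic import simulate_phase_cascade


class TestBins:
    @pytest.mark.parametrize(
        "hour,expected",
        [
            (11.0, PhaseBin.EARLY_DAY),  # the early-day mode of periodic ORFs
            (23.0, PhaseBin.EARLY_NIGHT),  # the early-night mode
            (6.0, PhaseBin.EARLY_DAY),  # left-closed boundary
            (5.999, PhaseBin.LATE_NIGHT),
            (12.0, PhaseBin.LATE_DAY),
            (18.0, PhaseBin.EARLY_NIGHT),
            (0.0, PhaseBin.LATE_NIGHT),
        ],
    )
    def test_bin_assignment(self, hour, expected):
        assert bin_peak_time(hour) is expected

    @pytest.mark.parametrize("hour", [-0.1, 24.0, 30.0])
    def test_out_of_range_rejected(self, hour):
        with pytest.raises(ValueError):
            bin_peak_time(hour)

    def test_bins_partition_any_peak_set(self):
        rng = np.random.default_rng(0)
        hours = rng.uniform(0, 24, size=500)
        bins = [bin_peak_time(h) for h in hours]
        counts = {b: bins.count(b) for b in PhaseBin}
        assert sum(counts.values()) == 500


class TestCircularMean:
    def test_symmetric_pair(self):
        h, rbar = circular_mean(CircularSample.from_hours("g", [10.0, 12.0]))
        assert h == pytest.approx(11.0, abs=1e-9)
        assert rbar < 1.0

    def test_wraps_midnight(self):
        h, _ = circular_mean(CircularSample.from_hours("g", [23.0, 1.0]))
        assert h == pytest.approx(0.0, abs=1e-9)

    def test_balanced_antipodes_have_no_mean(self):
        h, rbar = circular_mean(CircularSample.from_hours("g", [0.0, 12.0]))
        assert np.isnan(h) and rbar == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_recovers_mean(self):
        # 10.883 h is 10:53 on the clock
        df = simulate_phase_cascade([("g", 1000, 10.883, 8.0)], seed=4)
        h, _ = circular_mean(CircularSample.from_hours("g", df["peak_time"].to_numpy()))
        err = abs(h - 10.883)
        assert min(err, 24 - err) < 0.1

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        hours = rng.uniform(0, 24, size=50)
        h, rbar = circular_mean(CircularSample.from_hours("g", hours))
        ref = float(pingouin.circ_mean(hours_to_radians(hours))) % (2 * np.pi)
        assert h == pytest.approx(ref * 24 / (2 * np.pi), abs=1e-9)
        assert rbar == pytest.approx(float(pingouin.circ_r(hours_to_radians(hours))), abs=1e-9)

    def test_weights_shift_the_mean(self):
        s = CircularSample.from_hours("g", [6.0, 12.0], weights=[3.0, 1.0])
        h, _ = circular_mean(s)
        assert 6.0 < h < 9.0

    def test_pooled_mean_of_balanced_categories(self):
        samples = [
            CircularSample.from_hours("a", [10.0] * 5),
            CircularSample.from_hours("b", [12.0] * 5),
        ]
        h, _ = pooled_circular_mean(samples)
        assert h == pytest.approx(11.0, abs=1e-9)


def brute_force_exact_p(hours_a, hours_b):
    """Enumerate every split of the pooled sample into groups of the
    observed sizes and report the tail fraction of the W statistic."""
    pooled = np.concatenate([hours_to_radians(hours_a), hours_to_radians(hours_b)])
    n1, N = len(hours_a), len(pooled)
    sizes = [n1, N - n1]
    W_obs = _uniform_scores_statistic(pooled, sizes)
    count = total = 0
    for comb in itertools.combinations(range(N), n1):
        rest = [i for i in range(N) if i not in comb]
        W = _uniform_scores_statistic(pooled[list(comb) + rest], sizes)
        total += 1
        if W >= W_obs - 1e-12:
            count += 1
    return count / total


class TestWatsonWheeler:
    def test_identical_values_give_p_one(self):
        g = [CircularSample.from_hours(l, [7.0, 7.0, 7.0]) for l in "ab"]
        res = watson_wheeler(g, seed=0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_duplicated_group_is_null(self):
        hours = [1.0, 5.0, 9.0, 14.0, 20.0]
        g = [CircularSample.from_hours(l, hours) for l in "ab"]
        res = watson_wheeler(g, tiebreak_iterations=400, seed=1)
        assert res.p_value > 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0, 24, 4), rng.uniform(0, 24, 4)
        res = watson_wheeler(
            [CircularSample.from_hours("a", a), CircularSample.from_hours("b", b)],
            exact=True,
        )
        assert res.p_value == pytest.approx(brute_force_exact_p(a, b), abs=1e-12)

    def test_separated_groups_detected(self):
        df = simulate_phase_cascade([("a", 25, 9.0, 6.0), ("b", 25, 15.0, 6.0)], seed=3)
        g = [
            CircularSample.from_hours(l, df.loc[df["group"] == l, "peak_time"].to_numpy())
            for l in ("a", "b")
        ]
        assert watson_wheeler(g).p_value < 1e-4

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.uniform(0, 24, 10), rng.uniform(0, 24, 12)
        r0 = watson_wheeler(
            [CircularSample.from_hours("a", a), CircularSample.from_hours("b", b)]
        )
        delta = 7.3
        r1 = watson_wheeler(
            [
                CircularSample.from_hours("a", (a + delta) % 24),
                CircularSample.from_hours("b", (b + delta) % 24),
            ]
        )
        assert r1.statistic == pytest.approx(r0.statistic, abs=1e-9)
        assert r1.p_value == pytest.approx(r0.p_value, abs=1e-9)

    def test_tie_jitter_averaging_is_stable_across_seeds(self):
        # ~30% ties; the averaged p must not wander with the jitter seed
        hours_a = [1.0, 5.0, 5.0, 9.0, 13.0, 17.0, 21.0, 5.0, 11.0, 15.0]
        hours_b = [2.0, 6.0, 6.0, 10.0, 14.0, 18.0, 22.0, 6.0, 12.0, 16.0]
        ps = [
            watson_wheeler(
                [
                    CircularSample.from_hours("a", hours_a),
                    CircularSample.from_hours("b", hours_b),
                ],
                tiebreak_iterations=1000,
                seed=s,
            ).p_value
            for s in range(8)
        ]
        assert np.std(ps) <= 0.005

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n=1"):
            watson_wheeler(
                [CircularSample.from_hours("a", [1.0]), CircularSample.from_hours("b", [2.0, 3.0])]
            )


class TestWatsonWilliams:
    def test_group_against_itself_is_null(self):
        hours = [9.0, 10.0, 11.0, 10.5, 9.5]
        res = watson_williams([CircularSample.from_hours(l, hours) for l in "ab"])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_two_hour_separation_detected(self):
        df = simulate_phase_cascade([("a", 20, 10.0, 20.0), ("b", 20, 12.0, 20.0)], seed=9)
        g = [
            CircularSample.from_hours(l, df.loc[df["group"] == l, "peak_time"].to_numpy())
            for l in ("a", "b")
        ]
        assert watson_williams(g).p_value < 0.001

    def test_low_concentration_carries_warning(self):
        rng = np.random.default_rng(10)
        g = [CircularSample.from_hours(l, rng.uniform(0, 24, 20)) for l in "ab"]
        res = watson_williams(g)
        assert res.warnings and "unreliable" in res.warnings[0]


class TestCascade:
    @staticmethod
    def planted(seed, shift=3.0):
        groups = [("c0", 30, 10.0 + shift, 4.0)] + [
            (f"c{i}", 30, 10.0, 4.0) for i in range(1, 6)
        ]
        return simulate_phase_cascade(groups, seed=seed)

    def test_shifted_category_flagged(self):
        df = self.planted(seed=2)
        res = cascade_test(df["peak_time"], df["group"], seed=0)
        assert res.loc["c0", "flagged"]
        assert res["flagged"].sum() <= 2

    def test_null_cascade_rarely_flags(self):
        flags = []
        for seed in range(20):
            df = self.planted(seed=seed, shift=0.0)
            res = cascade_test(df["peak_time"], df["group"], seed=seed)
            flags.append(int(res["flagged"].sum()))
        # BH at 0.05 across six categories: false flags should be rare
        assert np.mean(flags) < 0.5

    def test_singletons_reported_untested(self):
        df = self.planted(seed=1)
        extra = df.iloc[:1].copy()
        extra["group"] = "lonely"
        import pandas as pd

        df2 = pd.concat([df, extra], ignore_index=True)
        res = cascade_test(df2["peak_time"], df2["group"], seed=0)
        assert np.isnan(res.loc["lonely", "p"]) and not res.loc["lonely", "flagged"]

    def test_taxon_homogeneity_detects_divergent_lineage(self):
        import pandas as pd

        rows = []
        for tx, mean in (("diatom", 10.0), ("haptophyte", 10.0), ("cyano", 16.0)):
            df = simulate_phase_cascade([("psii", 15, mean, 12.0)], seed=hash(tx) % 2**31)
            df["taxon"] = tx
            rows.append(df)
        allrows = pd.concat(rows, ignore_index=True)
        res = category_taxon_homogeneity(
            allrows["peak_time"], allrows["group"], allrows["taxon"]
        )
        assert res.loc["psii", "p"] < 0.01
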