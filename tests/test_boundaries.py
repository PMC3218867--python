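
import numpy as np
import pytest

from scnascan import boundaries as bd
from scnascan.scoring import ScnaScorer
from scnascan.simulate import SimScenario, simulate_profiles, _marker_set
from scnascan.peaks import peel_off
from scnascan.ziggurat import classify_events, iterate_zd

from conftest import event_frame, profile_set


def contrib_from_intervals(intervals, n, amp=1.0):
    """One sample per interval, constant copy amplitude over its span."""
    mat = np.zeros((len(intervals), n))
    for i, (a, b) in enumerate(intervals):
        mat[i, a:b] = amp
    return mat


class TestMcr:
    def test_single_event_full_extent(self):
        mat = contrib_from_intervals([(10, 50)], 100)
        assert bd.mcr(mat.sum(axis=0), (0, 100)) == (10, 50)

    def test_nested_events_triple_overlap(self):
        mat = contrib_from_intervals([(10, 50), (30, 70), (45, 55)], 100)
        assert bd.mcr(mat.sum(axis=0), (0, 100)) == (45, 50)

    def test_plateau_of_equal_maxima(self):
        g = np.zeros(30)
        g[12:16] = 3.0
        assert bd.mcr(g, (0, 30)) == (12, 16)


class TestLeaveKOut:
    intervals = [(10, 50), (30, 70), (45, 55)]

    def test_k0_is_mcr(self):
        mat = contrib_from_intervals(self.intervals, 100)
        assert bd.leave_k_out(mat, (0, 100), k=0) == bd.mcr(mat.sum(axis=0), (0, 100))

    def test_leave_one_out_union(self):
        mat = contrib_from_intervals(self.intervals, 100)
        assert bd.leave_k_out(mat, (0, 100), k=1) == (30, 55)

    def test_exhaustive_enumeration_oracle(self, rng):
        # brute-force over all <=1-subsets on random fixtures of <=10 events
        for _ in range(10):
            n_ev = int(rng.integers(2, 10))
            ivs = []
            for _ in range(n_ev):
                a = int(rng.integers(0, 60))
                ivs.append((a, a + int(rng.integers(5, 40))))
            mat = contrib_from_intervals(ivs, 120)
            got = bd.leave_k_out(mat, (0, 120), k=1)
            base = mat.sum(axis=0)
            extents = [bd.mcr(base, (0, 120))]
            for i in range(n_ev):
                extents.append(bd.mcr(base - mat[i], (0, 120)))
            want = (min(e[0] for e in extents), max(e[1] for e in extents))
            assert got == want

    def test_identical_events_leave_one_out_is_mcr(self):
        mat = contrib_from_intervals([(20, 40)] * 4, 60)
        assert bd.leave_k_out(mat, (0, 60), k=1) == (20, 40)

    def test_k_exceeding_contributors_errors(self):
        mat = contrib_from_intervals([(5, 10), (6, 12)], 20)
        with pytest.raises(ValueError, match="contributing"):
            bd.leave_k_out(mat, (0, 20), k=2)


class TestRangeNull:
    def test_constant_profiles_zero_percentiles(self):
        null = bd.range_null(np.zeros((4, 50)), n_permutations=25, rng=0)
        for w in (2, 5, 20, 50):
            assert null.percentile(0.9, w) == 0.0

    def test_width_one_zero(self):
        null = bd.range_null(contrib_from_intervals([(5, 15)], 40), 25, rng=0)
        assert null.percentile(0.5, 1) == 0.0

    def test_percentile_monotone_in_width(self, rng):
        mat = rng.choice([0.0, 0.0, 1.0], size=(6, 80))
        null = bd.range_null(mat, n_permutations=30, rng=1)
        for gamma in (0.5, 0.75, 0.95):
            pcts = [null.percentile(gamma, w) for w in range(2, 80, 3)]
            assert all(b >= a - 1e-12 for a, b in zip(pcts, pcts[1:]))

    def test_deterministic_given_seed(self):
        mat = contrib_from_intervals([(5, 25), (40, 60)], 80)
        a = bd.range_null(mat, 30, rng=np.random.default_rng(7))
        b = bd.range_null(mat, 30, rng=np.random.default_rng(7))
        assert np.allclose(a.sorted_, b.sorted_)

    def test_small_ensemble_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            bd.range_null(np.zeros((2, 10)), n_permutations=5, rng=0)


class TestRegBounder:
    def test_degenerate_null_returns_mcr(self):
        g = np.zeros(40)
        g[20] = 5.0
        null = bd.RangeNull(np.zeros((30, 41)))
        assert bd.regbounder_interval(g, (0, 40), 0.75, null) == (20, 21)

    def test_interval_contains_mcr_and_nests_in_gamma(self, rng):
        for trial in range(5):
            ivs = [(int(a), int(a) + int(rng.integers(5, 30)))
                   for a in rng.integers(0, 70, size=8)]
            mat = contrib_from_intervals(ivs, 100)
            g = mat.sum(axis=0)
            null = bd.range_null(mat, 40, rng=trial)
            region = (0, 100)
            m = bd.mcr(g, region)
            prev = None
            for gamma in (0.5, 0.75, 0.95):
                iv = bd.regbounder_interval(g, region, gamma, null)
                assert iv[0] <= m[0] and iv[1] >= m[1]
                if prev is not None:
                    assert iv[0] <= prev[0] and iv[1] >= prev[1]
                prev = iv

    def test_calibration_on_simulated_drivers(self):
        # target capture stays at or above the confidence level
        sc = SimScenario(n_samples=200, n_markers=600, primary_target=(300, 303),
                        primary_freq=0.06, secondary_freq=0.0)
        mk = _marker_set(sc)
        caps = {0.5: 0, 0.75: 0}
        found = 0
        for rep in range(15):
            prof, _, _ = simulate_profiles(sc, np.random.default_rng(40 + rep), mk)
            events, _, _, _ = iterate_zd(prof, max_rounds=0)
            events = classify_events(events)
            scorer = ScnaScorer().fit(events, prof)
            pks = peel_off(scorer, events, prof, "amp", "standard")
            near = [r for r in pks.itertuples(index=False)
                    if abs((r.peak_start + r.peak_end) / 2 - 301) < 100]
            if not near:
                continue
            found += 1
            r = near[0]
            rb = bd.RegBounder(n_permutations=40, seed=rep).fit(scorer)
            for gamma in caps:
                lo, hi = rb.interval("amp", "1", (r.region_start, r.region_end), gamma)
                caps[gamma] += int(lo <= 300 and hi >= 303)
        assert found >= 8
        for gamma, c in caps.items():
            assert c / found >= gamma


class TestTheoreticalMinSize:
    def test_target_always_inside_mcr(self):
        mcrs = [(10, 20)] * 60
        targets = [(12, 15)] * 60
        assert bd.theoretical_min_size(mcrs, targets, 0.9) == 10.0

    def test_two_point_displacement_closed_form(self):
        # target sits d markers beyond the left or right MCR edge, equally
        # often: at full confidence the minimal size is MCR + 2d
        d = 7
        mcrs = [(50, 60)] * 100
        targets = [(50 - d, 50 - d + 1)] * 50 + [(60 + d - 1, 60 + d)] * 50
        got = bd.theoretical_min_size(mcrs, targets, 0.999)
        assert np.isclose(got, 10 + 2 * d)
        # at 50% confidence one side suffices
        got50 = bd.theoretical_min_size(mcrs, targets, 0.5)
        assert np.isclose(got50, 10 + d)

    def test_monotone_in_gamma(self, rng):
        mcrs = [(30, 32)] * 80
        targets = [(30 + int(rng.normal(0, 5)), 31 + int(rng.normal(0, 5)))
                   for _ in range(80)]
        sizes = [bd.theoretical_min_size(mcrs, targets, gam)
                 for gam in (0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes)

    def test_small_ensemble_errors(self):
        with pytest.raises(ValueError, match="50"):
            bd.theoretical_min_size([(0, 1)] * 10, [(0, 1)] * 10, 0.5)


def test_expected_split_half_overlap():
    # two independent 75% regions both contain the target 56% of the time
    assert np.isclose(bd.expected_split_half_overlap(0.75), 0.5625)
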