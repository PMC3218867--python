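import numpy as np
import pytest
from scipy import stats

from scnascan import ziggurat as zg

from conftest import profile_set


def reconstruct_vector(events, final, n):
    v = np.full(n, final, dtype=float)
    for s, e, a in events:
        v[s:e] += a
    return v


class TestInitialDeconstruction:
    def test_flat_vector_no_events(self):
        ev, basal = zg.initial_deconstruction(np.zeros(4))
        assert ev == [] and basal == 0.0

    def test_single_elevated_run(self):
        ev, basal = zg.initial_deconstruction(np.array([0, 0, 1.0, 1.0, 0]))
        assert ev == [(2, 4, 1.0)] and basal == 0.0

    def test_staircase_peels_nested_events(self):
        ev, basal = zg.initial_deconstruction(np.array([0, 1.0, 2.0, 1.0, 0]))
        assert basal == 0.0
        assert (2, 3, 1.0) in ev and (1, 4, 1.0) in ev and len(ev) == 2

    def test_identity_on_random_profiles(self, rng):
        # 1,000 random piecewise profiles reconstruct exactly
        for _ in range(1000):
            n = int(rng.integers(4, 40))
            v = np.zeros(n)
            for _ in range(rng.integers(0, 6)):
                a, b = sorted(rng.integers(0, n, size=2))
                v[a:b + 1] += rng.choice([-1.0, -0.5, 0.5, 1.0])
            ev, basal = zg.initial_deconstruction(v)
            assert np.allclose(reconstruct_vector(ev, basal, n), v, atol=1e-9)


def uniform_bg():
    return zg.BackgroundModel()


class TestBasalLevels:
    def test_all_zero_chromosome(self):
        b_amp, b_del, ev, final, ll = zg.fit_basal_levels(np.zeros(6), uniform_bg())
        assert b_amp == b_del == 0.0 and ev == []

    def test_even_split_breaks_tie_toward_zero(self):
        v = np.array([1.0, 1.0, 0.0, 0.0])
        b_amp, b_del, ev, final, ll = zg.fit_basal_levels(v, uniform_bg())
        assert b_amp == b_del == 0.0
        assert len(ev) == 1 and ev[0][2] == 1.0

    def test_brute_force_over_candidate_levels(self):
        # 60% of markers at +1, 40% at -1: best basal maximizes total logP;
        # under a uniform background both single-level choices emit one
        # event of equal probability, so coverage breaks the tie (+1 wins)
        v = np.array([1.0] * 6 + [-1.0] * 4)
        bg = uniform_bg()
        b_amp, b_del, ev, final, ll = zg.fit_basal_levels(v, bg)

        def loglik_for(b):
            evs, fin, l = zg.deconstruct(v, bg, (b, b))
            return l

        best_level = max([1.0, -1.0], key=loglik_for)
        assert b_amp == b_del == best_level == 1.0
        assert np.allclose(reconstruct_vector(ev, final, 10), v)


class TestDeconstruct:
    def test_whole_chromosome_event(self):
        ev, final, ll = zg.deconstruct(np.full(8, 0.5), uniform_bg(), (0.0, 0.0))
        assert ev == [(0, 8, 0.5)] and final == 0.0

    def test_profile_at_basal_empty(self):
        ev, final, ll = zg.deconstruct(np.full(5, 0.2), uniform_bg(), (0.2, 0.2))
        assert ev == []

    def test_stacked_split_when_background_favors_low_amplitudes(self):
        bg = zg.BackgroundModel()
        # drown the background in low-amplitude events so P(+1) >> P(+2)
        bg.add_events(np.full(500, 0.4), np.full(500, 1.0), np.array(["amp"] * 500))
        v = np.array([0, 0, 2.0, 2.0, 0])
        ev, final, ll = zg.deconstruct(v, bg, (0.0, 0.0), max_stack=3)
        assert 2 * bg.log_prob_scalar(0.4, 1.0) > bg.log_prob_scalar(0.4, 2.0)
        assert len(ev) == 2
        assert all(e[:2] == (2, 4) for e in ev)
        assert np.isclose(sum(e[2] for e in ev), 2.0)
        assert np.allclose(reconstruct_vector(ev, final, 5), v)

    def test_single_step_kept_when_background_is_flat(self):
        ev, final, ll = zg.deconstruct(np.array([0, 2.0, 0.0]), uniform_bg(), (0.0, 0.0))
        assert ev == [(1, 2, 2.0)]


class TestBackgroundModel:
    def test_single_event_maximal_bin(self):
        ev = zg.pd.DataFrame if False else None
        from conftest import event_frame
        cat = event_frame([("S1", "1", 0, 5, 0.5, 0.3, "focal", "amp")])
        bg = zg.estimate_background(cat)
        f = bg.freq_["amp"]
        assert np.isclose(f.sum() + bg.freq_["del"].sum(), 2.0)
        li, ai = bg._bins(0.3, 0.5)
        assert f[li, ai] == f.max()

    def test_frequencies_not_counts(self):
        # the model is a frequency distribution: duplicating the catalog
        # leaves the (unsmoothed) frequencies unchanged
        from conftest import event_frame
        one = zg.estimate_background(event_frame([("S1", "1", 0, 5, 0.5, 0.3)]))
        two = zg.estimate_background(event_frame(
            [("S1", "1", 0, 5, 0.5, 0.3), ("S2", "1", 0, 5, 0.5, 0.3)]))
        assert np.allclose(one.counts_["amp"] / one.counts_["amp"].sum(),
                           two.counts_["amp"] / two.counts_["amp"].sum())

    def test_empty_catalog_uniform_with_warning(self):
        from conftest import event_frame
        with pytest.warns(UserWarning, match="uniform"):
            bg = zg.estimate_background(event_frame([]))
        assert np.allclose(bg.freq_["amp"], bg.freq_["amp"][0, 0])

    def test_recovers_generating_distribution(self, rng):
        # draw (length, amplitude) pairs from a known discrete mixture and
        # check the raw histogram counts by chi-square goodness of fit
        from conftest import event_frame
        cells = [(0.1, 0.2), (0.3, 0.6), (0.7, 1.2)]
        probs = [0.5, 0.3, 0.2]
        n = 10_000
        picks = rng.choice(3, size=n, p=probs)
        rows = [("S", "1", 0, 5, cells[k][1], cells[k][0], "focal", "amp")
                for k in picks]
        bg = zg.estimate_background(event_frame(rows))
        observed = []
        for frac, amp in cells:
            li, ai = bg._bins(frac, amp)
            observed.append(bg.counts_["amp"][li, ai])
        assert sum(observed) == n
        p = stats.chisquare(observed, np.array(probs) * n).pvalue
        assert p > 0.01

    def test_log_prob_always_finite(self):
        bg = uniform_bg()
        q = bg.log_prob(np.array([0.0, 0.5, 1.0]), np.array([1e-9, 0.5, 99.0]), "del")
        assert np.all(np.isfinite(q))


class TestIterateZd:
    def test_flat_cohort_converges_immediately(self):
        prof = profile_set(np.zeros((3, 10)))
        with pytest.warns(UserWarning, match="uniform"):
            events, bg, basal, trace = zg.iterate_zd(prof)
        assert len(events) == 0

    def test_single_event_cohort_fixed_point(self):
        mat = np.zeros((4, 20))
        mat[:, 5:10] = 1.0
        prof = profile_set(mat)
        events, bg, basal, trace = zg.iterate_zd(prof)
        assert len(events) == 4
        assert set(zip(events["start"], events["end"])) == {(5, 10)}
        assert len(trace) <= 2 or np.isclose(trace[-1], trace[0])

    def test_loglik_trace_monotone_on_stacked_cohort(self, rng):
        mat = np.zeros((12, 50))
        for i in range(12):
            a = int(rng.integers(0, 25))
            mat[i, a:a + 10] += 1.0
            mat[i, a + 3:a + 7] += 1.0
        events, bg, basal, trace = zg.iterate_zd(profile_set(mat), max_rounds=5)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_reconstruction_identity_through_estimator(self, rng):
        mat = np.zeros((6, 40))
        for i in range(6):
            for _ in range(3):
                a, b = sorted(rng.integers(0, 40, size=2))
                mat[i, a:b + 1] += rng.choice([-0.8, 0.6, 1.2])
        prof = profile_set(mat)
        est = zg.ZigguratDeconstructor().fit(prof)
        rec = zg.reconstruct(est.events_, prof, include_basal=est.basal_levels_)
        assert np.allclose(rec.data["1"], mat, atol=1e-9)


class TestClassifyAndReconstruct:
    @pytest.mark.parametrize("frac,expected", [
        (0.99, "arm_level"),
        (0.50, "focal"),
        (0.98, "arm_level"),  # boundary assigned to the arm class
    ])
    def test_length_cutoff(self, frac, expected):
        from conftest import event_frame
        ev = zg.classify_events(event_frame([("S", "1", 0, 5, 1.0, frac)]))
        assert ev.iloc[0]["klass"] == expected

    def test_monotone_in_arm_fraction(self, rng):
        from conftest import event_frame
        fracs = np.sort(rng.uniform(0, 1, size=50))
        ev = zg.classify_events(event_frame(
            [("S", "1", 0, 5, 1.0, f) for f in fracs]))
        klass = (ev["klass"] == "arm_level").to_numpy()
        assert np.all(np.diff(klass.astype(int)) >= 0)

    def test_focal_plus_arm_equals_all(self, rng):
        from conftest import event_frame
        rows = []
        for i in range(8):
            rows.append((f"S{i}", "1", int(rng.integers(0, 10)), int(rng.integers(10, 20)),
                         float(rng.choice([-1, 0.5, 1])), float(rng.uniform(0, 1))))
        ev = zg.classify_events(zg.pd.DataFrame(
            [(s, c, a, b, m, f, "focal", "amp" if m > 0 else "del")
             for s, c, a, b, m, f in rows], columns=zg.EVENT_COLUMNS))
        prof = profile_set(np.zeros((8, 20)))
        full = zg.reconstruct(ev, prof)
        focal = zg.reconstruct(ev, prof, klass="focal")
        arm = zg.reconstruct(ev, prof, klass="arm_level")
        assert np.allclose(full.data["1"], focal.data["1"] + arm.data["1"])

    def test_arm_only_catalog_focal_reconstruction_flat(self):
        from conftest import event_frame
        ev = zg.classify_events(event_frame([("S0", "1", 0, 20, 1.0, 1.0)]))
        prof = profile_set(np.zeros((1, 20)))
        assert np.allclose(zg.reconstruct(ev, prof, klass="focal").data["1"], 0.0)
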