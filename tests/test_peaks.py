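import numpy as np
import pandas as pd
import pytest

from scnascan import peaks as pk
from scnascan.scoring import ScnaScorer
from scnascan.simulate import scenario_secondary, simulate_profiles, _marker_set
from scnascan.ziggurat import classify_events, iterate_zd

from conftest import event_frame, profile_set


class TestSignificantRegions:
    def test_nothing_significant(self):
        assert pk.significant_regions({"1": np.ones(5)}) == []

    def test_single_run(self):
        q = np.ones(30)
        q[10:21] = 0.1
        assert pk.significant_regions({"1": q}) == [("1", 10, 21)]

    def test_runs_split_by_gap(self):
        q = np.ones(10)
        q[2:4] = 0.05
        q[5:7] = 0.05
        assert pk.significant_regions({"1": q}) == [("1", 2, 4), ("1", 5, 7)]


def arbitration_fixture(seed=1, n_pri=12, n_span=10, n_sec=8, n_sam=60, n_mark=200):
    """Primary driver [50,60); secondary [150,160) with a spanning subset;
    a per-sample noise event fattens the permutation null."""
    rows = []
    si = 0
    for _ in range(n_pri):
        rows.append((f"S{si}", "1", 50, 60, 1.0)); si += 1
    for _ in range(n_span):
        rows.append((f"S{si}", "1", 50, 160, 1.0)); si += 1
    for _ in range(n_sec):
        rows.append((f"S{si}", "1", 150, 160, 1.0)); si += 1
    rng = np.random.default_rng(seed)
    for s in range(n_sam):
        st = int(rng.integers(0, n_mark - 10))
        rows.append((f"S{s}", "1", st, st + 10, 1.0))
    ev = event_frame(rows)
    prof = profile_set(np.zeros((n_sam, n_mark)))
    return ev, prof


def hits(df, lo, hi):
    return any(r.peak_start < hi and r.peak_end > lo for r in df.itertuples(index=False))


class TestStandardPeelOff:
    def test_single_driver_single_peak(self):
        ev = event_frame([(f"S{i}", "1", 10, 20, 1.0) for i in range(8)])
        prof = profile_set(np.zeros((8, 50)))
        scorer = ScnaScorer().fit(ev, prof)
        peaks = pk.peel_off(scorer, ev, prof, "amp", "standard")
        assert len(peaks) == 1
        assert peaks.iloc[0]["peak_start"] >= 10 and peaks.iloc[0]["peak_end"] <= 20

    def test_disjoint_drivers_two_peaks_by_score(self):
        rows = [(f"S{i}", "1", 10, 20, 1.0) for i in range(10)]
        rows += [(f"T{i}", "1", 60, 70, 1.0) for i in range(6)]
        ev = event_frame(rows)
        prof = pk.CopyProfileSet(
            [r[0] for r in rows], profile_set(np.zeros((1, 100))).markers,
            {"1": np.zeros((16, 100))})
        scorer = ScnaScorer().fit(ev, prof)
        peaks = pk.peel_off(scorer, ev, prof, "amp", "standard")
        assert len(peaks) == 2
        assert peaks.iloc[0]["gmax"] > peaks.iloc[1]["gmax"]
        assert hits(peaks.iloc[:1], 10, 20) and hits(peaks.iloc[1:], 60, 70)

    def test_fully_dependent_secondary_lost(self):
        # every secondary event also spans the primary: after peel-off of
        # the primary nothing remains at the secondary locus
        rows = [(f"S{i}", "1", 10, 20, 1.0) for i in range(10)]
        rows += [(f"T{i}", "1", 10, 50, 1.0) for i in range(5)]
        ev = event_frame(rows)
        prof = pk.CopyProfileSet(
            [r[0] for r in rows], profile_set(np.zeros((1, 80))).markers,
            {"1": np.zeros((15, 80))})
        scorer = ScnaScorer().fit(ev, prof)
        peaks = pk.peel_off(scorer, ev, prof, "amp", "standard")
        assert len(peaks) == 1


class TestArbitratedPeelOff:
    def test_partial_overlap_recovered_only_by_arbitration(self):
        ev, prof = arbitration_fixture()
        scorer = ScnaScorer().fit(ev, prof)
        std = pk.peel_off(scorer, ev, prof, "amp", "standard")
        arb = pk.peel_off(scorer, ev, prof, "amp", "arbitrated")
        assert hits(std, 50, 60) and hits(arb, 50, 60)
        assert not hits(std, 140, 170)
        assert hits(arb, 140, 170)

    def test_share_conservation(self):
        ev, prof = arbitration_fixture()
        scorer = ScnaScorer().fit(ev, prof)
        arb = pk.peel_off(scorer, ev, prof, "amp", "arbitrated")
        totals = {}
        for r in arb.itertuples(index=False):
            for e, f in zip(r.event_ids, r.shares):
                totals[e] = totals.get(e, 0.0) + f
        assert totals and all(f <= 1.0 + 1e-9 for f in totals.values())
        # events split across peaks still sum to their full weight
        multi = [e for r in arb.itertuples(index=False) for e in r.event_ids]
        dup = {e for e in multi if multi.count(e) > 1}
        for e in dup:
            assert np.isclose(totals[e], 1.0)

    def test_no_overlap_event_keeps_full_share(self):
        ev = event_frame([(f"S{i}", "1", 5, 15, 1.0) for i in range(8)])
        prof = profile_set(np.zeros((8, 40)))
        scorer = ScnaScorer().fit(ev, prof)
        arb = pk.peel_off(scorer, ev, prof, "amp", "arbitrated")
        assert len(arb) == 1
        assert np.allclose(arb.iloc[0]["shares"], 1.0)

    @pytest.mark.parametrize("rep", range(3))
    def test_equivalent_to_standard_without_overlap(self, rep):
        sc = scenario_secondary(0.0, n_samples=120)
        mk = _marker_set(sc)
        prof, _, _ = simulate_profiles(sc, np.random.default_rng(900 + rep), mk)
        events, _, _, _ = iterate_zd(prof, max_rounds=0)
        events = classify_events(events)
        scorer = ScnaScorer().fit(events, prof)
        std = pk.peel_off(scorer, events, prof, "amp", "standard")
        arb = pk.peel_off(scorer, events, prof, "amp", "arbitrated")
        # peak locations always agree at 0% driver overlap
        cols = ["chrom", "peak_start", "peak_end"]
        pd.testing.assert_frame_equal(std[cols].reset_index(drop=True),
                                      arb[cols].reset_index(drop=True))
        # ... and the whole tables agree when no event (not even a long
        # passenger) covers two peak maxima, the stated condition
        maxima = [(r.chrom, r.peak_start) for r in std.itertuples(index=False)]
        focal = events[(events["klass"] == "focal") & (events["direction"] == "amp")]
        n_covered = focal.apply(
            lambda e: sum(e["start"] <= m < e["end"]
                          for c, m in maxima if c == e["chrom"]), axis=1)
        if (n_covered <= 1).all():
            pd.testing.assert_frame_equal(
                std[cols + ["gmax", "q"]].reset_index(drop=True),
                arb[cols + ["gmax", "q"]].reset_index(drop=True))


class TestEvaluateRecovery:
    def peaks_df(self, intervals):
        return pd.DataFrame(
            [("amp", "1", s, e, s, e, 1.0, 0.01, i, 0, None, None)
             for i, (s, e) in enumerate(intervals)], columns=pk.PEAK_COLUMNS)

    def test_peak_on_secondary_only_independent(self):
        rec = pk.evaluate_recovery(self.peaks_df([(600, 605)]), (400, 405), (600, 605))
        assert rec["secondary_independent"] and not rec["secondary_dependent"]

    def test_wide_peak_covering_both_dependent(self):
        rec = pk.evaluate_recovery(self.peaks_df([(380, 620)]), (400, 405), (600, 605))
        assert rec["secondary_dependent"] and not rec["secondary_independent"]

    def test_no_peak_on_secondary(self):
        rec = pk.evaluate_recovery(self.peaks_df([(400, 406)]), (400, 405), (600, 605))
        assert rec["primary_found"]
        assert not rec["secondary_independent"] and not rec["secondary_dependent"]
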