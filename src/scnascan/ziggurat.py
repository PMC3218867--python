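"""Ziggurat deconstruction of segmented copy-number profiles.

A segmented profile is the per-marker sum of the individual somatic
copy-number alterations (SCNAs) that produced it.  Because events overlap
and stack, the underlying set is not directly observable; this module
recovers the most likely set by iterative optimization:

1. seed a catalog by peeling each chromosome to flatness, always merging
   the segment whose level is closest to a neighbour;
2. estimate a background model — the joint (length-fraction, |amplitude|)
   frequency distribution of events — from the pooled catalog;
3. re-deconstruct every chromosome against up to two fitted basal levels,
   choosing merges (and stacked-event splits) that maximize the summed
   background log-probability of the emitted events;
4. alternate 2 and 3 until the total log-likelihood stabilizes.

The emitted events of a chromosome always sum, marker by marker, to the
input vector minus the final basal level (the reconstruction identity),
and events are classified focal vs arm-level by the fraction of their
containing arm they cover (arm-level at >= 98% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ArmTable, CopyProfileSet, MarkerSet

__all__ = [
    "BackgroundModel",
    "ArmIndex",
    "ZigguratDeconstructor",
    "initial_deconstruction",
    "fit_basal_levels",
    "deconstruct",
    "estimate_background",
    "iterate_zd",
    "classify_events",
    "reconstruct",
]

_EPS = 1e-9  # amplitude below which a step is numerical dust, not an event

EVENT_COLUMNS = ["sample", "chrom", "start", "end", "amp", "arm_fraction", "klass", "direction"]


@dataclass
class ArmIndex:
    """Per-chromosome arm assignment: marker -> arm id, and arm sizes."""

    arm_id: np.ndarray
    arm_counts: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.arm_id)

    def arm_fraction(self, start: int, end: int) -> float:
        """Event length as a fraction of its containing arm's marker count;
        centromere-spanning events use the whole-chromosome count."""
        a0, a1 = self.arm_id[start], self.arm_id[end - 1]
        denom = self.arm_counts[a0] if a0 == a1 else self.n_markers
        return min((end - start) / denom, 1.0)

    @classmethod
    def build(cls, markers: MarkerSet, arms: ArmTable | None) -> dict[str, "ArmIndex"]:
        out = {}
        for chrom in markers.chromosomes:
            if arms is None:
                n = markers.n_markers(chrom)
                out[chrom] = cls(np.zeros(n, dtype=np.intp), np.array([n]))
            else:
                out[chrom] = cls(*arms.marker_arms(markers, chrom))
        return out


class BackgroundModel:
    """Smoothed joint frequency of passenger SCNAs over (length, amplitude).

    One 2-D histogram per direction: ``n_length_bins`` linear bins of
    arm-fraction over (0, 1] by ``n_amp_bins`` log-spaced bins of |log2
    amplitude| over (0, ``amp_max``]; out-of-range amplitudes clip into the
    edge bins.  Additive smoothing (``pseudocount`` per bin) keeps every
    log-probability finite.
    """

    def __init__(self, n_length_bins: int = 25, n_amp_bins: int = 25,
                 amp_max: float = 1.5, pseudocount: float = 1.0):
        self.n_length_bins = n_length_bins
        self.n_amp_bins = n_amp_bins
        self.amp_max = amp_max
        self.pseudocount = pseudocount
        self._len_edges = np.linspace(0.0, 1.0, n_length_bins + 1)
        self._amp_edges = np.geomspace(amp_max / 1000.0, amp_max, n_amp_bins + 1)
        self.counts_ = {d: np.zeros((n_length_bins, n_amp_bins)) for d in ("amp", "del")}
        self._refresh()

    def _refresh(self):
        self.freq_, self._logp = {}, {}
        b = self.n_length_bins * self.n_amp_bins
        for d, c in self.counts_.items():
            f = (c + self.pseudocount) / (c.sum() + self.pseudocount * b)
            self.freq_[d] = f
            self._logp[d] = np.log(f)

    def _bins(self, length_fraction, amplitude):
        li = np.clip(np.searchsorted(self._len_edges, length_fraction, "left") - 1,
                     0, self.n_length_bins - 1)
        ai = np.clip(np.searchsorted(self._amp_edges, np.abs(amplitude), "left") - 1,
                     0, self.n_amp_bins - 1)
        return li, ai

    def add_events(self, length_fraction, amplitude, direction) -> None:
        length_fraction = np.atleast_1d(length_fraction)
        amplitude = np.atleast_1d(amplitude)
        direction = np.atleast_1d(direction)
        li, ai = self._bins(length_fraction, amplitude)
        for d in ("amp", "del"):
            sel = direction == d
            np.add.at(self.counts_[d], (li[sel], ai[sel]), 1.0)
        self._refresh()

    def log_prob(self, length_fraction, amplitude, direction: str):
        """log P(event) for events of one direction; finite for every
        in-range query by construction."""
        li, ai = self._bins(length_fraction, amplitude)
        return self._logp[direction][li, ai]

    def log_prob_scalar(self, length_fraction: float, amplitude: float) -> float:
        d = "amp" if amplitude > 0 else "del"
        li, ai = self._bins(length_fraction, abs(amplitude))
        return float(self._logp[d][li, ai])


# ---------------------------------------------------------------------------
# the peel engine

def _rle(v: np.ndarray) -> list[list]:
    """Run-length encode into mutable [start, end, level] triples."""
    edges = np.flatnonzero(np.diff(v) != 0) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(v)]])
    return [[int(s), int(e), float(v[s])] for s, e in zip(starts, ends)]


def _split_amp(amp: float, frac: float, bg: BackgroundModel | None, max_stack: int):
    """Split one step of amplitude ``amp`` into up to ``max_stack`` stacked
    events of equal amplitude when the background favours it; returns the
    list of exact-sum parts and the total log-probability."""
    if bg is None:
        return [amp], 0.0
    best_j, best_ll = 1, bg.log_prob_scalar(frac, amp)
    for j in range(2, max_stack + 1):
        ll = j * bg.log_prob_scalar(frac, amp / j)
        if ll > best_ll + 1e-12:
            best_j, best_ll = j, ll
    if best_j == 1:
        return [amp], best_ll
    part = amp / best_j
    parts = [part] * (best_j - 1)
    parts.append(amp - part * (best_j - 1))  # exact-sum remainder
    return parts, best_ll


def _band_dist(level: float, lo: float, hi: float) -> float:
    return max(level - hi, lo - level, 0.0)


def _peel(segs: list[list], b_lo: float, b_hi: float,
          bg: BackgroundModel | None, armf, max_stack: int = 1):
    """Peel a segment sequence to a single flat level, emitting events.

    Each iteration merges one segment into a neighbour, emitting an event
    spanning the merged segment with amplitude equal to the level step.
    Merge choice: maximize emitted-event log-probability under ``bg`` (or
    minimize |amplitude| when ``bg`` is None), preferring merges that move
    toward the basal band, then peeling the level farthest from the band,
    then leftmost.  Terminates in at most ``len(segs) - 1`` merges; a final
    closing event brings the remaining flat level to the nearest basal.

    Returns ``(events, final_level, loglik)`` with events as
    ``(start, end, amplitude)`` triples that sum per marker to the input
    minus ``final_level``.
    """
    events: list[tuple[int, int, float]] = []
    loglik = 0.0
    segs = [list(s) for s in segs]
    while len(segs) > 1:
        dists = [max(s[2] - b_hi, b_lo - s[2], 0.0) for s in segs]
        peelable = [k for k, dv in enumerate(dists) if dv > _EPS]
        if not peelable:
            peelable = range(len(segs))
        best = None
        for k in peelable:
            dk = dists[k]
            for j in (k - 1, k + 1):
                if not 0 <= j < len(segs):
                    continue
                amp = segs[k][2] - segs[j][2]
                if abs(amp) < _EPS:
                    continue
                if bg is None:
                    score, parts, ll = -abs(amp), None, 0.0
                else:
                    frac = armf(segs[k][0], segs[k][1])
                    parts, ll = _split_amp(amp, frac, bg, max_stack)
                    score = round(ll, 12)
                key = (score, dists[j] < dk - _EPS, dk, -k, j < k)
                if best is None or key > best[0]:
                    best = (key, k, j, parts, ll, amp)
        if best is None:  # all steps below dust threshold: fuse silently
            segs[0][1] = segs[-1][1]
            del segs[1:]
            break
        _, k, j, parts, ll, amp = best
        if parts is None:
            parts = [amp]
        s, e = segs[k][0], segs[k][1]
        for p in parts:
            events.append((s, e, p))
        loglik += ll if bg is not None else 0.0
        segs[k][2] = segs[j][2]
        # fuse equal-level neighbours
        m = 0
        while m < len(segs) - 1:
            if segs[m][2] == segs[m + 1][2]:
                segs[m][1] = segs[m + 1][1]
                del segs[m + 1]
            else:
                m += 1
    final = segs[0][2]
    if _band_dist(final, b_lo, b_hi) > _EPS:
        target = b_hi if final > b_hi else b_lo
        amp = final - target
        frac = armf(segs[0][0], segs[0][1])
        parts, ll = _split_amp(amp, frac, bg, max_stack)
        for p in parts:
            events.append((segs[0][0], segs[0][1], p))
        loglik += ll if bg is not None else 0.0
        final = target
    return events, final, loglik


def _initial_core(v, eps):  # pragma: no cover - exercised via initial_deconstruction
    n = len(v)
    # run-length encode
    starts = np.empty(n, np.int64)
    ends = np.empty(n, np.int64)
    levels = np.empty(n, np.float64)
    nseg = 0
    i = 0
    while i < n:
        j = i + 1
        while j < n and v[j] == v[i]:
            j += 1
        starts[nseg] = i
        ends[nseg] = j
        levels[nseg] = v[i]
        nseg += 1
        i = j
    # reference level: most markers, ties toward the level nearest zero
    ref = levels[0]
    best_cov = -1
    for k in range(nseg):
        cov = 0
        for k2 in range(nseg):
            if levels[k2] == levels[k]:
                cov += ends[k2] - starts[k2]
        if cov > best_cov or (cov == best_cov and abs(levels[k]) < abs(ref)):
            ref = levels[k]
            best_cov = cov
    ev_s = np.empty(2 * n, np.int64)
    ev_e = np.empty(2 * n, np.int64)
    ev_a = np.empty(2 * n, np.float64)
    nev = 0
    while nseg > 1:
        bk = -1
        bj = -1
        b_score = 0.0
        b_tow = False
        b_dist = 0.0
        any_peelable = False
        for k in range(nseg):
            if abs(levels[k] - ref) > eps:
                any_peelable = True
                break
        for k in range(nseg):
            dk = abs(levels[k] - ref)
            if any_peelable and dk <= eps:
                continue
            for j in (k - 1, k + 1):
                if j < 0 or j >= nseg:
                    continue
                amp = levels[k] - levels[j]
                if abs(amp) < eps:
                    continue
                score = -abs(amp)
                tow = abs(levels[j] - ref) < dk - eps
                left = j < k
                take = False
                if bk < 0:
                    take = True
                elif score != b_score:
                    take = score > b_score
                elif tow != b_tow:
                    take = tow
                elif dk != b_dist:
                    take = dk > b_dist
                elif k != bk:
                    take = k < bk
                else:
                    take = left
                if take:
                    bk, bj, b_score, b_tow, b_dist = k, j, score, tow, dk
        if bk < 0:
            ends[0] = ends[nseg - 1]
            nseg = 1
            break
        ev_s[nev] = starts[bk]
        ev_e[nev] = ends[bk]
        ev_a[nev] = levels[bk] - levels[bj]
        nev += 1
        levels[bk] = levels[bj]
        # fuse equal-level neighbours
        m = 0
        for k in range(1, nseg):
            if levels[k] == levels[m]:
                ends[m] = ends[k]
            else:
                m += 1
                starts[m] = starts[k]
                ends[m] = ends[k]
                levels[m] = levels[k]
        nseg = m + 1
    if abs(levels[0] - ref) > eps:
        ev_s[nev] = starts[0]
        ev_e[nev] = ends[0]
        ev_a[nev] = levels[0] - ref
        nev += 1
    return ev_s[:nev], ev_e[:nev], ev_a[:nev], ref


try:  # optional acceleration for the cohort-scale seed round
    from numba import njit

    _initial_core = njit(cache=True)(_initial_core)
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _reference_level(segs) -> float:
    """Marker-weighted modal level; ties toward the level nearest zero."""
    cov: dict[float, int] = {}
    for s, e, lv in segs:
        cov[lv] = cov.get(lv, 0) + (e - s)
    return min(cov, key=lambda lv: (-cov[lv], abs(lv)))


def initial_deconstruction(v: np.ndarray, armf=None):
    """Seed deconstruction of one chromosome vector: peel each segment into
    its closest adjacent segment until flat.  Returns ``(events,
    basal_level)``; a flat input yields no events.
    """
    v = np.ascontiguousarray(v, dtype=float)
    if _HAVE_NUMBA:
        ev_s, ev_e, ev_a, ref = _initial_core(v, _EPS)
        return [(int(s), int(e), float(a)) for s, e, a in zip(ev_s, ev_e, ev_a)], float(ref)
    armf = armf or (lambda s, e: (e - s) / len(v))
    segs = _rle(v)
    ref = _reference_level(segs)
    events, final, _ = _peel(segs, ref, ref, None, armf)
    return events, final


def fit_basal_levels(v: np.ndarray, bg: BackgroundModel, armf=None,
                     max_stack: int = 3, max_candidates: int = 3):
    """Choose up to two basal levels maximizing deconstruction likelihood.

    Candidate levels are the observed segment levels (the
    ``max_candidates`` best-covered ones), evaluated singly and in
    (amp >= del) pairs.  Ties break toward the level covering the most
    markers, then toward the level nearest zero.

    Returns ``(b_amp, b_del, events, final_level, loglik)`` for the winning
    deconstruction.
    """
    armf = armf or (lambda s, e: (e - s) / len(v))
    segs = _rle(np.asarray(v, dtype=float))
    cov: dict[float, int] = {}
    for s, e, lv in segs:
        cov[lv] = cov.get(lv, 0) + (e - s)
    levels = sorted(cov, key=lambda lv: (-cov[lv], abs(lv)))[:max_candidates]
    best = None
    for b in levels:
        cands = [(b, b)]
        for b2 in levels:
            if b2 < b - _EPS:
                cands.append((b, b2))
        for b_hi, b_lo in cands:
            events, final, ll = _peel(segs, b_lo, b_hi, bg, armf, max_stack)
            covered = cov.get(b_hi, 0) + (cov.get(b_lo, 0) if b_lo != b_hi else 0)
            # ties: prefer a single basal, then most-covered, then nearest 0
            key = (round(ll, 9), b_hi == b_lo, covered, -min(abs(b_hi), abs(b_lo)))
            if best is None or key > best[0]:
                best = (key, b_hi, b_lo, events, final, ll)
    _, b_hi, b_lo, events, final, ll = best
    return b_hi, b_lo, events, final, ll


def deconstruct(v: np.ndarray, bg: BackgroundModel, basal: tuple[float, float],
                armf=None, max_stack: int = 3):
    """Deconstruct one chromosome vector against fitted basal levels,
    maximizing summed background log-probability of the emitted events.
    Returns ``(events, final_level, loglik)``.
    """
    armf = armf or (lambda s, e: (e - s) / len(v))
    b_amp, b_del = basal
    return _peel(_rle(np.asarray(v, dtype=float)), b_del, b_amp, bg, armf, max_stack)


# ---------------------------------------------------------------------------
# catalog-level operations

def _catalog_to_frame(raw: list, arm_index: dict[str, ArmIndex]) -> pd.DataFrame:
    rows = []
    for sample, chrom, events in raw:
        ai = arm_index[chrom]
        for s, e, a in events:
            rows.append((sample, chrom, s, e, a, ai.arm_fraction(s, e),
                         "focal", "amp" if a > 0 else "del"))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df


def estimate_background(events: pd.DataFrame, n_length_bins: int = 25,
                        n_amp_bins: int = 25, amp_max: float = 1.5,
                        pseudocount: float = 1.0) -> BackgroundModel:
    """Estimate the passenger background from a pooled event catalog.

    An empty catalog yields the uniform (pure-smoothing) model with a
    warning.
    """
    bg = BackgroundModel(n_length_bins, n_amp_bins, amp_max, pseudocount)
    if len(events) == 0:
        warnings.warn("empty event catalog: background model is uniform")
        return bg
    bg.add_events(events["arm_fraction"].to_numpy(),
                  events["amp"].to_numpy(),
                  events["direction"].to_numpy())
    return bg


def classify_events(events: pd.DataFrame, broad_len_cutoff: float = 0.98) -> pd.DataFrame:
    """Set ``klass``: arm-level iff arm_fraction >= cutoff, else focal."""
    if not 0 < broad_len_cutoff <= 1:
        raise ValueError("broad_len_cutoff must be in (0, 1]")
    events = events.copy()
    events["klass"] = np.where(events["arm_fraction"].to_numpy() >= broad_len_cutoff,
                               "arm_level", "focal")
    return events


def iterate_zd(profiles: CopyProfileSet, arms: ArmTable | None = None,
               max_rounds: int = 5, tol: float = 1e-4, max_stack: int = 3,
               n_length_bins: int = 25, n_amp_bins: int = 25,
               amp_max: float = 1.5, pseudocount: float = 1.0,
               broad_len_cutoff: float = 0.98):
    """Run the full iterative deconstruction over a cohort.

    Round 0 seeds the background from closest-neighbour peels; each later
    round refits basal levels and re-deconstructs every chromosome under
    the current background, then re-estimates it.  Stops when the relative
    total log-likelihood gain falls below ``tol`` or after ``max_rounds``;
    if a round ever lowers the likelihood the previous state is kept, so
    the reported trace is non-decreasing.

    Returns ``(events, background, basal_levels, loglik_trace)``.
    """
    arm_index = ArmIndex.build(profiles.markers, arms)
    raw0, basal0 = [], []
    for chrom, mat in profiles.data.items():
        armf = arm_index[chrom].arm_fraction
        for si, sample in enumerate(profiles.samples):
            ev, final = initial_deconstruction(mat[si], armf)
            raw0.append((sample, chrom, ev))
            basal0.append((sample, chrom, final, final, final))
    catalog = _catalog_to_frame(raw0, arm_index)
    bg = estimate_background(catalog, n_length_bins, n_amp_bins, amp_max, pseudocount)
    basal = basal0
    trace: list[float] = []
    for _ in range(max_rounds):
        raw, basal_new, total_ll = [], [], 0.0
        for chrom, mat in profiles.data.items():
            armf = arm_index[chrom].arm_fraction
            for si, sample in enumerate(profiles.samples):
                b_amp, b_del, ev, final, ll = fit_basal_levels(
                    mat[si], bg, armf, max_stack=max_stack)
                raw.append((sample, chrom, ev))
                basal_new.append((sample, chrom, b_amp, b_del, final))
                total_ll += ll
        if trace and total_ll < trace[-1]:
            break  # keep the previous, better state
        new_catalog = _catalog_to_frame(raw, arm_index)
        catalog, basal = new_catalog, basal_new
        converged = trace and abs(total_ll - trace[-1]) <= tol * max(abs(trace[-1]), 1.0)
        trace.append(total_ll)
        if converged:
            break
        bg = estimate_background(catalog, n_length_bins, n_amp_bins, amp_max, pseudocount)
    catalog = classify_events(catalog, broad_len_cutoff)
    basal_df = pd.DataFrame(basal, columns=["sample", "chrom", "b_amp", "b_del", "b_recon"])
    return catalog, bg, basal_df, trace


def reconstruct(events: pd.DataFrame, profiles: CopyProfileSet,
                klass: str | None = None, include_basal: pd.DataFrame | None = None) -> CopyProfileSet:
    """Per-marker sum of event amplitudes, optionally filtered by class
    (``"focal"`` / ``"arm_level"``) and offset by the fitted basal levels.

    ``reconstruct(all events) + basal`` reproduces the input profiles
    exactly (to float tolerance).
    """
    out = CopyProfileSet(
        list(profiles.samples), profiles.markers,
        {c: np.zeros_like(a) for c, a in profiles.data.items()})
    s_index = {s: i for i, s in enumerate(profiles.samples)}
    ev = events if klass is None else events[events["klass"] == klass]
    for row in ev.itertuples(index=False):
        out.data[row.chrom][s_index[row.sample], row.start:row.end] += row.amp
    if include_basal is not None:
        for row in include_basal.itertuples(index=False):
            out.data[row.chrom][s_index[row.sample]] += row.b_recon
    return out


class ZigguratDeconstructor(BaseEstimator):
    """Cohort-level ziggurat deconstruction as a scikit-learn estimator.

    Parameters mirror :func:`iterate_zd`.  After :meth:`fit`:

    ``events_`` : DataFrame
        Classified SCNA catalog (sample, chrom, marker interval, log2
        amplitude, arm fraction, focal/arm class, direction).
    ``background_`` : BackgroundModel
    ``basal_levels_`` : DataFrame (sample, chrom, b_amp, b_del, b_recon)
    ``loglik_trace_`` : list of per-round total log-likelihoods.
    """

    def __init__(self, max_rounds=5, tol=1e-4, max_stack=3, n_length_bins=25,
                 n_amp_bins=25, amp_max=1.5, pseudocount=1.0, broad_len_cutoff=0.98):
        self.max_rounds = max_rounds
        self.tol = tol
        self.max_stack = max_stack
        self.n_length_bins = n_length_bins
        self.n_amp_bins = n_amp_bins
        self.amp_max = amp_max
        self.pseudocount = pseudocount
        self.broad_len_cutoff = broad_len_cutoff

    def fit(self, profiles: CopyProfileSet, arms: ArmTable | None = None):
        if not isinstance(profiles, CopyProfileSet):
            raise TypeError("fit expects a CopyProfileSet")
        ev, bg, basal, trace = iterate_zd(
            profiles, arms, max_rounds=self.max_rounds, tol=self.tol,
            max_stack=self.max_stack, n_length_bins=self.n_length_bins,
            n_amp_bins=self.n_amp_bins, amp_max=self.amp_max,
            pseudocount=self.pseudocount, broad_len_cutoff=self.broad_len_cutoff)
        self.events_ = ev
        self.background_ = bg
        self.basal_levels_ = basal
        self.loglik_trace_ = trace
        self.n_rounds_ = len(trace)
        return self

    def transform(self, profiles: CopyProfileSet, klass: str | None = "focal") -> CopyProfileSet:
        """Reconstruct the class-filtered profiles of the fitted cohort."""
        return reconstruct(self.events_, profiles, klass=klass)
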