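"""Marker-level significance scoring of focal SCNAs.

The G-score at a marker sums, over samples, the copy-number-space amplitude
of each sample's focal alteration there (G = frequency x amplitude).  Log2
ratios are capped and converted to copy units (``c = 2 * 2**r``); amplitudes
below a low noise threshold (|log2| <= 0.1 by default) are ignored.

P-values come from the permutation null in which each sample's marker
locations are independently shuffled: the null G at a single marker is then
the sum of one draw per sample from that sample's own amplitude histogram.
That distribution is computed exactly by iterated discrete convolution of
the per-sample histograms (Monte Carlo permutation is retained as a test
oracle).  Benjamini-Hochberg correction over all markers gives q-values,
separately per direction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import CopyProfileSet

__all__ = [
    "copy_change",
    "sample_contributions",
    "NullDistribution",
    "monte_carlo_null",
    "gscore_track",
    "pvalues",
    "qvalues",
    "ScnaScorer",
]

DIRECTIONS = ("amp", "del")


def copy_change(log2_ratio, direction: str, cap_log2: float = 1.5):
    """Convert a log2 copy ratio into a copy-space amplitude.

    The ratio is first clamped to ``[-cap_log2, +cap_log2]`` (probe
    saturation), then total copies ``c = 2 * 2**r``; amplification
    amplitude is ``max(c - 2, 0)`` and deletion amplitude ``max(2 - c, 0)``.
    """
    r = np.asarray(log2_ratio, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite log2 ratio")
    if cap_log2 <= 0:
        raise ValueError("cap_log2 must be positive")
    c = 2.0 * np.exp2(np.clip(r, -cap_log2, cap_log2))
    if direction == "amp":
        out = np.maximum(c - 2.0, 0.0)
    elif direction == "del":
        out = np.maximum(2.0 - c, 0.0)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.isscalar(log2_ratio) else out


def _cc(a: np.ndarray, direction: str, cap_log2: float) -> np.ndarray:
    # copy_change without input validation (hot path)
    c = 2.0 * np.exp2(np.clip(a, -cap_log2, cap_log2))
    return np.maximum(c - 2.0, 0.0) if direction == "amp" else np.maximum(2.0 - c, 0.0)


def sample_contributions(log2_amp, direction: str, noise_threshold: float = 0.1,
                         cap_log2: float = 1.5):
    """Per-sample copy-space contribution at each marker.

    ``log2_amp`` is the sample's summed focal log2 amplitude (per
    direction); magnitudes at or below ``noise_threshold`` contribute 0.
    """
    a = np.asarray(log2_amp, dtype=float)
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    out = _cc(a, direction, cap_log2)
    out[np.abs(a) <= noise_threshold] = 0.0
    return out


class NullDistribution:
    """Exact permutation null of the single-marker G-score.

    Discrete pmf over G bins of width ``bin_width`` (copy units), built by
    convolving the per-sample amplitude histograms; mass beyond the table
    is lumped into an overflow bin that still counts toward every in-range
    tail.  ``tail(g)`` returns the inclusive right tail P(G >= g), floored
    at the smallest positive representable mass (never 0).
    """

    def __init__(self, pmf: np.ndarray, bin_width: float, overflow: float = 0.0):
        self.pmf = np.asarray(pmf, dtype=float)
        self.bin_width = float(bin_width)
        self.overflow = float(overflow)
        sf = np.cumsum(self.pmf[::-1])[::-1] + self.overflow
        self.sf = np.minimum(sf, 1.0)
        pos = self.sf[self.sf > 0]
        self.min_tail = float(pos.min()) if pos.size else np.finfo(float).tiny

    @property
    def total_mass(self) -> float:
        return float(self.pmf.sum() + self.overflow)

    def tail(self, g):
        """Inclusive right-tail probability P(G >= g)."""
        k = np.rint(np.asarray(g, dtype=float) / self.bin_width).astype(np.intp)
        k = np.clip(k, 0, len(self.pmf))
        sf_ext = np.concatenate([self.sf, [self.overflow]])
        p = np.maximum(sf_ext[k], self.min_tail)
        return float(p) if np.isscalar(g) else p

    @classmethod
    def from_sample_values(cls, per_sample_values, bin_width: float = 0.01,
                           max_bins: int = 1 << 18,
                           truncate_at: float | None = None) -> "NullDistribution":
        """Convolve per-sample amplitude histograms exactly.

        ``per_sample_values``: iterable of 1-D arrays, each the multiset of
        one sample's per-marker copy-space amplitudes.  ``truncate_at``
        caps the table just above that G value (tails at or below it stay
        exact; mass beyond moves to the overflow bin).
        """
        sparse = []
        support = 0
        for vals in per_sample_values:
            vals = np.asarray(vals, dtype=float)
            bins = np.rint(vals / bin_width).astype(np.intp)
            counts = np.bincount(bins)
            uniq = np.flatnonzero(counts)
            sparse.append((uniq, counts[uniq] / len(vals)))
            support += int(uniq[-1]) if uniq.size else 0
        n = support + 1
        if truncate_at is not None:
            n = min(n, int(np.rint(truncate_at / bin_width)) + 2)
        if n > max_bins:
            warnings.warn(
                f"null support of {n} bins exceeds table size {max_bins}; "
                "excess mass lumped into the overflow bin")
            n = max_bins
        pmf = np.zeros(n)
        pmf[0] = 1.0
        overflow = 0.0
        for uniq, probs in sparse:
            if len(uniq) == 1 and uniq[0] == 0:
                continue  # degenerate sample: convolution is the identity
            new = np.zeros(n)
            nov = overflow  # overflow mass can only stay beyond the table
            for k, p in zip(uniq, probs):
                if k == 0:
                    new += p * pmf
                elif k < n:
                    new[k:] += p * pmf[: n - k]
                    nov += p * pmf[n - k:].sum()
                else:
                    nov += p
            pmf, overflow = new, nov
        return cls(pmf, bin_width, overflow)


def monte_carlo_null(per_sample_values, n_draws: int, rng) -> np.ndarray:
    """Literal marker-permutation null (test oracle): draw one amplitude per
    sample per replicate and sum."""
    total = np.zeros(n_draws)
    for vals in per_sample_values:
        vals = np.asarray(vals, dtype=float)
        total += rng.choice(vals, size=n_draws, replace=True)
    return total


# ---------------------------------------------------------------------------
# track-level helpers

def _focal_log2_matrices(events: pd.DataFrame, profiles: CopyProfileSet,
                         klass: str | None = "focal"):
    """Per-direction, per-chromosome (n_samples x n_markers) matrices of
    summed event log2 amplitudes, built by edge-scatter + cumsum."""
    s_index = {s: i for i, s in enumerate(profiles.samples)}
    out = {}
    focal = events if klass is None else events[events["klass"] == klass]
    for d in DIRECTIONS:
        sub = focal[focal["direction"] == d]
        mats = {}
        for chrom, a in profiles.data.items():
            grp = sub[sub["chrom"] == chrom]
            if not len(grp):
                mats[chrom] = np.zeros_like(a)
                continue
            diff = np.zeros((a.shape[0], a.shape[1] + 1))
            si = grp["sample"].map(s_index).to_numpy()
            np.add.at(diff, (si, grp["start"].to_numpy()), grp["amp"].to_numpy())
            np.add.at(diff, (si, grp["end"].to_numpy()), -grp["amp"].to_numpy())
            mats[chrom] = np.cumsum(diff[:, :-1], axis=1)
        out[d] = mats
    return out


def gscore_track(events: pd.DataFrame, profiles: CopyProfileSet,
                 noise_threshold: float = 0.1, cap_log2: float = 1.5,
                 klass: str | None = "focal", noise_threshold_del: float | None = None):
    """G-score vectors per direction and chromosome from an event catalog.

    By default only focal events are scored (``klass=None`` scores all, the
    legacy low/high-amplitude modes).  ``noise_threshold_del`` allows an
    asymmetric deletion threshold (legacy high-amplitude filtering).

    Returns ``(gscore, contributions)`` where ``contributions[d][chrom]`` is
    the per-sample copy-space amplitude matrix whose column sums are the
    G-scores.
    """
    scored = events if klass is None else events[events["klass"] == klass]
    if not len(scored):
        warnings.warn("no events to score: G-score track is identically zero")
    log2m = _focal_log2_matrices(events, profiles, klass)
    thr = {"amp": noise_threshold,
           "del": noise_threshold if noise_threshold_del is None else noise_threshold_del}
    contrib = {d: {c: sample_contributions(m, d, thr[d], cap_log2) if m.any()
                   else np.zeros_like(m)
                   for c, m in log2m[d].items()} for d in DIRECTIONS}
    g = {d: {c: m.sum(axis=0) for c, m in contrib[d].items()} for d in DIRECTIONS}
    return g, contrib


def pvalues(gscore: dict, null: "NullDistribution") -> dict:
    """Per-marker inclusive right-tail p-values against the genome-wide
    permutation null (one direction)."""
    return {chrom: null.tail(g) for chrom, g in gscore.items()}


def qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up over a flat p-value vector."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _q_by_chrom(pv: dict) -> dict:
    chroms = list(pv)
    flat = np.concatenate([pv[c] for c in chroms])
    q = qvalues(flat)
    out, i = {}, 0
    for c in chroms:
        out[c] = q[i: i + len(pv[c])]
        i += len(pv[c])
    return out


class ScnaScorer(BaseEstimator):
    """Marker-level G-score / p / q track as a scikit-learn estimator.

    Fit on a classified event catalog plus the cohort profiles (the
    profiles supply the marker-space geometry and sample list).  Fitted
    attributes, each a ``{direction: {chrom: vector}}`` mapping:
    ``gscore_``, ``pvalues_``, ``qvalues_``; plus ``null_`` (per-direction
    :class:`NullDistribution`) and ``contributions_`` (per-sample
    copy-space amplitude matrices).
    """

    def __init__(self, noise_threshold: float = 0.1, cap_log2: float = 1.5,
                 bin_width: float = 0.01, q_threshold: float = 0.25,
                 klass: str | None = "focal", noise_threshold_del: float | None = None):
        self.noise_threshold = noise_threshold
        self.cap_log2 = cap_log2
        self.bin_width = bin_width
        self.q_threshold = q_threshold
        self.klass = klass
        self.noise_threshold_del = noise_threshold_del

    def fit(self, events: pd.DataFrame, profiles: CopyProfileSet):
        self.samples_ = list(profiles.samples)
        self.chromosomes_ = list(profiles.data)
        self.gscore_, self.contributions_ = gscore_track(
            events, profiles, self.noise_threshold, self.cap_log2,
            self.klass, self.noise_threshold_del)
        self.null_ = {}
        self.pvalues_ = {}
        self.qvalues_ = {}
        for d in DIRECTIONS:
            per_sample = np.concatenate(
                [self.contributions_[d][c] for c in self.chromosomes_], axis=1)
            # every queried score is bounded by the track maximum, so the
            # table can stop just above it with exact tails
            gmax = max((float(np.max(g)) for g in self.gscore_[d].values()), default=0.0)
            self.null_[d] = NullDistribution.from_sample_values(
                per_sample, self.bin_width, truncate_at=gmax * 1.05 + 1.0)
            self.pvalues_[d] = pvalues(self.gscore_[d], self.null_[d])
            self.qvalues_[d] = _q_by_chrom(self.pvalues_[d])
        return self

    def rescore(self, contributions: dict, direction: str):
        """(G, p, q) per chromosome for modified contribution matrices,
        against the fitted (original) null."""
        g = {c: m.sum(axis=0) for c, m in contributions.items()}
        p = pvalues(g, self.null_[direction])
        return g, p, _q_by_chrom(p)
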