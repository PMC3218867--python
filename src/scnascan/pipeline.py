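"""End-to-end orchestration: I/O -> deconstruction -> separation ->
scoring -> peak identification -> boundaries -> reports.

`GisticPipeline` is the in-memory estimator composing the stage
estimators; `run_gistic` adds file I/O, logging and output writing around
it, driven by a `RunConfig` (loadable from YAML).  All stochastic stages
draw their seeds from one master seed, so identical config + seed gives
identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from . import io as gio
from .boundaries import RegBounder
from .gene_gistic import GeneScorer
from .peaks import PeakCaller
from .scoring import ScnaScorer
from .ziggurat import ZigguratDeconstructor, reconstruct

__all__ = ["RunConfig", "GisticPipeline", "run_gistic", "run_legacy_filter_mode"]

log = logging.getLogger("scnascan")

LEGACY_MODES = {
    # (event class filter, amp threshold, del threshold) per filtering mode
    "low_amp": (None, 0.1, None),
    "high_amp": (None, 0.848, 0.737),
    "focal_length": ("focal", 0.1, None),
}


@dataclass
class RunConfig:
    """Every knob of a full run; all thresholds in documented ranges."""

    seg: str = ""
    markers: str = ""
    genes: str | None = None
    arms: str | None = None
    cnv_mask: str | None = None
    output_dir: str = "scnascan_out"
    noise_threshold_log2: float = 0.1
    cap_log2: float = 1.5
    broad_len_cutoff: float = 0.98
    q_threshold: float = 0.25
    confidence: float = 0.75
    bin_width: float = 0.01
    zd_rounds: int = 5
    gene_gistic: bool = False
    peel_method: str = "arbitrated"
    arbitration: str = "proportional"
    boundary_method: str = "regbounder"
    n_permutations: int = 100
    include_sex: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        checks = [
            (0 < self.noise_threshold_log2 < 2, "noise_threshold_log2 in (0, 2)"),
            (self.cap_log2 > 0, "cap_log2 > 0"),
            (0 < self.broad_len_cutoff <= 1, "broad_len_cutoff in (0, 1]"),
            (0 < self.q_threshold <= 1, "q_threshold in (0, 1]"),
            (0 < self.confidence < 1, "confidence in (0, 1)"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid configuration: expected {msg}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class GisticPipeline(BaseEstimator):
    """The full analysis as one composed scikit-learn estimator.

    ``fit(profiles, arms=None, genes=None)`` runs deconstruction, focal
    scoring, peel-off and boundary estimation; fitted attributes expose
    each stage (``deconstructor_``, ``scorer_``, ``caller_``,
    ``bounder_``, ``gene_scorer_``) plus the combined ``peaks_`` table
    with wide intervals.
    """

    def __init__(self, noise_threshold: float = 0.1, cap_log2: float = 1.5,
                 broad_len_cutoff: float = 0.98, q_threshold: float = 0.25,
                 confidence: float = 0.75, bin_width: float = 0.01,
                 zd_rounds: int = 5, peel_method: str = "arbitrated",
                 arbitration: str = "proportional", boundary_method: str = "regbounder",
                 gene_gistic: bool = False, n_permutations: int = 100, seed: int = 0):
        self.noise_threshold = noise_threshold
        self.cap_log2 = cap_log2
        self.broad_len_cutoff = broad_len_cutoff
        self.q_threshold = q_threshold
        self.confidence = confidence
        self.bin_width = bin_width
        self.zd_rounds = zd_rounds
        self.peel_method = peel_method
        self.arbitration = arbitration
        self.boundary_method = boundary_method
        self.gene_gistic = gene_gistic
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, profiles: gio.CopyProfileSet, arms: gio.ArmTable | None = None,
            genes: pd.DataFrame | None = None):
        if profiles.n_samples == 0:
            raise ValueError("no samples in the input cohort")
        log.info("deconstructing %d samples over %d chromosomes",
                 profiles.n_samples, len(profiles.data))
        self.deconstructor_ = ZigguratDeconstructor(
            max_rounds=self.zd_rounds, amp_max=self.cap_log2,
            broad_len_cutoff=self.broad_len_cutoff).fit(profiles, arms)
        events = self.deconstructor_.events_
        log.info("catalog: %d events (%d focal)", len(events),
                 int((events["klass"] == "focal").sum()))
        self.scorer_ = ScnaScorer(
            noise_threshold=self.noise_threshold, cap_log2=self.cap_log2,
            bin_width=self.bin_width, q_threshold=self.q_threshold).fit(events, profiles)
        self.caller_ = PeakCaller(method=self.peel_method, arbitration=self.arbitration,
                                  q_threshold=self.q_threshold).fit(
            self.scorer_, events, profiles)
        self.bounder_ = RegBounder(gamma=self.confidence,
                                   n_permutations=self.n_permutations,
                                   seed=self.seed).fit(self.scorer_)
        self.peaks_ = self.bounder_.apply_to_peaks(self.caller_.peaks_,
                                                   method=self.boundary_method)
        log.info("%d significant peaks", len(self.peaks_))
        self.gene_scorer_ = None
        if self.gene_gistic and genes is not None:
            self.gene_scorer_ = GeneScorer(
                noise_threshold=self.noise_threshold, cap_log2=self.cap_log2,
                bin_width=self.bin_width).fit(genes, profiles, events)
        return self


def _load_inputs(config: RunConfig):
    markers = gio.read_markers(config.markers, include_sex=config.include_sex)
    seg = gio.read_seg(config.seg)
    if seg.empty:
        raise ValueError("no samples in the SEG input")
    profiles = gio.project_to_markers(seg, markers)
    if config.cnv_mask:
        cnv = pd.read_csv(config.cnv_mask, sep="\t", header=None, comment="#")
        profiles = gio.exclude_cnv(profiles, cnv)
    arms = gio.read_arm_table(config.arms) if config.arms else None
    genes = gio.read_gene_table(config.genes, markers) if config.genes else None
    return profiles, arms, genes


def _peaks_with_bp(peaks: pd.DataFrame, markers: gio.MarkerSet) -> pd.DataFrame:
    out = peaks.drop(columns=["event_ids", "shares"], errors="ignore").copy()
    for col in ("region", "peak", "wide"):
        if f"{col}_start" not in out.columns:
            continue
        out[f"{col}_start_bp"] = [int(markers.positions(c)[s])
                                  for c, s in zip(out["chrom"], out[f"{col}_start"])]
        out[f"{col}_end_bp"] = [int(markers.positions(c)[e - 1])
                                for c, e in zip(out["chrom"], out[f"{col}_end"])]
    return out


def run_gistic(config: RunConfig):
    """Run the full pipeline from files to the output bundle.

    Writes score tracks, the peak table with wide boundaries, the event
    catalog, focal/arm-level reconstructions, the gene score table when
    enabled, and a run log echoing every effective parameter.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.as_dict()
    profiles, arms, genes = _load_inputs(config)
    pipe = GisticPipeline(
        noise_threshold=config.noise_threshold_log2, cap_log2=config.cap_log2,
        broad_len_cutoff=config.broad_len_cutoff, q_threshold=config.q_threshold,
        confidence=config.confidence, bin_width=config.bin_width,
        zd_rounds=config.zd_rounds, peel_method=config.peel_method,
        arbitration=config.arbitration, boundary_method=config.boundary_method,
        gene_gistic=config.gene_gistic, n_permutations=config.n_permutations,
        seed=config.seed)
    try:
        pipe.fit(profiles, arms, genes)
    except Exception as e:
        raise RuntimeError(f"pipeline stage failed: {e}") from e
    markers = profiles.markers
    gio.write_score_track(out / "score_track.tsv", markers, pipe.scorer_, params)
    gio.write_peak_table(out / "peaks.tsv", _peaks_with_bp(pipe.peaks_, markers), params)
    gio.write_event_catalog(out / "events.tsv", pipe.deconstructor_.events_, markers, params)
    for klass, name in (("focal", "focal_profiles.seg"), ("arm_level", "arm_profiles.seg")):
        rec = reconstruct(pipe.deconstructor_.events_, profiles, klass=klass)
        gio.profiles_to_seg(rec).to_csv(out / name, sep="\t", index=False)
    if pipe.gene_scorer_ is not None:
        gio.write_gene_scores(out / "gene_scores.tsv", pipe.gene_scorer_.gene_scores_, params)
    with open(out / "run_log.txt", "w") as fh:
        for k, v in params.items():
            fh.write(f"{k} = {v}\n")
    return pipe


def run_legacy_filter_mode(config: RunConfig, mode: str):
    """Score with one of the legacy filtering strategies.

    ``low_amp`` keeps every event above |log2| 0.1; ``high_amp`` keeps
    only events beyond +0.848 / -0.737 (the amplitude route to removing
    arm-level events); ``focal_length`` keeps focal events above |log2|
    0.1 (the length route).  Enables side-by-side comparison of the three
    filters on any dataset.
    """
    if mode not in LEGACY_MODES:
        raise ValueError(f"unknown legacy mode {mode!r}; choose from {sorted(LEGACY_MODES)}")
    klass, thr_amp, thr_del = LEGACY_MODES[mode]
    profiles, arms, _ = _load_inputs(config)
    zd = ZigguratDeconstructor(max_rounds=config.zd_rounds, amp_max=config.cap_log2,
                               broad_len_cutoff=config.broad_len_cutoff).fit(profiles, arms)
    scorer = ScnaScorer(noise_threshold=thr_amp, noise_threshold_del=thr_del,
                        cap_log2=config.cap_log2, bin_width=config.bin_width,
                        q_threshold=config.q_threshold, klass=klass).fit(zd.events_, profiles)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**config.as_dict(), "legacy_mode": mode}
    gio.write_score_track(out / f"score_track_{mode}.tsv", profiles.markers, scorer, params)
    return scorer
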