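# scnascan

Significance analysis of somatic copy-number alterations (SCNAs) in
cancer cohorts.

Tumor genomes accumulate amplifications and deletions; most are random
passengers, a few recur because they are selected for.  Given segmented
log2 copy-ratio profiles for a cohort, `scnascan` finds the genomic
regions altered more often and more strongly than a background model of
passenger formation can explain, and localizes the likely driver gene in
each region.  It is aimed at cancer-genomics analysts working from
SEG-format segmentation output (array or sequencing derived).

The pipeline:

1. **Ziggurat deconstruction** — split each profile into discrete,
   possibly stacked events that sum exactly back to the profile,
   maximizing likelihood under an iteratively estimated background
   frequency model over event (length, amplitude).
2. **Focal/arm-level separation** — events covering ≥ 98% of a chromosome
   arm are arm-level; the rest are focal and are scored.
3. **Scoring** — per-marker G-score `G(i) = Σ_samples a_s(i)` with `a`
   the capped copy-space amplitude (`c = 2·2^r`, amp `max(c−2,0)`, del
   `max(2−c,0)`; |log2| ≤ 0.1 ignored).  P-values come from the exact
   convolution form of the marker-permutation null; Benjamini–Hochberg
   q-values at q ≤ 0.25, separately for gains and losses.
4. **GeneGISTIC** (optional) — gene-level deletion scores (per-sample
   minimum within the gene) against gene-size-matched running-window
   minima nulls, for suppressors hit by non-overlapping deletions.
5. **Peel-off** — standard (greedy removal) or arbitrated (score shares
   redistributed among peaks an event spans) iteration yields independent
   significant peaks.
6. **Boundaries** — MCR, leave-k-out, or RegBounder wide peaks; RegBounder
   grows each peak until the drop from its maximum exceeds the γ-quantile
   of a cyclic-shift permutation null of boundary drops, giving intervals
   that contain the target with probability ≥ γ.

A driver/passenger simulator generates benchmark cohorts with planted
drivers and ground truth; `scnascan benchmark` reproduces the two
standard experiment designs.  See `docs/methods.md` for models,
assumptions and numerical choices.

## Worked example

Simulate a 120-sample cohort with one amplified driver locus present in
20% of samples (markers 400–405 on a 1,000-marker chromosome, 100 kb
spacing), then run the pipeline:

```bash
scnascan simulate -o sim --n-samples 120 --primary-freq 0.2 --seed 11
scnascan run --seg sim/cohort.seg --markers sim/markers.tsv -o out --seed 11
# -> 1 significant peaks -> out
```

`out/peaks.tsv` (selected columns):

```
direction  chrom  peak_start  peak_end  gmax   q        peak_start_bp  peak_end_bp  wide_start_bp  wide_end_bp
amp        1      400         402       29.69  9.78e-4  40100000       40200000     36100000       46200000
```

The single amplification peak tops out at markers 400–402 (G = 29.7 copy
units × samples, q ≈ 1e-3) — inside the planted target — and the
RegBounder wide interval (75% confidence) spans 36.1–46.2 Mb around it.
`out/score_track.tsv` holds the per-marker G and −log10 q tracks in both
directions, `out/events.tsv` the deconstructed event catalog, and
`out/focal_profiles.seg` / `out/arm_profiles.seg` the separated genome
representations.

Library use mirrors scikit-learn: `GisticPipeline(...).fit(profiles)`
exposes the fitted stages (`deconstructor_`, `scorer_`, `caller_`,
`bounder_`, `peaks_`), and each stage (`ZigguratDeconstructor`,
`ScnaScorer`, `PeakCaller`, `RegBounder`, `GeneScorer`) is an estimator
with `get_params`/`set_params` and trailing-underscore fitted attributes.

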