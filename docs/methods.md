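# Methods

This note documents the statistical model behind `seroprofile`, the
parameters that matter, the synthetic data it is validated on, and the
design choices made where the procedure itself is under-specified.

## The discrimination model

The pipeline treats a serum sample as a vector of normalized peak areas on
a unit-m/Z grid and asks, for a binary cohort, how consistently each
sample's peaks side with one group.

**Unit-mass binning.** Raw (m/Z, intensity) points are assigned to
`round(m/Z)` with half rounded away from zero, and intensities within a
bin are summed. Rounding (rather than truncation) is the common MS
convention and is deterministic; points rounding outside the configured
range are discarded and counted in the log. In-range total intensity is
conserved exactly.

**Local normalization.** Within every non-overlapping segment of
`segment_width` m/Z units (default 10, anchored at the range lower bound),
intensities are rescaled so the segment sums to `segment_target` (default
100). Any per-sample global intensity scale — sample loading, spray
efficiency — cancels exactly in each segment's ratio, which is the
property the rest of the pipeline relies on. All-zero segments cannot be
scaled and stay zero (logged); a partial final segment is scaled like any
other (moot at the default 400–2000 range). Normalization is invariant to
a global scale to within floating-point rounding (bit-exact for
power-of-two scales; ≲1e-12 relative otherwise).

**Peak areas.** Two modes:

* `bin` (default): each unit bin's normalized intensity is its own peak
  area. The discrimination operates on unit m/Z values, so for data that
  are already unit-binned this is the faithful default.
* `centroid`: valley-to-valley segmentation. A valley is a bin ≤ both
  neighbours; a plateau of valleys collapses to its leftmost bin and a
  shared valley bin belongs to the peak on its left (ties broken leftward
  throughout, so segmentation is deterministic). A peak's area is the sum
  of its bins and its centroid is the intensity-weighted mean m/Z rounded
  to unit; every non-zero bin belongs to exactly one peak, so total
  intensity is conserved.

**Replicate averaging.** Areas are computed per replicate and then
averaged arithmetically per unit m/Z (any replicate count ≥ 1 is accepted
and recorded; triplicates are the expected design). Averaging after peak
assignment matches the "replicate-averaged peak areas" formulation; the
order is configurable in principle but this is the documented default.

**LOOCV peak selection and PCV scoring.** For each left-out sample the
remaining N−1 profiles are screened per unit m/Z in the analysis range
(default 400–1908, which may be narrower than the normalization range):

* an abundance floor drops bins whose larger group-mean area is below
  `min_peak_frac` (default 0.3%) of the maximum group-mean area in the
  left-in dataset — computed per fold, which preserves leave-one-out
  hygiene (the alternative, a single global floor, would let the left-out
  sample influence its own fold's candidate list);
* a Welch (unequal-variance) *t*-test with Welch–Satterthwaite degrees of
  freedom is applied one-tailed **in the direction of the observed mean
  difference**, i.e. p = P(T ≥ |t|), equivalent to half the two-sided p.
  Equal means give p = 0.5; two constant equal groups give p = 1, constant
  different groups give p = 0. Bins with p < `alpha` (default 0.05) are the
  fold's significant peaks.

Each selected peak carries a *peak classification value* (PCV), defined
here as the arithmetic midpoint of the two left-in group means (the
procedure's "midpoint metric"; no other formula is implied by its
description). The left-out sample's area strictly above the PCV classifies
the peak to the higher-mean group; at or below, to the other group. The
sample's score is 100 × (#peaks classified to group 1)/(#peaks), so the
two per-group score components always sum to 100%. The left-out sample
contributes nothing to selection, means or PCVs; a fold with zero
significant peaks produces an undefined score that is excluded downstream
with a loud warning.

Per-peak p-values are deliberately not corrected for multiple testing —
the randomization null is the procedure's over-fitting control — and no
baseline subtraction, smoothing, deisotoping or charge deconvolution is
performed.

**Statistical behaviour to be aware of.** Two properties follow from the
construction and are verified by the test suite rather than assumed away:

1. Because the screening tail is chosen from the observed direction, a
   truly null bin is "significant" with probability 2α (P(|t| > t_α)),
   not α. The fixed-direction one-tailed Welch test is α-calibrated; the
   data-directed screen is not, and its null selection rate is ~10% at
   α = 0.05.
2. Under the null, LOOCV scores are slightly *anti*-discriminative:
   excluding the left-out sample leaves its group with n−1 members, so
   that group's left-in mean is noisier, and conditioning on significance
   biases the PCV against the left-out sample. Null cohorts therefore show
   systematic inverse separation, and a two-sided Welch test on
   randomized-label scores is anti-conservative (~30% of null separation
   p-values fall below 0.05 at n = 10+10) rather than uniform. The
   randomization control is still informative — structured cohorts show
   p-values many orders of magnitude below their own randomized reruns —
   but its p-value should be read as a contrast, not as a calibrated
   test level.

**Evaluation.** With group-1 score moments (m1, s1) and group-2 (m2, s2)
(sample SDs, n−1 divisor; the divisor is a documented choice):

* SD-balanced cut-off: k = (m1 − m2)/(s1 + s2); cutoff = m2 + k·s2
  = m1 − k·s1, the threshold the same number of SDs from both means.
  Zero total spread flags infinite separation and falls back to the
  midpoint.
* Confusion counts at the cut-off (strictly above → positive group),
  sensitivity TP/(TP+FN), specificity TN/(TN+FP), efficiency
  (TP+TN)/total.
* Separation p: two-sided Welch *t* on the scores (configurable to
  one-sided; the test is not otherwise dictated).
* Cohen's d = (m1 − m2)/√((s1² + s2²)/2) irrespective of group sizes
  (this form reproduces the reference values for unequal-n comparisons;
  a df-weighted pooled SD is the usual textbook alternative). Displayed
  values are truncated — not rounded — to two decimals, alongside full
  precision, matching the reference presentation.
* Power: two-sample noncentral-*t* with ncp = d·√(n1·n2/(n1+n2)),
  df = n1+n2−2, two-sided α (scipy's far tail can underflow to NaN at
  large ncp; the vanishing term is then dropped).
* ROC by sweeping all observed scores; tied scores form single threshold
  steps so the trapezoidal AUC equals the Mann–Whitney statistic
  (#concordant + ½#ties)/(n1·n2).

**Randomization control.** "Manually balanced" relabeling is
operationalized as a stratified permutation: group labels are shuffled
within (sex × age-band) strata (decade bands by default; unknown metadata
forms its own stratum and is never imputed). This conserves overall group
sizes and per-stratum — hence per-sex and per-age-band — group composition
exactly for every seed; strata with a single member keep their label
(logged). One shuffle per run mirrors the single randomized comparison of
the reference analysis; `--n-shuffles` aggregates a null distribution when
a fuller control is wanted.

**Blinded validation.** `train` runs the LOOCV on training samples to fix
the cut-off from their score distributions, then selects the final peak
set once on *all* training samples (left_out_id "none"). Using the full
training set rather than one fold's N−1 subset is the documented reading
of an ambiguous prescription; a per-fold-union alternative would select
slightly more peaks but was not adopted. `classify_blinded` scores a new
sample against the frozen PCVs and thresholds it at the frozen cut-off;
training output is invariant to blinded-set contents by construction.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `segment_width` | 10 | m/Z | stated normalization segment |
| `segment_target` | 100 | intensity | stated normalization sum |
| normalization range | 400–2000 | m/Z | acquisition range |
| `alpha` | 0.05 | — | stated screening level |
| `min_peak_frac` | 0.003 | fraction | stated 0.3% abundance floor |
| analysis range | 400–1908 | m/Z | stated discrimination range |
| `peak_mode` | `bin` | — | unit-m/Z discrimination |
| age bands | 10 | years | decade strata for balancing |

## The synthetic cohort generator

`synthetic.SyntheticConfig` emulates the statistical structure the
analysis assumes: per-sample triplicate unit-mass spectra, log-normal peak
intensities, a configurable set of discriminating unit-m/Z peaks, and the
nuisance effects the pipeline must remove.

* Each bin has a cohort-level log-mean; a fraction `peak_density`
  (default 0.2) of bins carry chemical signal, the rest sit at a relative
  noise floor (`noise_ratio`, default 1e-4) far below the 0.3% abundance
  floor. Real serum profiles are sparse in exactly this sense; an
  all-dense baseline would hand the screen ~75 chance-significant bins per
  fold and dilute every score toward 50%.
* Samples draw biological levels around the bin log-mean with log-SD
  `baseline_sigma` (0.4); `n_discriminating` bins (default 130, the scale
  of the reference comparisons) shift the group-1 log-mean by
  ±`effect_size`·`baseline_sigma`, half up and half down, since real
  discriminatory peaks rise in either group.
* Replicates get multiplicative jitter with CV `replicate_cv` (0.15 — a
  plausible direct-infusion repeatability), and each sample a global scale
  `exp(N(0, sample_scale_sigma))` (0.3) that normalization must cancel:
  regenerating with scale sigma 0 vs 0.5 leaves LOOCV scores unchanged to
  1e-9.
* Metadata (sex ratio, ages 35–79, a 64% diabetes flag in group 1) feeds
  the balanced randomization. Everything is deterministic under the seed,
  including the written TSV cohort (byte-identical across reruns); a
  `truth.json` sidecar lists the planted peaks for recovery tests.

Presets shape cohorts like the study's comparisons — `cabg_vs_control`
(25+25), `training_blinded` (20+20 with a 5+5 holdout), `t2dm_split`
(16 vs 9) — with effect sizes calibrated once so the LOOCV score moments
land near the corresponding reported distributions (e.g. the 25+25 preset
yields group score means ≈ 61/40 with SDs ≈ 5 and 130–170 significant
peaks per fold, against reported 56.9/37.8, SDs ≈ 5, 129–140 peaks).

The generator deliberately omits isotope envelopes, charge states,
chemical noise, instrument drift and batch effects. Passing tests on
synthetic cohorts therefore demonstrate the pipeline's statistical
machinery — calibration, power, recovery, invariances — under its own
assumptions; they do not certify performance on real sera, where peak
correlation structure and drift could behave differently.

## Numerical choices and degenerate inputs

* Rounding: half away from zero everywhere a value meets the unit grid.
* Welch with both group variances zero: p = 1 if means equal, else 0;
  groups of fewer than 2 samples are an error.
* PCV ties ("at or below") always classify to the lower-mean group.
* Cut-off with s1 + s2 = 0: midpoint, k flagged infinite; swapped group
  means are reordered with a notice.
* Undefined (zero-peak) scores are NaN, excluded from every metric and
  counted in reports.
* Scores, selections and shuffles are exactly reproducible given a seed;
  the test suite pins the LOOCV scorer bit-for-bit against an independent
  plain-loop reimplementation.

## Validation problem sizes

The automated checks run at desk scale, chosen so the full suite completes
in well under a minute of CPU: calibration on 200 null cohorts of 10+10
samples over a 300-bin range; power and recovery on 100 and 50 seeds of
15+15 samples over the full 1601-bin range with 100 planted peaks;
preset-moment checks at 25+25. Larger ranges and cohort sizes only
tighten the Monte-Carlo bands.

## Known limitations

* The screening stage's data-directed tail and the LOOCV score bias
  (above) mean nominal α does not equal the realized null rates; the
  package reports both behaviours honestly rather than recalibrating the
  procedure it implements.
* mzML support covers the common case (MS1 scans, 32/64-bit float arrays,
  plain or zlib-packed); exotic encodings are out of scope.
* The generator's independence across bins understates the correlation of
  real isotopologue/adduct clusters, so synthetic recovery rates are
  likely optimistic relative to real spectra.
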