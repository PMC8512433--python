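# Methods

This note documents the models, algorithms and design choices behind
`vinomix`, in the order the pipeline applies them, together with the
assumptions of the synthetic-study generator and the limits of what passing
tests demonstrate about real instrument data.

## The synthetic study generator

`synthio.simulate_study` produces scan-mode GC-MS runs with known truth. Its
assumptions, and what they deliberately leave out:

* **Chromatography.** Every compound elutes as a *Gaussian* profile with a
  single global width (σ = 2.5 s by default, i.e. ~5.9 s FWHM, inside the
  5–20 s detection window). The apex position comes from the compound's
  retention index through piecewise-linear interpolation of the C7–C30
  alkane ladder — the exact inverse of the van den Dool–Kratz convention the
  identification stage uses, which makes the ladder self-consistency
  property (a compound at RI 100·n apexes at the C\_n alkane) testable to one
  scan. Tailing, fronting, column bleed and co-elution-induced peak-shape
  distortion are not modelled; width-based filters are exercised, but the
  detector's behaviour on asymmetric peaks is untested.
* **Amplitudes.** A compound at concentration *c* µg/L with response *r*
  produces a base-ion chromatographic area of exactly *c·r* counts·s; other
  ions scale by their relative spectrum intensity (/999). The sampled profile
  is renormalised so the *discrete* trapezoid equals the target area, which
  lets the total-ion-current conservation test assert equality at 1e-6
  relative rather than quadrature slack.
* **Variation.** Biological variation is a per-(compound, sample) log-normal
  factor with mean exactly 1 and the requested CV (σ² = ln(1+cv²),
  µ = −σ²/2); treatment effects are multiplicative per factor level;
  duplicate injections share the biological draw and differ only in retention
  drift (per-run N(0, 0.01 min)) and detector noise. Noise is Poisson
  (variance = mean) around signal + a constant floor; a floor of zero
  switches noise off entirely so that the "no randomness ⇒ identical runs"
  contract holds exactly. Matrix effects, carryover and batch drift in
  response are not modelled.
* **Acquisition.** Nominal-mass channels (integers 29–300), centroid MS1.
  The scan rate is configurable; the default is 120 scans/min (2 scans/s),
  chosen once as the coarsest rate that still samples a 5.9 s-FWHM peak with
  ~12 points — enough for apex and half-height estimation — while keeping a
  48-run study desk-sized. Runs are written/read as mzML (64-bit float
  arrays, no compression, scan times in seconds); libraries as MSP with
  `Name`, `RI`, `Num Peaks` fields.

**The built-in study** mirrors a two-factor vineyard design: 4 rootstocks ×
3 irrigation regimes × 2 vines = 24 wines, injected in duplicate (48 runs),
with 24 named wine volatiles (plausible EI spectra and retention indices,
including isoamyl acetate at 495 µg/L with a 30 µg/L odor threshold and
β-damascenone at 8.59 µg/L grafted / ×1.105 own-rooted), 36 unnamed
volatiles, and 2-octanol / 4-methyl-2-pentanol / 3-octanone spiked at
50/100/50 ppb. Twelve named compounds carry planted rootstock shifts.
The shifts span 35–55 %: a design-stage power analysis (one-way ANOVA,
4 groups × 6 biological samples, log-scale SD 0.15) gives only ~60–70 %
per-compound power at BH q < 0.05 for a 30 % shift, so a recoverable planted
panel needs most shifts comfortably above that floor; all satisfy the ≥ 25 %
convention for a "strong" effect. β-damascenone's ~10 % contrast is planted
*below* the untargeted screen's resolving power at this n — it represents
the class of subtle effects that only the targeted calibration arm resolves.

## Feature extraction

* **Detection** runs per integer m/z channel (unit-mass data: the usual
  0.01–0.015 m/z slice widths fall below channel spacing, so each nominal
  mass is its own slice). Apexes are local maxima of a Gaussian-smoothed EIC
  (kernel σ = peakwidth_min/2.355). The half-height width filter is applied
  to the *deconvolved* width, √(w_obs² − w_kernel²), so the 5–20 s window
  refers to the underlying peak; for Gaussian peaks this is exact, for other
  shapes approximate. S/N = (raw height − baseline)/noise with baseline the
  median and noise 1.4826×MAD of the channel outside candidate windows
  (floor 1). Area integrates the raw EIC above a straight line between the
  window endpoints, clipped at zero.
* **Retention alignment** replaces raw-profile dynamic warping with
  peak-group warping: groups present in ≥ 90 % of runs with exactly one peak
  per run anchor a lowess fit of (deviation from median rt) vs rt per run;
  the warp subtracts the smoothed deviation and is clamped to strict
  monotonicity, so scans can never reorder. Fewer than five anchors falls
  back to alkane-ladder anchors when available, otherwise identity + warning.
* **Grouping** follows the kernel-density approach: per slice, peaks group
  under maxima of a Gaussian density over rt (bandwidth 5 s); a group is
  kept iff some rootstock×irrigation class contains it in at least
  max(minsamp, minfrac × class size) runs — the minfrac boundary is
  inclusive, and combining minfrac with minsamp as a per-class floor keeps
  minfrac binding at the default minsamp = 1. One peak per run per feature
  (largest area wins). Feature ids are `M{mz}T{rt}` with rt in minutes to
  two decimals.
* **Gap filling** integrates the raw warped EIC over the group's median rt
  window; a zero integral falls back to a noise-floor area so downstream
  log-scale statistics never meet zeros. Duplicate injections are averaged
  arithmetically afterwards. Fill-in is on by default (`fill` flag).

## Differential statistics

* **Preprocessing**: each sample is divided by its 2-octanol response
  *rescaled by the median IS response across samples*. The rescaling keeps
  values on the raw counts scale; without it the log(x+1) pseudocount
  dominates ratio-scale values (≪ 1), the log fails to normalise the
  log-normal variation, and null F statistics become measurably miscalibrated.
  After log(x+1), features are autoscaled (mean 0, SD 1, ddof 1); constant
  columns are dropped.
* **Screen**: one-way fixed-effects ANOVA per feature per factor —
  deliberately one-way at the feature stage (the two-way model with
  interaction is reserved for quantified compounds). BH q-values are computed
  within each factor's family. Degenerate features (no variance at all)
  report p = 1 rather than NaN.
* **PCA** by SVD of the centred autoscaled matrix; component signs are fixed
  so the largest-|loading| element is positive, making outputs reproducible.
* **PLS-DA** is NIPALS PLS2 on one-hot class membership. R²Y = 1 − RSS/TSS;
  Q² = 1 − PRESS/TSS with PRESS from leave-one-out refits, each fold
  re-centred on its training data (the global autoscaling is not redone per
  fold; with n = 24 its leakage is negligible relative to the class-mean
  re-centring). VIP uses unit-norm weight vectors and per-component explained
  Y-variance (t'tc'c), which enforces mean(VIP²) = 1 identically — a useful
  invariant check. The permutation test permutes labels B times and reports
  (1 + #{null ≥ observed})/(B + 1) on the Q² statistic; the attainable
  minimum is therefore 1/(B+1), ~0.1 % at B = 1000. B < 20 is refused.
* **Variance partition**: per PC, `score ~ rootstock + irrigation +
  rootstock:irrigation` with type-I sums of squares in that order (equal to
  type-III on the balanced design); fractions are SS_term/SS_total and sum
  to 1 with the residual. Empty cells drop the interaction with a warning.
* **Cross-batch overlap**: independently processed batches (e.g. years) are
  compared by feature-id string by default; because ids encode m/z and rt, an
  rt-tolerance matcher (same m/z, nearest rt within tolerance, one-to-one) is
  provided for columns that drift between batches. The right tolerance is
  data-dependent and left to the caller.

**What "null calibration" does and does not show.** Ions of one compound
share a biological draw, so feature-level p-values are block-correlated;
an i.i.d. KS uniformity test over ~330 features amplifies the ordinary
sampling noise of the 60 underlying compounds and rejects even when the
per-compound p-values are uniform. Uniformity is therefore asserted on one
feature per co-eluting cluster (the most intense ion), where independence
holds. Real data has the same block structure, plus correlation sources
(shared precursors, batch effects) the generator does not emulate.

## Identification

* Pseudo-spectra: single-linkage clustering of significant features on rt
  with a 3 s gap threshold (the gap is a package choice, surfaced in config;
  compounds in the built-in study are spaced ≥ 16 RI units so clusters are
  unambiguous). Member intensities are cross-sample means, rescaled to a 999
  base peak.
* Match factor: weighted cosine with W = intensity^0.5 × m/z, the common
  identity-search weighting; exact nominal-mass matching; symmetric and
  scale-invariant; cross-checked in tests against an independent cosine
  implementation. The library "probability" field of commercial search
  engines (an in-library ambiguity model) is deliberately not implemented;
  the match factor is the gate.
* Retention index: van den Dool–Kratz linear interpolation, the standard for
  temperature-programmed runs; the isothermal logarithmic form is available
  behind `form="kovats"` with a dead-time parameter. Extrapolation beyond
  the ladder is refused rather than guessed.
* Two-step rule: tentative iff match ≥ 700 **and** |RI_calc − RI_lit| ≤ 15.
  The tolerance accepts the ~12-unit gaps typical of column-to-literature
  comparison with margin. Ties in match factor break toward the smaller RI
  gap, which is what defeats decoy library entries sharing a true compound's
  spectrum at a displaced RI. Confirmation against an authentic-standard run
  requires rt agreement within 3 s after warping and a spectral match ≥ 700.

## Quantitation

* Calibration is closed-form weighted least squares with weights 1/x; the
  weighted r² (1 − Σw(y−ŷ)²/Σw(y−ȳ_w)²) must reach 0.99 for a curve to be
  used — a failing curve is flagged, not an error. In the synthetic pipeline
  the calibration series is itself simulated and measured through the same
  peak detection, so integration biases cancel between calibrant and sample
  exactly as they do with real standards. Predictions outside the calibrated
  range are flagged; negative inversions clip to 0 with a flag.
* Semi-quantitation assumes a response factor of 1 versus the 50 µg/L
  2-octanol spike (conc = ratio × 50). OAV = concentration / odor threshold;
  a missing threshold yields "no OAV", never zero. Concentrations are
  replicate-averaged before ANOVA (consistent with the feature-stage
  averaging).
* The compound-level model is a two-way ANOVA with interaction (type-I SS);
  the post-hoc over the 12 interaction cells is Tukey HSD by default, with
  Duncan's multiple range test behind a flag (the two appear interchangeably
  in practice; Tukey controls family-wise error and is the package default).
  Letters come from the insert-and-absorb compact-letter-display algorithm
  and are verified in tests to be a valid clique cover: two cells share a
  letter iff their pairwise test is non-significant.

## Pipeline, problem sizes and determinism

The orchestrator runs detection → alignment → averaging → preprocessing →
per-factor ANOVA/FDR → PCA/PLS-DA/variance partition → pseudo-spectra →
two-step identification → standard confirmation → calibration → OAV →
compound ANOVA, writing each intermediate as CSV plus a JSON manifest whose
funnel counts (features → significant → tentative → confirmed → quantified)
are non-increasing by construction. All randomness flows from a single seed;
re-running a configuration reproduces every output byte-for-byte.

Default problem sizes are chosen for a desk-scale study: 48 runs of ~4700
scans × ~160 active channels simulate in a few seconds and the whole funnel
completes in well under a minute; tests that repeat the permutation machinery
use B = 200 with the estimator's properties tested separately, while the
pipeline default remains B = 1000.

## Known limitations

* Detection assumes roughly uniform scan spacing and Gaussian-like peaks; no
  CWT ridgeline analysis, no deconvolution of genuinely co-eluting compounds
  beyond rt-gap clustering.
* The warping model is smooth and monotone; abrupt pressure-spike shifts
  would be under-corrected.
* High-resolution m/z, profile spectra, MS2/MRM data and LC-MS are out of
  scope; the MRM transition lists of triple-quadrupole methods are treated as
  metadata only.
* Odor thresholds are matrix-dependent literature values supplied as an
  editable table; OAV rankings inherit their uncertainty.
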