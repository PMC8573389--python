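# Methods

## Scope and model

`megfc` implements a frequency-resolved functional-connectivity (FC) analysis
of multichannel MEG-like recordings around absence-seizure termination, plus a
synthetic-data generator that provides ground truth for every stage.  The
analysis chain is:

1. **Segmentation.** Around each spike-and-wave discharge (SWD) three windows
   are cut: *ictal* = the 3 s from seizure onset, *termination* = the 3 s
   before seizure offset, *interictal* = a 30-s window at least 10 s away from
   the seizure.  Seizures must last ≥ 6 s so the two 3-s windows are disjoint.
   The interictal window is placed at the earliest position after the seizure,
   falling back to the latest position before it — a deterministic tie-break
   where only a minimum distance is prescribed.
2. **Band decomposition.** Seven bands: delta (1–4 Hz), theta (4–8), alpha
   (8–12), beta (12–30), gamma (30–80), ripple (80–250), fast ripple
   (250–500).  Filters are zero-phase (forward–backward) Butterworth
   band-passes of order 4, preceded by a zero-phase notch comb (quality 30) at
   50 Hz and its harmonics.  Segments are filtered after extraction with 1 s
   of context from the recording (reflection padding if unavailable), then
   cropped, so filter transients stay outside the analysed window.
3. **Connectivity.** For each segment and band, the FC matrix holds the
   Pearson correlation R of every channel pair, R = C(X_a,X_b)/(S_a·S_b) with
   C the covariance.  An edge survives when the correlation-t statistic
   T = R·√(K−2)/√(1−R²) exceeds the two-sided critical t at significance α
   (default 0.05) with K−2 degrees of freedom, equivalently
   |R| ≥ r* = t_crit/√(K−2+t_crit²).  Positive edges are *excitatory*,
   negative *inhibitory*; thresholding is two-sided on |R| and both signs
   enter the graph.
4. **Graph metrics.** S = mean |R| over retained edges (weighted); D = 2|E|/n;
   L = mean hop-count shortest path over connected unordered pairs,
   unreachable pairs excluded, undefined (NaN + flag) when no pair connects;
   C = mean local clustering, degree-<2 nodes contributing 0.  D, L, C are
   binary on the thresholded graph; S alone uses the weights, since it is
   explicitly a strength.
5. **Pattern calls.** Each retained edge belongs to exactly one class:
   intra-frontal, intra-posterior (posterior = parietal ∪ occipital),
   anterior–posterior (one frontal and one posterior endpoint), or other
   (anything touching central/temporal channels).  The segment's label is the
   specific class whose edge fraction reaches θ (default 0.5), else
   *distributed*.  This dominance rule replaces a visual judgement of
   connection maps and is the largest formalization gap in the package: the
   counts it yields depend on θ and on the threshold's sparsity, so published
   per-band counts are treated as qualitative context, not as targets.
6. **Statistics.** Fisher's exact test (two-sided, hypergeometric) on the 2×2
   table of a pattern label across periods, per band; paired Student's
   t-tests on each of S, D, L, C between periods per band (ictal and
   termination come from the same seizure, so paired is the default; unpaired
   is a flag); partial correlation of per-patient metrics with clinical
   features after least-squares residualization against age, sex (M=1, F=0)
   and disease duration.  The 7 bands × 4 metrics comparisons are corrected
   as one family of 28 by both Bonferroni and Benjamini–Hochberg FDR; a
   result is flagged significant by the stricter of the two (configurable).
   Because Bonferroni-adjusted p dominates the BH q, the stricter rule is
   effectively Bonferroni; both columns are always reported.

## Threshold calibration and the effective sample count

The t-criterion assumes K independent samples.  For unfiltered independent
noise that assumption holds and the edge retention rate under the null is α
(verified: 0.052 at α = 0.05, K = 18000).  Band-filtered signals, however,
are autocorrelated: a 3-s segment of bandwidth B carries only about 2·B·T
independent samples (≈ 300 for gamma, ≈ 18 for delta — regardless of the
sampling rate).  With nominal K the null retention in the gamma band is ~55%:
the stated procedure is extremely permissive for band-limited data, which we
document rather than silently change — `sample_mode="nominal"` remains the
default.  The option `sample_mode="bandwidth"` substitutes
K_eff = 2·B·T and restores the ~α null rate in every band.  Count-based
pattern dominance is meaningless on ~55%-dense null networks, so the bundled
recovery experiment analyses with `sample_mode="bandwidth"` and a per-pair
α = 0.01 (≈ 1% null edge rate; r* ≈ 0.15 for gamma at T = 3 s).

## Synthetic data

The generator emulates: (a) 1/f^slope background noise per channel (spectral
shaping of white noise, exact slope control, unit variance, slope 1 by
default); (b) band-limited coupling planted by shared-latent mixing — within
the active window the in-band component of each grouped channel becomes
√(1−w)·b_i + √w·σ_i·z with w = rho_target, giving an expected in-band pairwise
correlation of exactly rho_target for equal-variance channels (closed-form
calibration, verified to ±0.05 over 50 replicates at rho ∈ {0.2, 0.5, 0.8});
(c) a 3 Hz spike-and-wave morphology: a narrow Gaussian spike (width 80 ms,
σ = width/4, smooth across cycle boundaries — a truncated spike would inject
broadband jump harmonics and artificially couple high-frequency bands) and a
negative half-sine slow wave (200 ms), spike/wave amplitude ratio 3, overall
amplitude 3 channel-SD (the relative SWD amplitude is not prescribed anywhere,
so it is a free parameter with that default).  All randomness descends from
one seed per call; identical config + seed is bit-identical.

What the generator does *not* model: cortical source geometry and field
spread, sensor noise covariance, artifacts, non-stationary background — so
passing recovery tests demonstrates that the pipeline detects the planted
statistical structure, not that it would reach identical conclusions on real
recordings.

## The recovery study design (frozen a priori)

22 patients (the bundled cohort table), 11 contributing one seizure and 11
two → 33 seizures; 30 channels (frontal 10, central 4, temporal 4, parietal
6, occipital 6); fs = 1200 Hz, which supports all seven bands at desk-scale
cost (the effective sample count, 2·B·T, is unchanged by the reduced rate);
7-s seizures.  Gamma-band couplings: during the ictal window one
frontal-group coupling at rho 0.30 (a frontal clique); during the termination
window twenty frontal↔posterior pairwise couplings at rho 0.55, two per
frontal channel, injected sequentially (later injections attenuate earlier
pair correlations by √(1−w) per subsequent mixing, leaving all planted cross
pair correlations ≥ ~0.25, comfortably above r* ≈ 0.15).  A pre-run power
analysis sized these choices: ~45 planted ictal edges and ~20 planted
termination edges against ~1–7 spurious edges per segment at the 1% null
rate, so the dominance rule calls the planted labels with large margin, and
the planted termination strength (mean |R| ≈ 0.33) exceeds the ictal one
(≈ 0.27), the planted analogue of a gamma-band strength increase at seizure
termination.  The same design makes clustering fall (clique → near-bipartite
topology); path length rises, a property of the planted topology (a clique
has L = 1) rather than a target of the experiment.

## Numerical choices and degenerate inputs

Zero-variance signals raise `UndefinedCorrelationError` rather than yielding
NaN edges; |R| = 1 raises on the t-transform (divergent).  Identical paired
samples in the t-test report (t = 0, p = 1); constant nonzero differences
raise `DegenerateTestError`, and the pipeline records such tests as NaN,
never significant.  Variables fully explained by covariates get partial
correlation 0 by convention (residual norm below 1e-10 of the variable's
scale).  Correlations are clipped to [−1, 1] against rounding; L of an
edgeless network is NaN with a flag; sample indices are floor(t·fs) with
half-open intervals; event durations are validated with a 1 ns tolerance.

## Problem sizes

Module tests run on seconds-long, few-channel signals.  The bundled
experiments use: threshold calibration — 20 segments × 15 channels at
K = 18000; recovery — 20 replicate 33-seizure cohorts at 30 channels,
fs = 1200; null calibration — 30 replicate cohorts at 10 channels; the
stats-battery null calibration — 200 replicate 28-test families.  These sizes
were chosen so the whole validation suite runs on one CPU in minutes while
keeping binomial error bars well inside the asserted bounds.

## Known limitations

* The pattern rule's agreement with visual network reading is untestable
  without the original recordings; per-band published counts are context.
* Nominal-K thresholding is anti-conservative for band-limited data (above);
  results obtained with it should be read as dense-network summaries.
* The paired t-test treats the 33 seizures as independent although 11
  patients contribute two seizures each; a mixed model would be the stricter
  choice and is out of scope.
* Partial correlations on 22 patients have wide sampling error; the pipeline
  reports them with corrected p-values but draws no conclusions.
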