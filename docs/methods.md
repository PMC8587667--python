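# Methods

This note documents the models, numerical choices and limitations behind
`chromalink`, in the order the pipeline runs them.

## Synthetic fingerprints

A chromatogram is modelled as a sum of Gaussian peaks on a constant
baseline with i.i.d. Gaussian detector noise, clipped at zero. This is the
simplest model that exhibits everything the pipeline must cope with; it
deliberately omits peak tailing, baseline drift, and the mass-spectral
dimension (traces are 1-D, TIC-like).

Structure of one dataset (`SynthConfig`):

* **Peak positions and widths** are drawn once for a master template and
  shared by all groups — retention is a property of the compound, not the
  source. Positions are uniform over the trace (4% margins), widths
  uniform in `peak_width_range`, minor heights log-normal
  (median ≈ 20 intensity units, σ_log = 0.8).
* **Group identity** lives in the peak-height pattern: each group
  multiplies the master heights by `exp(inter_sd · z)` per peak. Each
  sample again multiplies its group's heights by `exp(intra_sd · z)`.
  Multiplicative log-normal jitter keeps heights positive and makes the
  zero-variance limits exact.
* **The dominant peak** (THC analogue) sits at a fixed common position
  (65% of the run) in every group, re-pinned per group to
  `dominant_peak_ratio` × median(minor heights). With the default ratio of
  40 it dominates the covariance of every pair of traces, producing the
  masking regime: unlinked samples correlate nearly as highly as linked
  ones until a root transform compresses the peak.
* **Retention shift** is a single global per-sample offset, Normal(0,
  `shift_sd` points), applied by linear-interpolation resampling of the
  whole trace — run-to-run drift, not per-peak movement.
* **Determinism.** All randomness flows from one seed through
  `SeedSequence` spawn keys (master template, per-group, per-sample), so a
  dataset is bit-reproducible and any single sample can be regenerated.

Default study conditions: 10 groups × 10 samples, 5231 points per trace,
30 peaks, intra_sd 0.12 / inter_sd 0.35, shift_sd 3, baseline 2, noise
0.5. These emulate the target study design (including the option of a
ragged 9×10 + 1×7 layout) and are chosen so that the intra- and
inter-source correlation distributions overlap partially — realistic for
an agricultural crop whose within-plantation variability is substantial.
Tests and the acceptance script run scaled-down instances (6–48 samples,
400–1200 points) chosen to preserve this structure; segment counts,
slack ranges and pair counts stay in the regimes the full design uses.

`plant_outliers` distorts chosen samples by a smooth multiplicative
log-normal gain field (unit-variance noise smoothed over ≫ one peak
width). The set being distorted no longer carries its generating template,
so the distortion acts on the rendered trace; because the field varies
slowly, it is equivalent to re-drawing peak heights from a perturbed
template, and `distortion = 0` is an exact identity.

What passing tests on these data do **not** show: robustness to peak
tailing or co-elution changes, detector saturation, baseline wander, or
non-global retention distortions. Conclusions about real GC data need real
GC data.

## Correlation-Optimized Warping

Segment scheme: the target trace of length *L* is cut into
*N* = ⌊*L*/SL⌋ segments with nodes at 0, SL, 2·SL, …, (N−1)·SL, L−1; the
final segment absorbs the remainder. Sample-side nodes move within
cumulative bounds so that each segment's length change is in [−SS, +SS]
and both trace end points are fixed. Warped segments are linearly
interpolated onto the target segment's grid (no extrapolation, so warped
values stay within the sample's range; first-order preservation of peak
shape and area). The benefit of a placement is the sum of per-segment
Pearson correlations; a zero-variance segment (flat baseline) contributes
r = 0 — it neither rewards nor penalizes flat-on-flat matches. The dynamic
program over node positions is exact; tests verify it against exhaustive
enumeration on small instances. Both traces must be ≥ 2·SL points.

Dataset alignment warps every sample to a reference — the sample with the
highest mean correlation to all others (ties → lowest index). Repeated
alignment (`rounds > 1`) re-selects the reference each round and feeds the
output of one pass into the next, exactly as a single pass treats raw
data.

### Choosing SL and SS

* **ACOW** maximizes the mean correlation of warped samples to the
  reference. This objective is a deliberate simplification of the
  composite "warping effect / simplicity" criterion of the automated-COW
  literature: it is monotone in what the study actually scores
  (correlation recovery) and keeps the automated search directly
  comparable with the factorial design. The search is a coarse integer
  lattice (up to 11 levels per factor — exhaustive on narrow ranges)
  followed by ±1 discrete-coordinate descent. The objective is rugged in
  SL because segment boundaries interact with peak positions, which is why
  the lattice is dense rather than 3×3. Everything is deterministic; ties
  keep the first-evaluated candidate.
* **DoE** runs a 3² full factorial at levels low/centre/high of the two
  range presets (SL 15–100 or 25–200, SS 1–10; centres are
  half-up rounded midpoints: 58 and 113). The response is the mean
  intra-group correlation after alignment. A six-coefficient quadratic
  response surface is fitted by least squares on coded levels (−1/0/1) for
  reporting; the returned optimum is the best *measured* design point, not
  the model optimum, because the experiment, not the fit, is the ground
  truth at nine runs.

## Pretreatments

All operate on the aligned sample × time-point matrix; standard deviations
use the n−1 denominator throughout. Row scaling ("normalization") divides
each trace by its own SD; SNV centres and scales each trace; both then
optionally column-centre (the composite order follows the method names:
transform first, CC second). Auto-scaling column-centres then divides by
column SD, leaving zero-variance columns at 0 rather than raising. Root
transforms clip negatives to zero before rooting — detector intensities
are physically non-negative and signed roots would manufacture structure;
no rescaling is applied around the root (the pure elementwise transform,
as in illicit-profiling practice). Excision removes a half-open column
window (the dominant-peak region) from every trace before any other step;
the window is supplied explicitly (an argmax-centred helper exists but is
never a default, since the peak is identified by an analyst).

## Similarity, thresholds, errors

Similarity is the Pearson r of two whole pretreated traces in data-point
index space — untargeted, no peak table. Pairs partition into intra- and
inter-source lists by label equality.

Linkage thresholds pool intra r across all groups: value = r̄ − z·s_r with
z = 1.96 (95% CL) and 2.576 (99% CL), Gaussian assumption, sample SD. No
t-correction is applied (the z values are the method's convention). Note
that these are two-sided quantiles used in a one-sided rule: on truly
Gaussian intra values the expected FN rate is 2.5% / 0.5%, not 5% / 1% —
the unit tests assert the mathematically correct calibration. A pair
exactly at the threshold counts as linked, which is conservative in the
direction that matters (it can only raise FP, never hide it).

ROC curves sweep all observed r values (scikit-learn's `roc_curve`);
AUC is trapezoidal and equals the rank statistic
P(r_intra > r_inter) + ½·P(equal), an identity the tests verify by brute
force. The AUC confidence interval is a stratified percentile bootstrap
(intra and inter resampled independently, default 2000 resamples, seeded)
— chosen for distribution-freeness since no CI method is canonical here.

Outlier flagging operationalizes colour-map inspection: a group member is
flagged when the median of its correlations to the other members falls
below (median of those medians) − max(k_mad · 1.4826·MAD, 0.01). The
absolute floor of 0.01 r-units keeps tightly-clustered homogeneous groups
(MAD ~ 10⁻⁴) from flagging members over practically meaningless spread;
k_mad defaults to 3. Flagging never removes — removal is an explicit
opt-in in the pipeline config.

## Cross-validation

LNO partitions the intra and inter r-value lists (not the samples) into 20
disjoint uniform folds — disjoint rather than independently resampled so
the 20 repeats process the entire dataset exactly once; the fold seed is a
required, logged input. LOPO holds out one group per fold; the test FP set
is every inter pair touching the held-out group (each inter pair is
therefore tested twice across folds), which makes every pair involving the
unseen source a genuine out-of-fold pair. Overall rates pool raw counts
across folds.

## Pipeline

`run()` chains the stages from one declarative config and persists every
intermediate plus a JSON manifest (version, config echo, chosen SL/SS,
flagged outliers, seeds). Outlier flagging runs on the raw data before
parameter optimization; default alignment is one ACOW round. The
THC-influence variant repeats the pretreatment sweep on the excised
matrix. Re-running a config reproduces every output byte-identically; the
manifest deliberately contains no timestamps.

## Known limitations

* The synthetic generator's realism limits (above) bound what the test
  suite demonstrates about instrument data.
* The ACOW objective deviates from the cited composite criterion (see
  rationale above); absolute (SL, SS) choices may differ from other COW
  implementations even where alignment quality does not.
* Thresholds assume Gaussian intra correlations; heavy left tails (e.g.
  unflagged outliers) inflate s_r and lower the threshold, trading FN for
  FP silently.
* With strongly pretreated data (column centring, auto-scaling) intra
  correlations can be small or negative, making r̄ − z·s_r thresholds
  meaningless in practice even though they are computed faithfully.
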