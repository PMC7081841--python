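# Methods

## Scope and model

MSAP profiles CCGG-site cytosine methylation by comparing two double digests
of the same DNA: EcoRI+HpaII (EH) and EcoRI+MspI (EM). HpaII will not cut
when the internal cytosine is methylated on both strands; MspI will not cut
when the external cytosine is hemi-methylated. The per-locus band-presence
pair therefore carries the methylation call: EH+/EM+ → type I
(unmethylated), EH+/EM− → type II (hemi-methylated), EH−/EM+ → type III
(fully methylated), EH−/EM− → type IV (uninformative: the site may be
absent, mutated, or methylated in a pattern blocking both enzymes — it is
counted for QC but excluded from every ratio denominator).

Ratios use only informative bands: hemi = n₂/(n₁+n₂+n₃), full =
n₃/(n₁+n₂+n₃), total = (n₂+n₃)/(n₁+n₂+n₃). The total is computed in that
pooled-count form (not as hemi + full) so the identity total ≡ hemi + full
holds to full precision. Group summaries sum counts over individuals and
recompute ratios from the pooled counts; this equals the
informative-band-weighted mean of the individual ratios and is the
convention that reproduces published pooled percentages from pooled type
counts exactly.

## Fragment binning

Sizes from all samples and both digests are pooled, sorted, and split into
bins wherever the gap between successive sizes exceeds 2 × `half_width_bp`
(single-linkage clustering in 1-D). The bin's nominal size is the mean of
its member sizes. Chaining can stretch a bin slightly past ±half-width
around its mean, so the fitted assignment intervals keep each bin's observed
extent (expanded to at least ±half-width); intervals remain pairwise
disjoint, and every peak used in fitting maps back to exactly one bin.
Multiple peaks of one sample in one bin collapse to a single presence call.
A sample with records for only one digest is excluded with a warning rather
than scored as all-absent, since an absent digest is a failed lane, not
evidence of methylation.

Defaults — analysis window 50–500 bp, tolerance ±0.5 bp, minimum height
50 RFU, minimum one sample per locus — follow common CE fragment-analysis
practice; all are exposed as options and none is claimed to reproduce any
particular study's locus count, which depends on instrument and scoring
software settings.

## Synthetic cohorts

The simulator draws what the scorer assumes: per-individual, per-locus
states sampled i.i.d. from `state_probs` (default 0.70/0.12/0.18/0.00 for
unmethylated/hemi/full/uninformative, close to pooled control-group type
frequencies in decapod hepatopancreas screens); locus positions uniform in
the size window conditioned on a minimum spacing (drawn by the slack-and-
shift construction, which is exact and O(n)); the deterministic state→(EH,
EM) mapping above; and CE noise on top — Gaussian size jitter (default
0.15 bp SD), per-band dropout (default 2%), log-normal peak heights
(log-mean 7.0, log-SD 0.6, i.e. median ≈ 1100 RFU), and Poisson spurious
peaks (default 1 per sample × digest) uniform in the window.

Choices worth recording:

* **Minimum locus spacing** defaults to `4·jitter_sd + 1` bp so neighbouring
  loci are separable at the default binning tolerance. With ten samples per
  locus the extreme jitter draws can still close a gap occasionally, merging
  two adjacent bins; at default noise this is rare and its effect on pooled
  ratios is well inside the Monte Carlo scatter (it pulls the estimate
  slightly toward type I, i.e. downward).
* **Size range** defaults to 50–1000 bp: 500 loci at 1.6 bp minimum spacing
  need ~800 bp of span, which a 50–500 bp window cannot hold; 50–1000 bp
  corresponds to CE runs with a long size standard.
* **Dropout is not neutral.** Dropping one band of a type-I locus fabricates
  a type II or III call, so small dropout *inflates* the apparent
  methylation ratio; dropping the single band of a type II/III locus removes
  it from the denominator. For per-band dropout d and cell probabilities
  (p₁, p₂, p₃) the expected observed ratio is
  `(p₁d(1−d)·2 + (p₂+p₃)(1−d)) / (p₁(1−d)² + 2p₁d(1−d) + (p₂+p₃)(1−d))`
  — about 0.3235 for d = 0.02 at the default frequencies, against a true
  0.30. The recovery tests check the estimate against both the generating
  value and this closed-form prediction.
* **Per-individual overdispersion** (`individual_effect_sd`) adds a
  logit-normal shift to each individual's methylated fraction among
  informative states, emulating the high between-individual methylation
  diversity seen in outbred invertebrate cohorts. It is off by default
  because no variance model is standard; the hemi/full split and the
  uninformative fraction are held fixed under the shift.
* **Seeding.** Locus sizes, states, and peak noise each draw from their own
  `SeedSequence(seed, spawn_key=(stage,))` substream, so every stage — and
  therefore every output file — is a pure function of (config, seed).

What the simulator does **not** emulate: signal-level electropherograms
(pull-up, stutter, saturation), size-standard miscalibration, fragment-length
dependent amplification bias, or linkage between nearby loci. Passing the
recovery tests therefore shows the scoring arithmetic and binning logic are
sound under idealised CE noise, not that any particular instrument's peak
calls are unbiased.

## Group statistics

One-way ANOVA and Tukey's HSD (studentized-range adjusted pairwise
p-values) wrap the standard scipy routines behind a validated interface;
groups need ≥ 2 observations, all-identical data raise a degenerate-data
error rather than returning NaN, and ANOVA on two groups equals the pooled
t-test (F = t²). For two-group comparisons at n ≈ 10 per group a seeded
permutation test on the mean difference is provided: two-sided p =
(1 + #{|Δ_perm| ≥ |Δ_obs|}) / (n_perm + 1) (the add-one estimator, never
exactly zero). When the number of distinct splits is at most `n_perm` the
test enumerates all splits and returns the exact p without the add-one
term. The Monte Carlo sampler works on the sorted pool and always resamples
the smaller group, making the p-value invariant to swapping the group labels
at a fixed seed; it is also invariant to adding a constant to all
observations. Note the |Δ|-counting two-sided rule differs from doubling the
smaller one-sided tail (scipy's convention) by at most a few ties.

Ratios are compared untransformed by default; an arcsine-square-root helper
is available for users who prefer variance stabilisation of proportions.
Methylation-ratio comparisons between groups use per-individual ratios as
the unit of analysis (n = individuals per group). Default α = 0.05.

## Assay calculators

* **2^−ΔΔCt.** Replicate Cqs are averaged arithmetically per (sample, gene);
  ΔCt = Cq_target − Cq_reference per sample (reference default EF1-α);
  ΔΔCt subtracts the control-group mean ΔCt; fold = 2^−ΔΔCt. Per group the
  report carries the mean ΔΔCt (whose 2^−· is the geometric-mean fold) and
  the arithmetic mean ± SD of per-sample folds, the conventional
  presentation. No amplification-efficiency correction is applied — the
  model is the pure 2^−ΔΔCt method.
* **Apoptosis index.** AI = Σpositive / Σtotal pooled over a sample's
  microscope fields (robust to unequal cell totals per field and invariant
  to splitting a field), and the group AI is the mean over samples.
* **Cumulative mortality.** 100 × cumulative dead / initial cohort size,
  monotone non-decreasing by validation. The denominator is uncorrected for
  animals removed at sampling points by default (the convention that makes
  9/200 = 4.5%); `sampled_per_timepoint` enables a corrected denominator.
* **T-AOC.** U/mg protein = (ΔA/min) / 0.01 / mg protein, directly from the
  unit definition. Heart rate and lactate need no bespoke computation and
  are treated as pass-through measurements.

## Numerical and design notes

* Peak tables round-trip bit-exactly: CSV floats are written by shortest
  repr and parsed with pandas' `round_trip` converter.
* Binning is permutation-invariant (a stable sort precedes clustering) and
  presence is monotone in the height threshold.
* Undefined ratios (no informative band) are NaN with a `defined` flag, not
  zero.
* Test problem sizes (cohorts of 10 × 500 loci, 5–20 seeds, 1000 null
  replicates at 199 permutations) keep the full suite and the acceptance
  script to roughly two minutes combined while leaving Monte Carlo standard
  errors well below the tolerances being checked.
* The CLI is a thin layer over the library; every run writes a
  `provenance.json` sidecar (parameters, seed, input SHA-256, version) and
  reruns with an identical sidecar produce byte-identical outputs.

## Limitations

Real MSAP panels add biology the scorer cannot see: restriction-site
polymorphism masquerading as type IV, comigrating non-homologous fragments
in one bin, and partial digestion. The simulator's i.i.d. states and
independent dropout are deliberate simplifications; recovery under them
bounds the pipeline's arithmetic, not field performance. Per-individual
published ratios are generally not reproducible from pooled counts, and no
outlier rule is applied to "abnormal" individuals — QC output flags them for
the analyst instead.
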