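# Methods

## The statistical picture

A functioning circadian clock makes the joint distribution P(t, g) of clock
time t and panel expression state g highly structured: conditional on t the
state is unimodal around a point on a closed daily cycle, and the
stochasticity of the oscillator plus measurement noise gives the
conditional covariance rapidly decaying eigenvalues.  `chronotell`
estimates P(g|t) from a training timecourse and, because sampling times are
uniform over the day, reads P(t|g) for a new sample off the same object up
to normalisation.  Everything the package reports — the internal phase T,
the maximum likelihood ML, the dysfunction score Θ — is a functional of
this estimated likelihood curve.

## Model construction

**Normalisation.**  Three modes, chosen per dataset:

* *timecourse* — each (instance, gene) training series standardised to
  mean 0, SD 1 (sample SD, ddof = 1 throughout).  The offsets and scales
  are stored as a recipe; test samples from a known instance are
  normalised with the training statistics (*timecourse-matched*).  Test
  data that themselves form a full series per instance can instead be
  standardised by their own series (`self_timecourse_normalise`), the
  right choice across platforms or batches and the convention used inside
  leave-one-out cross-validation, where normalisation is computed once on
  the full series before the model-fitting split.  Self-series
  standardisation presupposes a rhythmic series: for arrhythmic data (a
  stopped clock) only matched or intergene normalisation is meaningful.
* *intergene* — each sample's G-vector standardised across its entries,
  which maps the vector onto its shape and removes per-sample affine
  distortions; the only option when no training series exists for the
  sample's instance.
* *both* — timecourse first, then intergene per sample.

**Local projections.**  At each training timepoint t_i the N_s normalised
vectors are centred and their top d = 3 principal directions U_i extracted
(numpy SVD; component signs fixed so the largest-magnitude loading is
positive, making archives byte-reproducible).  Projection of data is the
plain linear map U_iᵀg — centring affects only which subspace is chosen,
not the evaluation geometry.  d = 3 presumes the residual covariance is
dominated by a few shared directions; the synthetic generator reproduces
exactly that regime (low-rank factors + diagonal noise).

**Per-time Gaussians and splines.**  All training data are projected
through each U_i and a Gaussian (sample mean, ddof-1 covariance) is fitted
per training time j.  Two regularisations protect small N_s: a ridge of
τ·trace/d (τ = 1e−4) when the covariance condition number exceeds 1e8, and
— crucial in the noiseless limit — a data-scale ridge τ·mean(P²) when the
covariance is at round-off level, since a trace-proportional ridge on a
numerically-zero matrix is itself zero and lets floating-point noise
dominate the quadratic form.  Means (d channels) and the d(d+1)/2 distinct
covariance entries are interpolated over the day by a periodic
shape-preserving cubic (PCHIP with Fritsch–Carlson derivative limiting,
made periodic by three-period knot replication; derivatives are local
two-slope quantities, so the central period is exactly periodic and C¹ at
the seam).  Entrywise covariance interpolation can leave matrices
indefinite between knots; a batched eigenvalue screen over the evaluation
grid repairs offenders by clipping eigenvalues at 1e−8·trace/d, and the
repair count is reported on the fitted model.

**Evaluation grid.**  1440 points (1-minute resolution) by default.  Θ is
a proportion of the day, so the grid bounds its discretisation error at
1/1440 ≈ 0.07%; the grid is configurable.

## Single-sample inference

Per timepoint family the log-density of the projected sample is evaluated
on the grid (cached Cholesky factors; vectorised over samples).  The
combined curve is the mean over the N_t per-timepoint curves after flooring
each at l_thresh; the floor prevents one family's unreliable extreme-low
density from destroying another's confident high density at the same t,
and makes ML monotone in l_thresh by construction.  T is the grid argmax
(earliest on ties, with `flat_curve` / `multimodal` flags rather than
silent tie-breaking); ML = exp(max).

**Θ.**  The likelihood-ratio curve (max 1) is compared with
C(t|T) = η(1 + ε + cos 2π(t−T)/24), with the constraint
0 < ηε < η(2+ε) < 1 so C's trough is positive and its crest below 1.
Defaults η = 0.35, ε = 0.15 (crest ≈ 0.75, trough ≈ 0.05); exceedance is
strict, so a curve exactly on C does not count.  Keeping η, ε fixed across
datasets is what makes Θ values comparable between cohorts.

**Peaks and re-timing.**  Local maxima on the circular grid count as peaks
when they rise above C at their own location (an absolute prominence
threshold is available); plateaus count once, and a peak split across the
24→0 seam is detected once.  `adjust_time_by_second_peak` implements the
cohort-level correction of re-timing samples that fall in a configured
implausible window (e.g. before 07:00) by their second-highest peak.

**Choosing l_thresh.**  `choose_lthresh` returns the largest candidate such
that (i) at most 5% of training/control profiles have floored (flat)
stretches rising above C — flat regions contribute to Θ in a way that
encodes low ML, and should be rare in healthy data — and (ii) at least 90%
of test samples have log ML above the candidate.  When the two conditions
conflict it returns the candidate maximising (ii) subject to (i), plus the
full trade-off table.  The "flat region intersecting C" test is
operationalised as: any grid point within 1e−9 of the floor whose LRF value
exceeds C.

**Dysfunction taxonomy.**  Relative to training quantiles stored in the
model archive: `lowML` (ML below the 1% training quantile — the state is
off-manifold), `highTvar` (Θ above the 99% quantile with a non-flat
contribution: secondary peaks or a broad main peak), `relTwrong`
(circular timing error beyond 4 h while neither of the above holds —
a clock that confidently reports the same wrong time, the signature of an
oscillator frozen on its cycle).  `relTwrong` needs the true collection
time and is skipped with a notice otherwise.

## Cohort analyses

All timing arithmetic is circular: signed errors T − T_a live in
(−12, 12] (with +12 preferred at the antipode) and group displacements are
circular means via the resultant vector, flagged undefined when the
resultant length is below 0.1.  Leave-one-out cross-validation removes one
sample or one whole instance per fold and refits the model; the per-group
circular mean of signed errors is the *timing displacement* (per
individual: the molecular chronotype), and corrected errors are computed
against T_a shifted by the group displacement.  Group comparisons use the
two-sided Wilcoxon rank-sum test, which is invariant to monotone
transforms of ML.

**Cosinor and PDP.**  Gene rhythms are fitted by the linearised cosinor
(intercept + cos/sin design, least squares), reporting mesor, amplitude,
peak-time acrophase in [0, 24), and the F-test of the harmonic pair.
Phase-displacement (PDP) regression fits per-gene acrophase against group
displacement by OLS after unwrapping each gene's phases toward its
circular mean (a ±24 h adjustment; genes whose unwrapped spread still
exceeds 6 h are flagged but reported).  A slope near ±1 with high r²
indicates the group differences are a coherent phase shift of the whole
panel; with the peak-time acrophase convention used here a coherent
*advance* of the clock shifts acrophases opposite in sign to the timing
displacement, so the magnitude, not the sign, carries the coherence
information.

**Θ stratification.**  Given a pluggable differential-expression test
(default: per-gene rank-sum with Benjamini–Hochberg at 0.05 — deliberately
simple, not a moderated-statistics reproduction), `theta_stratify_and_resample`
estimates p_rand(m) — the chance of m or more DEGs between a random group
of size n and the rest — against p_Θ(m), where the group is the n worst
clocks by Θ at an l_thresh drawn randomly per iteration from a configured
range (so the conclusion is robust to both choices).  Both curves are
non-increasing step functions of m and come with binomial Monte-Carlo
standard errors.

**Precision without time stamps.**  Samples whose estimated T falls in a
window are projected onto the first principal component of their
expression; a Gaussian-kernel local-linear smooth (Silverman bandwidth on
T; the degree-1 refinement of a Nadaraya–Watson smooth, chosen because the
degree-0 estimator's O(bandwidth) boundary bias would contaminate the
deviations at the window edges) gives the mean curve of the projection
against T.  Each sample's horizontal deviation from the curve (nearest
preimage on a 481-point window grid) estimates its timing scatter, and the
deviation SD upper-bounds the SD of P(T|g).  The curve must be monotone
over ≥ 80% of the window, and at least 30 samples are required.

## The synthetic generator

`ClockSimConfig` defines the study conditions used throughout the tests:
G = 12 genes, N_t = 6 timepoints 4 h apart, N_s = 12 instances; amplitudes
0.6–1.8 (log-scale units), acrophases evenly spread, mesor 7, a 20% second
harmonic (so the cycle is a genuine 2-harmonic limit curve, not a pure
sinusoid); residual noise is 2 shared Gaussian factors at SD 0.10 plus
diagonal SD 0.15, reproducing the low-rank-plus-diagonal covariance the
d = 3 projection assumes.  A chronotype offset δ is a clock *advance*:
the instance's state at external time t is the reference state at t + δ,
so estimated phases lead collection times by δ and fitted acrophases shift
by −δ.  Perturbation archetypes: coherent `phase_shift`,
`amplitude_collapse` (ρ < 1 ⇒ lowML), `gene_knockout` (one gene arrhythmic),
`phase_scramble` (incoherent per-gene offsets ⇒ highTvar) and
`frozen_clock` (every sample at one phase ⇒ relTwrong).  Perturbations
regenerate from the source config with the same noise stream, so a zero
perturbation is the exact identity.

What the generator does **not** emulate: platform/batch effects, count
noise (values are Gaussian on a log-like scale), non-sinusoidal waveform
asymmetries beyond the second harmonic, missing data, or inter-gene
correlation that varies with time of day.  Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
model's own assumptions, not performance on any real platform.

## Problem sizes and numerical choices

The test suite and acceptance script run at the generator's native scale
(72-sample cohorts, 1440-point grids, 20 random model refits, 500-rep
regression nulls, 200-sample precision fixtures) — sizes chosen so every
check completes in seconds while keeping estimator noise well below the
asserted margins.  Determinism: every stochastic step takes a
`numpy.random.default_rng` seed; model archives are JSON with sorted keys,
so refitting the same data yields byte-identical files.  Degenerate inputs
are handled explicitly rather than silently: constant series, constant
REVs, rank-deficient projections, coincident Gaussian clusters, all-floored
likelihood curves, singleton groups and non-monotone precision curves each
raise or flag as documented above.

## Known limitations

* Timecourse-matched normalisation restricts test data to instances present
  in training; intergene mode is the fallback and is less accurate.
* With N_s near d the per-time covariances are noisy; the ridge keeps them
  usable but ML values from sparsely-replicated training sets should be
  compared only within, not across, models.
* Θ integrates several dysfunction modes (broad peaks, secondary peaks,
  floored flats) into one number; the flags and the peak list should be
  inspected alongside it.
* The likelihood curve is not a calibrated posterior: no confidence
  interval for T is reported, and Θ is the exposed uncertainty statistic.
* The second-peak re-timing rule is a cohort-level heuristic requiring an
  a-priori implausible window; it is recorded on the profile whenever
  applied.
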