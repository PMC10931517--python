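# chronotell

Estimate the internal circadian phase of a **single transcriptomic sample**
and quantify how well its molecular clock is working.

Tissues keep 24 h time through a transcriptional oscillator; a panel of
core clock genes (*Arntl*, *Per1/2/3*, *Nr1d1/2*, *Cry1/2*, ...) traces a
closed curve in expression space once per day.  Given a training timecourse
(expression of the panel sampled around the clock in several tissues or
individuals), `chronotell` builds a time-indexed probabilistic model of that
curve and then, for any new sample — one patient biopsy, one mouse liver —
reads off:

* **T**, the internal phase: the clock time the transcriptome says it is;
* **ML**, the likelihood at T: how close the sample lies to the trained
  clock manifold (low ML = the clock state is abnormal);
* **Θ**, a dysfunction score in [0, 1]: the fraction of the day the
  likelihood-ratio curve stays above a cosine reference, capturing
  imprecise or multimodal timing (high Θ = unreliable clock).

Cohort-level tools build on these single-sample readouts: cross-validated
timing errors, per-individual *timing displacement* (molecular chronotype)
with error correction, phase-displacement regression (is a group difference
a coherent phase shift of the whole clock?), Θ-stratified
differential-expression resampling, and a precision estimator that needs no
time stamps at all.

## The model

Training samples at times t_i (N_t timepoints, N_s instances each) are
normalised (per-series *timecourse* standardisation, per-sample *intergene*
standardisation, or both) into rhythmic expression vectors g over the G
panel genes.  For each timepoint the local top-3 principal subspace U_i is
extracted, all data are projected through it, and a multivariate normal
N(μ_{i,j}, Σ_{i,j}) is fitted per training time.  Periodic shape-preserving
cubic splines through the means and the d(d+1)/2 covariance entries extend
each family to all times of day (with eigenvalue-clipping repair wherever
interpolation leaves a covariance indefinite), giving MVN families
P_{i,t}.  A test vector's likelihood curve is the truncated average

    log L_g(t) = (1/N_t) Σ_i max{ log P_{i,t}(g), l_thresh },

whose argmax is T and maximum is ML.  The likelihood ratio
R_g(t) = L_g(t)/L_g(T) is compared with C(t|T) = η(1 + ε + cos 2π(t−T)/24);
Θ is the fraction of the day with R_g(t) > C(t|T).  Defaults: d = 3,
l_thresh = −5, η = 0.35, ε = 0.15, 1-minute evaluation grid.

## Worked example

Everything below runs on synthetic data generated by the package itself
(cosinor-shaped genes, correlated residual noise, optional chronotypes and
perturbations):

```python
from chronotell import (ClockModel, ClockSimConfig, simulate_training,
                        leave_one_out)

es = simulate_training(ClockSimConfig(seed=7))      # 12 genes x 72 samples
model = ClockModel().fit(es)

test = simulate_training(ClockSimConfig(seed=8))    # an independent cohort
profile = model.score_samples(test.subset_samples([30]))[0]
print(profile.t, profile.ml, profile.theta)

loo = leave_one_out(es)
print(loo["abs_error"].median())
```

Output:

```
sample s_t2_inst06: collected at t = 8.0 h
  internal phase T = 7.72 h
  ML = 0.192   log ML = -1.650
  theta = 0.0375   peaks = 1
leave-one-out median |T - T_a| = 0.342 h over 72 samples
```

The sample collected at 8.0 h is timed at 7.72 h — a 17-minute error — with
a single likelihood peak and a low Θ, i.e. a healthy, precisely-timed
clock.  Leave-one-out over the whole cohort confirms ~20-minute median
accuracy under moderate noise.

A command-line interface wraps the same pipeline:

```bash
chronotell simulate --out-dir data --seed 3
chronotell train    --matrix data/expression.tsv --metadata data/metadata.tsv --out model.json
chronotell test     --model model.json --matrix data/expression.tsv \
                    --metadata data/metadata.tsv --out scores.tsv
chronotell crossval --matrix data/expression.tsv --metadata data/metadata.tsv --out-prefix cv
chronotell pdp      --matrix data/expression.tsv --metadata data/metadata.tsv \
                    --displacements cv.displacements.tsv --out pdp.tsv
```

## Layout

| module | contents |
| --- | --- |
| `chronotell.dataset` | `ExpressionSet`, `GenePanel`, TSV/CSV I/O, rhythmicity ranking |
| `chronotell.normalize` | timecourse / intergene / combined recipes, `ClockNormalizer` |
| `chronotell.spline` | periodic PCHIP interpolation, nearest-PD repair |
| `chronotell.model` | local PCA, per-time MVN fits, `ClockModel` (fit / predict / score_samples / save / load) |
| `chronotell.profile` | likelihood curves, T/ML/Θ, peaks, l_thresh selection, dysfunction flags |
| `chronotell.cohort` | leave-one-out CV, timing displacement, cosinor, PDP regression, Θ stratification, precision |
| `chronotell.simulate` | synthetic cohorts and perturbation archetypes |
| `chronotell.cli` | `chronotell` command |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
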