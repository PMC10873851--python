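# Methods

This note documents the model, the numerical choices and the design
decisions behind `mstates`, and what the synthetic validation does and
does not establish.

## The microstate model

Multichannel resting EEG is modeled as a sequence of discrete states:
at any instant the scalp potential field is (up to amplitude and
polarity) one of K fixed topographies `a_1 … a_K`, each zero-mean
across channels and unit L2 norm. Polarity is not part of a state's
identity — the same generator configuration produces fields of both
signs as the underlying oscillation swings — so every comparison
between maps uses the absolute spatial correlation, i.e. the Pearson
correlation across channels of the two channel-demeaned maps.

**GFP and peaks.** Global field power is the per-sample *population*
standard deviation across channels (the sample/population distinction
is a pure scale factor with no effect on peak locations; population is
used and documented here). After average-referencing, GFP equals the
RMS across channels. Topographies at strict interior local maxima of
the GFP have the best signal-to-noise and form the clustering
substrate. Plateau maxima contribute their first sample only
(deterministic and order-independent); peaks on masked samples are
dropped; series endpoints are never peaks.

**Clustering.** Modified k-means alternates (1) winner-takes-all
assignment by `|corr|` and (2) template update as the dominant
eigenvector of `Σ u_t u_tᵀ` over assigned maps (GFP-weighted in the
normalized formulation, which is equivalent) — the polarity-invariant
centroid. Convergence is declared when GEV improves by less than 1e-6;
at most 300 iterations; 50 restarts by default. Each restart clusters a
random 90% subsample of the peak maps (a stability device), candidates
are scored by full-set GEV, and the winner is refit on the full set.
Empty clusters are reseeded from the currently worst-fitted map. For
tiny inputs (partition count `k^n ≤ 8192`) the restarts are replaced by
one run initialized from the centroids of *every* partition; since both
k-means steps are monotone in GEV, the best run then provably attains
the exhaustive-partition optimum — this is what the brute-force
equivalence test exercises.

**Model order.** For each K in 1…12 the pipeline reports GEV and the
predictive-residual criterion
`σ̂² · ((C−1)/(C−1−K))²`, `σ̂² = Σ_t (‖u_t‖² − (a_{L_t}ᵀu_t)²) / (T(C−1))`
(C = channels). Spatially correlated residuals — real sensor noise is
spatially smooth — flatten this criterion beyond the true order, so the
bare argmin over-selects; the selection therefore uses a parsimony
rule: the smallest K whose criterion lies within 5% of the minimum.
A `force_k` override exists because automatic selection on real data is
never fully settled.

**Two-level clustering.** Stage 1 clusters each subject ×
condition's GFP-peak maps into K templates; stage 2 clusters the pooled
subject templates (each unit-norm, hence equally weighted) with the
same algorithm. Group classes are paired across conditions by
maximizing total `|corr|` with the Hungarian algorithm (greedy pairing
can mispair near-degenerate maps).

**TANOVA.** Each subject's class map is L2-normalized; the statistic is
the GFP of the difference between the two condition grand means; the
null swaps the condition assignment within subject. For n ≤ 12 subjects
all 2ⁿ swap patterns are enumerated and the p-value is the exact
proportion of null statistics ≥ observed; otherwise Monte-Carlo with
the positively biased estimator `(count + 1)/(n_perm + 1)`, which keeps
the test level-correct.

**Backfitting and parameters.** Every unmasked sample is labeled by
winner-takes-all `|corr|` (ties to the lowest class index; zero-variance
samples get class 0 with fit 0). No temporal smoothing and no
minimum-duration rejection are applied by default; a `peaks_only` mode
(label GFP peaks, propagate to the nearest peak) exists for sensitivity
analysis. A *run* is a maximal constant-label stretch of contiguous
unmasked samples. Runs touching an epoch edge or a mask boundary censor
the true dwell time: they are excluded from mean duration but kept in
coverage (coverage must be conserved; censored runs still occupy time).
A class observed only in censored runs reports their mean length with a
`censored` flag (a single-class epoch therefore reports the full epoch
length, flagged). Coverage is per class the share of *labeled* samples,
so coverages sum to one exactly.

**Statistics.** The class × condition repeated-measures ANOVA uses the
conventional within-subject sums-of-squares decomposition with
uncorrected degrees of freedom (no sphericity correction by default);
it is computed through `statsmodels.AnovaRM` and cross-checked in the
tests against an independently coded sums-of-squares oracle at 1e-9.
Note that for compositional parameters (coverage sums to one) the
condition main effect has a structurally zero error stratum and is
reported as NaN; the interaction — the quantity of interest — is
unaffected. Paired contrasts are two-tailed paired t tests; Cohen's d
uses the pooled SD of the two condition samples,
`mean(x−y) / sqrt((var(x)+var(y))/2)`, with the difference-score dz
reported alongside (reported effect sizes in this literature are closer
to the pooled form). The Bonferroni family is the class × parameter set
of contrasts with threshold `α/m` by default and a configurable preset
override. Trait correlations are Pearson r with t-based two-sided p
(df = n−2), corrected by Benjamini–Hochberg step-up across the declared
family (the plain BH variant; no dependency correction). The
neuroticism score sums 8 Likert items in [1, 5] after mapping
reverse-keyed items x → 6−x, giving the instrument range [8, 40];
odd-even reliability is the Pearson r between odd-item and even-item
sums.

## Filters

The band-pass is a zero-phase (forward–backward) Kaiser-window FIR,
designed for 60 dB stopband attenuation with a 2 Hz transition width —
phase distortion would corrupt topographic timing, which is the
quantity of interest. The notch is a zero-phase IIR second-order
section with quality factor 30. Downsampling low-passes at 80% of the
target Nyquist and decimates by the integer factor; the artifact mask
is decimated with a logical OR over each window so any artifact taints
its output sample.

Band-pass application is a configuration flag (`apply_bandpass`,
default off for cohort analysis). Raw laboratory recordings need it;
the synthetic cohorts are already band-limited, and zero-phase
filtering of a signal whose topography switches abruptly rings at the
state transitions and measurably shortens apparent durations even in
the noiseless limit. Real microstate transitions tend to coincide with
GFP troughs (small discontinuities); the generator does not enforce
that, which is a known limitation noted below.

## The synthetic generator

The generator's purpose is statistical, not biophysical: it produces
data with exactly the structure the analysis assumes, with every
generative parameter known.

* **Montage** — Fibonacci lattice on the upper unit hemisphere,
  8–256 channels (default 32; the algorithms are channel-count
  agnostic, and 32 keeps desk-scale runs fast).
* **Templates** — smooth random fields (Gaussian spatial kernel,
  length 0.6 chord units) orthonormalized and blended with one shared
  component so every template pair has spatial correlation 0.25 —
  separated, but not implausibly orthogonal.
* **State sequence** — semi-Markov: dwell times are discrete gamma with
  shape 2 (avoids the geometric law's excess of 1-sample states, which
  the backfitter must nonetheless handle) and the per-class mean
  (default 75 ms); consecutive states always differ; transition weights
  are solved by a multiplicative fixed point so the embedded chain's
  stationary visit rates reproduce the target coverages (default equal;
  with K = 2 visits necessarily alternate and coverage is set by the
  dwell ratio alone).
* **Rendering** — `amplitude · |carrier| · s(t) · template[state]` with
  a 10 Hz sinusoidal carrier whose polarity flips each half-cycle, so
  each state's map is constant up to sign. The carrier phase is offset
  by half a sample step, keeping envelope zeros off the sample grid
  (at an exact zero the topography is undefined). Sensor noise is
  temporally white and spatially smooth (same kernel as the templates),
  scaled to a signal-to-noise amplitude ratio; output is
  average-referenced.
* **snr default 12** — a calibration constant, not an empirical claim:
  duration recovery saturates above snr ≈ 12, while below ≈ 10 the
  near-trough samples flip labels often enough to bias durations
  downward by 15–20%. Template and coverage recovery are robust from
  snr ≈ 4.
* **Cohort** — defaults mirror a realistic resting-state design:
  36 subjects, 6 epochs × 45 s per condition at 200 Hz; an integer
  trait score drawn uniformly in [8, 40] (the instrument's range,
  without asserting a population distribution); fear-condition effects
  of −15%/+15% on class C/D duration and coverage; trait slopes of
  +0.005 (class C) and −0.008 (class D) per unit of the centered trait;
  and a 10% lognormal per-subject baseline jitter per class, shared
  across conditions. The last three are calibrated so that a
  study-scale cohort exhibits trait correlations around +0.4 (C) and
  −0.6 (D) and split-half reliabilities above 0.7 — the magnitudes this
  kind of study reports. After perturbation, coverages are renormalized
  by scaling the untargeted classes proportionally, preserving the
  sum-to-one invariant while keeping the targeted effects
  interpretable.

**What passing tests show — and what they do not.** The validation
demonstrates that the pipeline recovers templates, model order,
durations, coverages, effect directions and reliabilities from data
that satisfy the microstate model. Real EEG adds everything the
generator omits: broadband and nonstationary spectra, artifacts beyond
a boolean mask (the mask stands in for ICA-based removal and
interpolation, which are out of scope), volume-conduction structure,
imperfectly stable topographies, and transitions co-occurring with GFP
troughs. Recovery here is therefore a necessary check, not evidence
about effect sizes or reliabilities in real recordings.

## Scaled-down problem sizes

Desk-scale validation uses reduced designs, chosen once: recovery runs
on 20 cohorts of 6 subjects with 2 × 10 s epochs per condition;
directional-effect recovery on 50 cohorts of 36 subjects with 2 × 15 s
epochs (the study-scale subject count is kept because correlation signs
at realistic effect sizes are unstable in very small samples);
permutation-test calibration on 500 null datasets of 10 subjects at
199 permutations. The acceptance script uses the same scales slightly
reduced. Full-scale defaults remain the generator's defaults.

## Degenerate inputs and tie-breaks

Zero-variance maps raise on correlation; zero-variance samples backfit
to class 0 with fit 0; assignment ties break to the lowest class index;
flat GFP plateaus peak at their first sample; a constant nonzero paired
difference yields a flagged degenerate t result (identical samples
yield t = 0, p = 1, d = 0); missing ANOVA cells and channel-count
mismatches raise with both sides named.

## Known limitations

* No temporal smoothing or minimum-duration criterion in the default
  backfit; single-sample states are reported as observed.
* The exact TANOVA mode is capped at 2²⁰ enumerations; beyond that,
  Monte-Carlo only.
* The generator's state switches can occur at any carrier phase, which
  makes sharp re-filtering of rendered data inadvisable (see Filters).
* EDF support is read-only, through MNE.
* No alternative clustering families (agglomerative, PCA-based) and no
  occurrence-rate / transition-matrix reporting surface in v1 (they are
  computable from segmentations but not exposed as results).
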