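# Methods

`popsignal` implements a read-out model of parallel spike trains: a
hypothetical read-out neuron receives the spikes of a recorded
population through a set of synaptic weights, and those weights are
assumed to be tuned for the binary task the circuit solves
(discriminating "match" from "non-match" trials).  The package learns
the weights, reconstructs the resulting single-trial population signal,
and provides the statistical machinery (permutation nulls, perturbation
analyses, cross-correlations, laminar assignment) to interrogate it.

## Data model

Spike trains are binary tensors `o[n, j, k]` over neurons n, trials j
and 1-ms bins k, with per-trial labels y ∈ {−1 ("non-match"),
+1 ("match")}.  The default analysis window is [0, 400) ms after
stimulus onset (K = 400 bins, 0-based, half-open), analyzed separately
for the "target" and "test" stimulus presentations.  Only the test
window carries task information, which is the built-in negative
control: every analysis should come out flat on the target epoch.

The population PSTH is the neuron- and trial-average of `o`, smoothed
with a discrete Gaussian kernel of variance 10 ms² on support ±10 ms,
pre-normalized to unit sum (edges are zero-padded, so the outer ~10
bins are slightly attenuated).

## Decoding weights

Features are spike counts per neuron and trial over the window,
z-scored per neuron (sample variance, ddof = 1 — the convention is
exposed as an argument).  Z-scoring statistics are estimated on the
training trials and applied unchanged to validation trials
(`zscore_scope="train"`, default) to avoid leakage; pooling over all
trials is available as `"all"` since either convention is defensible
for this statistic.  Neurons with zero count variance get z-scores of
0 and stay in the population, keeping the neuron dimension stable.

Multivariate weights are the feature weights of a soft-margin linear
SVM (hinge loss + ½‖w‖², `sklearn.svm.SVC(kernel="linear")`, tolerance
1e-6 — the libsvm solver is deterministic, so weights are reproducible)
trained on the z-scored counts, then L2-normalized so weights are
comparable across sessions whose regularization differs.  No class
weighting is applied inside the objective; class imbalance is handled
at evaluation time by balanced accuracy (mean of sensitivity and
specificity).  The regularization parameter C is chosen on the training
set by stratified 5-fold cross-validation over the grid
{0.0012, 0.0015, 0.002, 0.005, 0.01, 0.05, 0.1, 0.5}, maximizing mean
fold balanced accuracy; ties go to the smallest C (strongest
regularization).  Trials are split into training and validation halves
(training gets ⌊J/2⌋, stratified by class) by Monte-Carlo
cross-validation, 100 runs by default, seeded and reproducible.

Univariate weights are per-neuron ROC-AUC scores of the spike counts,
computed through the rank form of the Mann-Whitney U statistic (exactly
pair counting with ties at ½), centered at the chance level ½ and
scaled by the L2 norm of the centered vector.  The L2 norm of the
centered scores is used deliberately: it is the only normalization
consistent with a centered numerator, and it mirrors the normalization
of the multivariate weights.

## Population signal

The single-trial signal is x_j(t) = (w̃ᵀ o_j(t)) ∗ u with a causal
exponential kernel u(τ) = exp(−λτ), λ = 1/20 ms⁻¹ by default — each
presynaptic spike causes a jump followed by a 20-ms decay, so x_j is
the model's synaptic input current.  The kernel support is truncated at
⌈5/λ⌉ bins (≥ 99.3% of the mass; configurable); history before the
window is zero, so signals start at 0.  The kernel is unnormalized by
default; dividing a signal by the kernel area Σu removes the pure
amplitude scaling of the filter and is exposed for comparisons across
time constants.

Signals are computed on validation trials only, centered on the
across-trial mean z(t) of the same cross-validation run, averaged
within condition, and summarized by the difference
Δx(t) = x̃ᵐ(t) − x̃ⁿᵐ(t).  Reported signals are means across
cross-validation runs.

Subpopulation read-outs zero out the weights of the excluded neurons
and rescale the rest by f = N/(g·N_sub), with g = 2 for the plus/minus
sign pools and g = 3 for the SG/G/IG layers, so signals are comparable
across pools of different size.  Zero weights belong to neither sign
pool.  By linearity, x = x⁺/f⁺ + x⁻/f⁻ exactly; the test suite holds
this to 1e-10.  Each subpopulation signal is centered on its own
across-trial mean.  Per-neuron (univariate) signals weight a single
neuron's spike train by its AUC weight.

## Null models and significance

The central null permutes condition labels *before weight learning and
again before condition averaging* (one shared permutation across
neurons per replicate), re-running the read-out end to end; nperm =
1000 by default.  C is held at the session's selected value inside the
null rather than re-selected per replicate.  The per-bin statistic is
compared with its null distribution two ways: the strict
outside-the-min/max-envelope criterion, and an empirical two-sided
p-value with add-one correction, p = (1 + #{|null| ≥ |obs|})/(nperm+1),
flagged at α = 0.05.  No correction across time bins is applied in the
default report (the per-bin presentation is the object of interest); a
Westfall-Young max-statistic variant is available for users who want
family-wise control.

Perturbation analyses remove one information source at a time from an
otherwise intact read-out: replacing the weights by uniform draws over
their range, randomizing only the signs (draws from the same-range
uniform, so the sign probability follows the dominant sign of the
original vector), randomizing only the moduli, binarizing to ±a with
a = mean|w̃|, or permuting the order of time bins (shared across
neurons, preserving counts and zero-lag coincidences).  A mode
"preserves" discrimination when the median time-averaged Δx across its
replicates falls outside the label-permutation null of the same
statistic.

CCF nulls randomize the assignment of neurons to pools (or layers)
while preserving pool sizes, by permuting the weight values across
neurons before splitting — isolating the effect of membership from the
effect of pool size.

## Cross-correlation

The raw CCF at lag τ ≥ 0 is R_xy(τ) = Σ_k x(t_k) y(t_k+τ) (biased — no
per-overlap division; the normalization makes the lag-0 value identical
either way), with negative lags by the symmetry R_xy(−τ) = R_yx(τ),
normalized by √(R_xx(0) R_yy(0)) so |R̃| ≤ 1.  CCFs are computed per
trial on the signals as produced by reconstruction (not re-centered; a
mean-subtracted option exists) and averaged within condition or over
all trials.  Zero-energy trials, for which the normalization is
undefined, are dropped from the average with a logged count.

Because x⁺ ≥ 0 and x⁻ ≤ 0 pointwise, the raw plus×minus CCF is
negative by construction; the informative comparison is against the
random-assignment null band.  Anti-correlated pool *rates* reduce the
co-modulation of |x⁺| and |x⁻| and therefore move the lag-0 value
*toward zero* relative to the random-assignment band, while a shared
positive gain would push it below the band; either way the true
assignment separates from the null, which is what the package tests.

## Laminar assignment from the CSD

The CSD is the three-point second spatial difference of the
trial-averaged laminar LFP, (V_{i−1} − 2V_i + V_{i+1})/h², edge
channels dropped, normalized to max |CSD| = 1.  The map is oriented
sink-positive (a local minimum of the extracellular potential in depth
— a current sink — maps to a positive value); the flag is exposed
because sign conventions differ across labs.  Normalization before the
covariance only rescales it and moves no zero crossing.

The strongest sink is the map's maximum within 20–100 ms post-onset.
The spatial covariance C = A Aᵀ/N_time (raw Gram form, not
mean-subtracted) is computed and its column through the sink channel
extracted; walking outward from the peak, the first sign change on each
side — linearly interpolated between channels — gives the upper and
lower G-layer borders.  If a side never crosses zero the border falls
back to the probe end, flagged.  Channels/neurons above the upper
border are SG, below the lower border IG, in between G; a depth exactly
on a border goes to G (deterministic partition).

## Synthetic generator

The generator emulates the statistical setting of laminar V1/V4
recordings in a delayed match-to-sample task: defaults are 20 neurons,
100 trials per condition, 400 ms at 1-ms bins, 5 Hz baseline, and a
10 Hz between-condition rate contrast confined to 200–400 ms of the
test window (late divergence).  Spiking is Bernoulli per bin
(discrete-time Poisson); no refractoriness, bursting or adaptation.
The condition effect is split symmetrically (±depth/2 with the neuron's
planted sign and the trial's label) so the population-summed rate is
identical across conditions: the population PSTH is condition-blind
while the signed pattern is fully decodable — the regime the read-out
model is designed for.  An optional shared latent input (Gaussian noise
smoothed at a 20-ms timescale, loaded +1/−1 on the plus/minus pools)
creates anti-correlated pool rates with realistic CCF width.  Rates are
clipped at zero before sampling; a bin probability above 1 raises.

The laminar LFP generator plants a negative-Gaussian-in-depth potential
(sink center mid-probe, width 2.5 channel spacings of 100 µm) times a
temporal bump at 60 ms; its second spatial derivative is a Mexican hat
whose zero crossings at ±1 Gaussian width are the planted G borders.
The `snr` parameter is defined on the trial-averaged CSD (the map the
border method operates on): per-trial LFP white noise is scaled so that
clean-CSD-peak / averaged-CSD-noise-SD equals `snr`.

What passing tests on this generator do **not** show about real data:
real spike trains have refractoriness, burstiness, non-Poisson count
dispersion and slow nonstationarities; real LFPs have structured
(1/f, oscillatory) noise and imperfectly planar laminar geometry; and
real modulation is heterogeneous across neurons rather than a fixed
±depth/2.  The generator validates correctness and calibration of the
machinery, not biological effect sizes.

## Pipeline sizes and numerical choices

Defaults follow the analysis the package models: λ = 1/20 ms⁻¹,
nperm = 1000, 100 cross-validation runs, α = 0.05.  Two cost-bounding
choices are the package's own: C is selected once per session/epoch on
the first run's training set (`c_selection="session"`; `"per_run"`
re-selects per split), and each label-permutation replicate is averaged
over `null_cv_runs` (default 10) of the splits rather than all 100.
The acceptance script and test suite use reduced problem sizes chosen
to keep each check's sampling error well inside its decision margin:
20 sessions for sign recovery, 50 for null BAC, 20 for the flag-rate
calibration (nperm = 200), 100 LFP instances for border recovery.

Degenerate inputs are handled deterministically: zero-variance neurons
get zero z-scores; a neuron with constant counts gets AUC ½ and weight
0; an empty sign pool or layer yields an invalid spec and an all-zero,
flagged signal; zero-energy trials are dropped from CCF averages;
an all-zero CSD map is an error for sink location.

## Known limitations

* The SVM intercept is kept on the raw (unnormalized) scale; only the
  direction of the weight vector is used downstream.
* The label-permutation null with `null_cv_runs` < `n_cv_runs` has
  slightly higher replicate variance than the full procedure; this is
  conservative for the envelope criterion.
* The t-test convenience statistic on time-averaged signals is an
  interpretation (two-sample t-test on per-trial time averages) and is
  not used for the main significance decisions.
* Layer analyses require a laminar LFP and per-neuron depths; without
  them the pipeline skips those blocks with a warning.
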