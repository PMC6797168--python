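# popsignal

Read-out of parallel spike trains as a low-dimensional population
signal.

`popsignal` is for neurophysiologists analyzing simultaneously recorded
spike trains (e.g. laminar-probe recordings in visual cortex during a
binary discrimination task) who want to go beyond the population PSTH.
It models a read-out neuron that weights each afferent's spikes by a
learned synaptic weight: weights w̃ are the L2-normalized feature
weights of a linear SVM trained to separate the two task conditions
from z-scored spike counts,

    s̃_nj = (s_nj − ⟨s_nj⟩_j) / √Var_j(s_nj),      w̃ = w / ‖w‖₂,

and the single-trial **population signal** is the weighted, causally
filtered spike train

    x_j(t) = Σ_τ  w̃ᵀ o_j(t − τ) · e^{−λτ},        λ = 1/20 ms⁻¹,

interpreted as the read-out neuron's synaptic input current.  Signals
are centered on the across-trial mean and averaged by condition; the
difference Δx(t) = x̃ᵐ(t) − x̃ⁿᵐ(t) is tested against a label-permutation
null (labels shuffled before weight learning *and* before condition
averaging).  On top of this core, the package provides:

* univariate (per-neuron ROC-AUC) weights and signals,
* sign-pool (plus/minus) and cortical-layer (SG/G/IG) decompositions
  with pool-size correction factors f = N/(g·N_sub),
* weight-perturbation analyses (random weights / signs / moduli,
  binary ±a weights, spike-timing permutation) that isolate which
  information source carries the discrimination,
* normalized cross-correlation functions between simultaneous pool or
  layer signals, with random-assignment nulls,
* current-source-density analysis of laminar LFP (second spatial
  difference, covariance zero-crossing method) to assign channels and
  neurons to supragranular / granular / infragranular layers,
* a synthetic-session generator with planted, recoverable structure,
  and a full-session pipeline with CLI.

## Worked example

```python
import numpy as np
import popsignal as ps

# synthetic session: 20 neurons, 100 trials/condition, 5 Hz baseline,
# 10 Hz condition contrast planted in 200-400 ms of the test window
sess = ps.generate_session(ps.SessionConfig(seed=1))
sts = sess.test

split = ps.monte_carlo_splits(sts.labels, n_runs=1, seed=0)[0]
cm = ps.spike_counts_zscored(sts, stats_trials=split.train_idx)
C = ps.select_regularization(cm.zscores[:, split.train_idx],
                             sts.labels[split.train_idx], seed=0)
wv = ps.learn_weights(cm.zscores[:, split.train_idx],
                      sts.labels[split.train_idx], C=C)
print("C:", C)
print("first 5 weights:", np.round(wv.weights[:5], 3))
print("sign recovery:", (np.sign(wv.weights) == sess.truth["signs"]).mean())

ker = ps.make_kernel()                       # exp(-t/20 ms), causal
x = ps.reconstruct_trials(sts, wv, ker, trials=split.valid_idx)
sig = ps.center_and_average(x, sts.labels[split.valid_idx])
print("mean difference 200-400 ms: %.3f" % sig.difference[200:].mean())

null = ps.label_permutation_null(sts, [split], kernel=ker, C=C,
                                 nperm=200, seed=0)["all"]
mask = ps.significance_mask(sig.difference, null, alpha=0.05)
print("flagged bins in 200-400 ms: %d / 200" % mask.flags[200:].sum())
print("flagged bins in 0-200 ms: %d / 200" % mask.flags[:200].sum())
```

Output:

```
C: 0.0012
first 5 weights: [-0.193  0.242  0.219 -0.209 -0.276]
sign recovery: 1.0
mean difference 200-400 ms: 0.804
flagged bins in 200-400 ms: 198 / 200
flagged bins in 0-200 ms: 2 / 200
```

The SVM picks the smallest grid C (the data are strongly separable),
the learned weight signs match all 20 planted modulation signs, and the
match−non-match signal difference is flagged against the permutation
null almost exclusively inside the planted 200–400 ms effect window —
the 2 early flagged bins are the expected false-positive rate at
α = 0.05.

The same analysis runs from the shell:

```sh
popsignal synth --out session.h5 --seed 1
popsignal run session.h5 --outdir report --nperm 200 --n-cv-runs 10
```

which writes `report/summary.json` (weights, signals, null bands,
perturbations, CCFs, laminar assignment) and delimited tables.
`popsignal weights|signal|nulls|ccf|layers` run the individual stages.

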