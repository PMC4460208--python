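# Methods

## Scope and data model

The package models cumulative drug release *Q(t)* (percent of dose, 0–110
to tolerate assay overshoot) from cylindrical solid lipid extrudates
characterized by diameter *d* (mm) and length *L* (mm). A dataset is a
table of (formulation, d, L, t, Q) records; the canonical study design
holds five formulations — (d, L) = (0.6, 14), (1.0, 10), (1.5, 29),
(2.7, 8), (3.5, 5) mm — sampled every 5 min up to 1000 min, i.e. 1000
records.

## Synthetic ground truth

The original measurements for this design were never deposited, so the
generator produces profiles from a known model: Weibull release
*Q = 100·(1 − exp(−(t/A)^K))* with diameter maps

* *A(d) = c₃^d* — the 63.2%-release time grows geometrically with
  diameter; with c₃ = 23.2 it spans ~7 min (d = 0.6) to ~6·10⁴ min
  (d = 3.5), so the thinnest extrudate releases completely inside the
  1000-min window while the thickest releases only a few percent;
* *K(d) = c₁·d/(d + c₂)* — a saturating shape map, K ∈ (0.63, 0.84) over
  the study diameters with (c₁, c₂) = (0.9, 0.25).

Measurement error is additive Gaussian on Q (default sd 1.0%), clipped to
[0, 110]; profiles are emitted as replicate-averaged curves. This
parametrization was chosen because (a) every constant is identifiable from
the five-profile design — the generate-then-fit recovery tests depend on
that — and (b) it yields monotone sigmoidal curves with the qualitative
diameter ordering expected of sustained-release extrudates. The registry
also carries the non-identifiable literal variant *K = c₁·d/(d + c₂·d)*
(which collapses to the constant c₁/(1+c₂)), selectable per model, but the
generator deliberately does not use it: a ground truth whose parameters
cannot be recovered even from noiseless data would make recovery testing
meaningless. What passing tests show is therefore that the *machinery*
(fitting, regression, screening) works on data of the study's shape and
noise scale — not that the synthetic curves match the unpublished
measurements.

## Equation registry

Four closed forms over (d, t), all vectorized, all returning NaN (rather
than raising) on out-of-family parameter regions so optimizers can
penalize them:

| id | form | parameters |
|---|---|---|
| `weibull` | 100·(1 − exp(−(t/A)^K)) | A > 0, K > 0 |
| `eq_indirect` | Weibull with A(d), K(d) maps above | c₁, c₂, c₃ |
| `eq7_direct` | (ln d + d + c₁·t + c₂)/(t + c₃·d² + d²) | c₁, c₂, c₃ |
| `eq_previous` | 100·(1 − exp(−(t/(c₅·d + c₆))^(exp(c₁·d + c₂·d·ln(c₃·d + c₄))))) | c₁…c₆ |

The source typography of the last two is ambiguous (collapsed fraction
bars and exponents); the parses above are this package's documented
readings, chosen so that `eq7_direct` behaves like a dissolution curve
(it saturates at c₁ ≈ 98, i.e. the maximal release, for large t) and
validated for finiteness over the study domain d ∈ [0.6, 3.5] mm,
t ∈ [0, 1100] min rather than against unverifiable point values. Per-profile
Weibull fitting optimizes (ln A, ln K) by Levenberg-Marquardt so positivity
is structural, starting from the interpolated 63.2%-release time and K = 1.

## Neural networks

MISO multilayer perceptrons with one activation throughout (linear,
logistic, tanh, or the odd logarithmic "fsr" unit sign(a)·ln(1+|a|), whose
exact original definition is not public — this implementation is a
documented choice). Training is deliberately the study's recipe rather
than a modern batch optimizer:

* **epoch = one pattern**: each epoch draws one random record and performs
  one update (a million epochs is then a million single-record updates);
* **momentum** 0.3;
* **delta-bar-delta** per-weight rates, initial 0.65; Jacobs' constants
  (additive increase κ = 0.01, multiplicative decrease φ = 0.9, trace
  decay 0.7) are not specified by the study and are config-exposed;
  rates stay strictly positive by construction;
* **jog-of-weights**: when train RMSE has not improved by more than
  `patience_tol` (default 0) for `patience_epochs` (default 100,000),
  every weight receives uniform noise of amplitude max(0.1·|w|, 0.01) and
  the patience resets. The noise form is unspecified in the source recipe;
  this is the package's choice. Train RMSE is refreshed every
  `eval_interval` (default 1000) epochs — evaluating after every single
  pattern would dominate runtime without changing behavior;
* **stop points**: snapshots (weight copies + train/held-out RMSE) at
  5k, 10k, 15k, 20k, 30k, 50k, 100k, 150k, 200k, 300k, 500k, 750k, 1M
  epochs; the selected model minimizes held-out RMSE (ties → earliest).
  Selecting on held-out error makes the test set part of model selection;
  the reported generalization error is therefore mildly optimistic, which
  is inherited from the protocol and flagged wherever it is used.

Targets must be pre-scaled into the activation's output range (the two
study ranges are ⟨0.2, 0.8⟩ for logistic and ⟨−0.8, 0.8⟩ for tanh);
training refuses out-of-range targets before the first epoch. Fixed-seed
runs are bit-reproducible.

## Sensitivity analysis and input reduction

Input importance of a trained network is the mean absolute partial
derivative of the output with respect to each input over the dataset,
computed from exact layer-by-layer Jacobians and normalized to sum to 1.
The collective variant averages normalized scores over an ensemble of
trained networks (rank aggregation was considered and rejected as less
informative for near-tied inputs; the mean keeps magnitude information).
Inputs with mean score ≥ 0.05 (default) are retained. The
derivative-magnitude formulation is one member of the family of
perturbation-based saliency methods; it is documented here as this
package's interpretation rather than a faithful reconstruction of any
specific historical variant.

## Genetic programming

Tree GP over {+, −, ×, ÷, pow, ln, sqrt, exp} with variable terminals and
ephemeral constants uniform in [−10, 10]. Protected semantics guarantee
finite evaluation everywhere: x/0 → 1, ln|x| with ln 0 → 0, √|x|,
|a|^b with clipped exponent, clipped exp, and a ±10¹² clamp per node.
Complexity is controlled by a node-count cap (`size_limit`; the study
swept its equivalent from 10 to 300 and equated it with tree depth — node
count is the stricter reading and the one enforced here). Evolution is
generational: tournament selection (size 3), subtree crossover (0.7),
subtree mutation (0.2), point mutation (0.1, including constant jitter),
single-individual elitism; offspring breaching the size cap are replaced
by their parent. Best-so-far fitness (RMSE) is monotone by construction.

**Constant polishing.** Each generation, the constants of the elite and of
a small random sample of individuals are refined by Nelder-Mead on the
training RMSE. This is essential, not cosmetic: ephemeral constants are
drawn from a bounded range, so a structurally correct tree such as
exp(c·d) for a steep time-scale map is hopeless until c is tuned, and
raw-fitness selection would discard the structure before mutation ever
found the constant. Runs stop at a fitness threshold (defaults: 1.0% RMSE
for direct Q regression; 0.01 for the Weibull A map and 5.0 for the K map,
taken from the study's stated pairing even though the looseness on K is
surprising), at a generation cap, or on an optional wall-clock budget;
generation-capped runs are deterministic per seed.

## Multistage fitting

Parameters of any registry equation are refitted de novo from the constant
vector (0.1, …, 0.1): simulated annealing first (Gaussian random-walk
proposals with step sd max(T, 0.01), T₀ = 10, geometric cooling 0.95 every
100 evaluations, 10,000 evaluations total — none of these are stated in
the source protocol and all are config-exposed), then the five local
methods Nelder-Mead, BFGS, L-BFGS-B, Powell, CG, each run independently
from the annealed point (no follow-on chaining); the lowest training RMSE
wins. The annealing budget is split over three independent restarts
because a single chain occasionally settles into a secondary basin of the
indirect model (a large-|c₁|, large-|c₂| region where the shape map
degenerates to a ratio); restarts make the global stage reliable without
changing the protocol's structure. Cross-validated fitting applies this
per leave-one-formulation-out fold, optionally preprocessing each training
fold (noising, balancing, or surrogate-model enhancement) while the test
fold is never touched, and reports pooled held-out RMSE plus per-parameter
CV% (sample standard deviation, n−1).

## Preprocessing

* **Noise augmentation**: one jittered copy per record appended (not
  substituted — augmentation is the standard anti-overfitting reading),
  each numeric field multiplied by a uniform draw from [1−a, 1+a],
  a = 5% by default.
* **Output balancing**: Q binned into 10 equal-width bins; nonempty bins
  are duplicated (cyclically) up to half the largest bin's count, so the
  max/min occupied-bin ratio is ≤ 2. Records are never deleted and no new
  Q value is invented. The binning/duplication scheme is this package's
  concrete reading of "multiply the under-represented low-output records".
* **Linear scaling**: per-variable min/max maps to ⟨0.2, 0.8⟩ or
  ⟨−0.8, 0.8⟩ with exact inverses (round-trip to ~1e-12).
* **Enhanced datasets**: a regular (d, t) grid from each input's training
  minimum to 110% of its maximum, step 3.33% of the min–max range with the
  boundary always included, evaluated through a trained surrogate
  (typically the best network wrapped with its scaling); grid nodes whose
  diameter matches the held-out formulation's (within 1e-9) are discarded
  so nothing leaks about the test geometry. Artificial records carry the
  training-set mean length (length does not enter the surrogate) and
  per-diameter ids `aug###`. The historical enhanced-set sizes
  (7400–7800 records) are not derivable from this stated step on two
  inputs (~1.3k nodes); the step is therefore a config knob at its stated
  default and set size is not asserted anywhere.

## Metrics

RMSE; the FDA similarity factor f₂ = 50·log₁₀((1 + msd)^−½·100)
(identical profiles → 100; ≥ 50 conventionally "similar"; log base 10 per
the FDA definition; no pre-truncation above 85% release by default,
exposed as an option); CV% = 100·sd(n−1)/|mean|.

## Problem sizes in the shipped tests and acceptance script

Tests and the acceptance run use deliberately scaled-down search budgets —
GP populations of 100–500 with tens of generations instead of 10,000 with
multi-hour budgets, network training of 10⁴–10⁵ single-pattern epochs
instead of 10⁶, annealing budgets of a few thousand evaluations — chosen
as the smallest sizes at which each scientific property (rediscovery,
recovery, screening) is comfortably demonstrated. Recovery sweeps use a
20-min sampling grid (250 records); everything else uses the full
1000-record design.

## Known limitations

* Synthetic data cannot validate fidelity to the unpublished
  measurements; all quantitative claims are about the machinery under the
  study's design, noise scale, and counts.
* The ~208-architecture network sweep of the original campaign is
  expressible (the sweep is a config-driven loop) but its exact
  composition was never specified and is not reconstructed.
* Neuro-fuzzy models are out of scope (no internals available).
* The direct-equation parse (`eq7_direct`) is a documented reading of
  ambiguous typography; no numeric claim in this package depends on the
  parse being the historical one.
* Weibull time scales far beyond the sampling window (the 3.5 mm
  formulation releases only a few percent by 1000 min) are weakly
  identified from single profiles — visible as inflated per-profile A
  estimates — though the indirect model's global fit is unaffected.
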