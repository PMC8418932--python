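# Methods

This note documents the models, numerical choices and limitations behind
`eegfocus`, in the order the pipeline runs.

## Preprocessing

Records are two-column ASCII files (one `x, y` pair per line; both the
comma- and whitespace-separated dialects are accepted). Class labels are
carried by filename convention (`focal_*` / `nonfocal_*`, or `F_*`/`N_*`),
not by file content. The difference channel *X − Y* removes activity
common to both electrodes — mains pickup, reference drift — while local
activity that differs between adjacent contacts survives. The
first-difference operator then shortens an *n*-sample record to *n − 1*
samples (10240 → 10239 for 20 s at 512 Hz) and attenuates the dominant
low-frequency trend. No amplitude normalization is applied before
decomposition, and no artifact rejection or resampling is attempted.

## Tunable Q-factor wavelet transform

The transform is defined by its stage filters: a low-pass/high-pass pair
with the power-complementary transition response
`θ(ω) = ½(1 + cos ω)√(2 − cos ω)` and scalings `β = 2/(Q+1)`,
`α = 1 − β/r`. Validity requires `α + β > 1` (a non-degenerate
transition band), which `design_params` enforces.

**Realization.** Only the frequency responses define the transform, so it
is realized directly in the DFT domain (the radix-2 realization): the
input is zero-padded to the next power of two, and at every stage the
low-pass branch keeps the band `|ω| ≤ απ` on `2·round(αN/2)` bins while
the high-pass branch keeps `(1−β)π ≤ |ω| ≤ π` on `2·round(βN/2)` bins.
Even rounding at each stage is what lets arbitrary — including odd —
input lengths such as 10239 pass through with exact reconstruction; the
reconstruction truncates the padded tail. Negative-frequency bins are
mirrored explicitly so real inputs give real subbands (the residual
imaginary part, at machine-epsilon level, is discarded). Analysis and
synthesis share the same real gain windows, and since `g0² + g1² = 1` on
the transition band the cascade is self-inverting; the round-trip
relative error is below 1e−10 in the tests (asserted at 1e−8). The
normalization is energy-preserving (a tight frame): subband energies sum
to the signal energy.

Zero-padding does introduce a boundary discontinuity for signals with a
nonzero edge value; for differenced EEG (near-zero mean and edges) the
effect is negligible, and reconstruction is exact regardless.

**Maximum level.** `max_levels(n, Q, r) = ⌊log(βn/8)/log(1/α)⌋` — the
deepest level at which the final low-pass branch still spans the
transition-band filters (β × length ≥ 8). It is validated against an
iterative oracle that multiplies the branch length by α until the next
stage would be inadmissible, and reproduces 35 for n ≈ 10240, Q = r = 3.

**Subband geometry.** Detail *j* has center frequency
`α^(j−1)(2−β)fs/4` and bandwidth `βα^(j−1)fs/4`, so `f_c/BW = Q` for
every detail; the approximation occupies `[0, α^J·fs/2]`. Details are
indexed 1..J from high to low frequency, approximation last.

## Entropy features

Per subband: `LE = Σ log(s_i²)` (the log(0) term defined as 0),
`LL2 = log Σ s_i²`, `SURE = n − #{|s_i| ≤ ε} + Σ min(s_i², ε²)` and
`TH = #{|s_i| > ε}`, with ε = 0.2 by default. Choices worth noting:

- **Log base.** Natural logs by default (matching the common numerical
  implementation of these entropies), with a base-2 switch in
  `EntropyConfig`. Tests pin the natural-log default.
- **Magnitudes, not signed values.** Wavelet coefficients are signed;
  thresholds compare `|s_i|`, otherwise TH would count only positive
  excursions. Ties at exactly ε count as below threshold in both SURE
  and TH.
- **Degenerate subbands.** `LL2` of an all-zero sequence returns 0 with a
  warning rather than −∞, keeping feature vectors finite.

Features are ordered as four contiguous blocks (LE, LL2, SURE, TH), each
running over subbands 1..J+1, giving 4(J+1) values (108 at J = 26).

The Kruskal–Wallis rank test (the two-group case, equivalent to a
Mann–Whitney test) yields one p-value per feature; the conventional
screen keeps p < 0.05. Constant columns are assigned p = 1. The χ²
approximation is validated against a 10,000-draw label-permutation null
in the tests.

## Wrapper feature selection

All six metaheuristics maximize the same fitness: a designated
classifier's pooled CV accuracy on the masked features. Shared
conventions, chosen where the algorithms' published descriptions are
silent:

- **Initialization**: every bit Bernoulli(½) under the run seed.
- **Binarization**: bit = 1 when a uniform draw ≤ S(v) = 1/(1+e^(−v));
  GWO uses the steeper transfer `T(x) = 1/(1+e^(−10(x−0.5)))` on
  positions confined to [0,1].
- **All-zero repair**: a classifier cannot be fit on zero features, so an
  all-zero candidate gets one uniformly random bit set.
- **Tie-break**: equal fitness prefers fewer selected features (selection
  exists to reduce model complexity).
- **Elitism**: the best-ever mask and a per-iteration best-so-far history
  are tracked for every method; histories are non-decreasing by
  construction. Fitness evaluations are memoized (they are deterministic
  under the run seed, and wrapper fitness dominates the cost).

Method-specific defaults follow the operating points stated for the
application: BBA 4 bats × 40 iterations with constant loudness/pulse
schedules (decay α = 1); BDE 10 vectors × 100 iterations, CR = 0.9; FA
6 fireflies × 100 iterations, α = 0.5, γ = 0 (attractiveness does not
decay with distance at γ = 0 — kept as the default, configurable); GA 10
chromosomes × 100 generations, CR = 0.8, MR = 0.01, roulette selection,
single-point crossover, 1-elitism; GWO 10 wolves × 100 iterations; PSO
10 particles × 100 iterations, c1 = c2 = 2, inertia annealed 0.9 → 0.4,
velocity clamp ±6. BBA's frequency bounds (f_min = 0, f_max = 2), its
loudness/pulse constants (A₀ = 1, r₀ = 0.5, γ = 0.9) and FA's zero-mean
random term `α(rand − ½)` are this package's choices where the published
operating point leaves them open. BBA's velocity pull is implemented as
`v += (x − gbest)·f` with the frequency drawn as `f_min + (f_min −
f_max)·β`, and its local walk perturbs the velocity by ε·(mean loudness)
before binarization.

The exhaustive oracle enumerates all non-empty masks (refusing d > 20)
with the same tie-break, and is itself double-checked against an
independent enumeration in the tests. On the benchmark landscapes used
for validation (monotone counting fitness at d = 8; a unique-target
Hamming landscape at d = 10 for PSO) each selector reaches the oracle
optimum in ≥ 85–90 % of 20 seeded runs.

## Classifiers and evaluation

- **KNN**: city-block (L1) distance, K ∈ 1..9 (scikit-learn backend).
- **SVM**: RBF kernel, `gamma = 1/(2σ²)` with σ ∈ 0.1..1.5 step 0.1,
  C = 1 (scikit-learn backend). Note the σ grid is narrow for
  standardized high-dimensional inputs; with ~100 features the kernel
  can collapse toward the majority vote. This mirrors the stated grid
  rather than a dimension-aware heuristic like σ ∝ √d.
- **FFNN / CFNN / Elman**: hand-written single-hidden-layer networks
  (10 tan-sigmoid units, logistic output) trained by minimizing
  L2-regularized cross-entropy (λ = 1e−4) with L-BFGS (max 200
  iterations), a quasi-Newton stand-in of the same second-order family
  as damped Gauss–Newton trainers. Weights are drawn from the run seed,
  so training is deterministic. CFNN adds a direct input→output
  connection. The Elman network unrolls the hidden layer for two passes
  over the (static) feature vector, the context fed by the first pass's
  hidden state; with a single pass from a zero context the recurrent
  weights would never participate and the network would collapse to the
  FFNN.
- **GRNN**: Gaussian-kernel (Nadaraya–Watson) regression of the 0/1
  class indicator, spread 1; queries whose kernels all underflow fall
  back to the nearest neighbor.

**Cross-validation**: stratified k-fold (default k = 10) with shuffling
under the run seed; every record is tested exactly once; features are
z-scored with statistics fit on each training split only (scaling is
this package's addition — networks and RBF kernels need comparable
scales; instance-based KNN/GRNN are scaled identically for uniformity).
Confusion counts are pooled over folds *before* computing ACC/SEN/SPE,
with focal as the positive class. Hyperparameter grids (K, σ) are scanned
over the *same* CV partition and the best pooled accuracy reported —
deliberately mirroring a "best value on the grid" protocol, which is
optimistic relative to nested CV; the report marks no inner loop.

The wrapper-fitness CV is decoupled from the final evaluation CV: both
default to 10 folds, but fitness folds can be reduced (tests and the
packaged end-to-end check use 3) to control the wrapper's cost without
touching the final metric.

## Synthetic data

The generator reproduces the statistical contrast the method exploits,
not epileptic electrophysiology. Focal-like channels: 2–3 sinusoids
drawn from 4–12 Hz (amplitudes 10–18 µV), a narrowband AR(2) process
(poles at radius 0.97, 8 Hz; SD 8 µV) and white noise (SD 5 µV).
Nonfocal-like channels: a broadband AR(2) (poles at radius 0.6, 40 Hz;
SD 25 µV) plus white noise (SD 25 µV). Both channels of a record carry
independent realizations of the class process, a *shared* interference
term (50 Hz mains, 15 µV; 0.3 Hz drift, 30 µV) and small sensor noise
(SD 2 µV), so the difference channel cancels the interference while
keeping the class signature. AR processes discard a 1 s burn-in. Records
are pure functions of (seed, class, index).

Defaults are 50 records per class at 512 Hz; the canonical record length
is 20 s, and 2 s records are used throughout the test suite and the
end-to-end checks so the full pipeline runs in seconds (a 2 s record
admits J ≤ 22, and the pipeline caps J accordingly). The classes are
separable mainly by broadband power and spectral concentration —
markedly easier than real focal/nonfocal discrimination. Passing the
end-to-end check (pooled ten-fold KNN accuracy ≥ 95 % after PSO
selection) therefore validates the pipeline's plumbing, bookkeeping and
reproducibility, not clinical performance; published focal-localization
accuracies on real recordings are in the low-to-mid 90s, not 100 %.

## Known limitations

- No artifact handling, montage logic or clinical formats (EDF/BDF);
  input is the two-column ASCII dialect only.
- The SVM σ grid can be uninformative on standardized high-dimensional
  features (see above); it is kept for fidelity to the stated protocol.
- Grid-best hyperparameter reporting is optimistic by construction.
- The Elman unrolling for static inputs is a design choice; sequence
  learning over time is out of scope.
- Synthetic separability means absolute metric values on synthetic data
  say nothing about real-data performance.
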