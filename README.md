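# eegfocus

Discriminating **focal** from **nonfocal** EEG signals in the tunable
Q-factor wavelet transform (TQWT) domain.

Intracranial EEG channels recorded inside the epileptogenic zone ("focal")
tend to be more rhythmic and less random than channels recorded elsewhere
("nonfocal"). This package implements a complete, tested pipeline that
exploits that contrast to localize candidate focal channels from short
two-channel recordings — the signal-processing step that precedes surgical
planning in pharmacoresistant focal epilepsy:

1. **Preprocessing** — records hold two adjacent-channel series *X* and *Y*
   (512 Hz, 20 s in the reference recording protocol); the difference
   channel *X − Y* cancels interference common to both electrodes, and a
   first-difference operator `A_diff[i] = a[i+1] − a[i]` whitens the 1/f
   trend.
2. **TQWT decomposition** — an oversampled perfect-reconstruction wavelet
   filter bank with tunable Q-factor *Q* (oscillation count), redundancy
   *r* and level count *J*. The scalings are `β = 2/(Q+1)`,
   `α = 1 − β/r`, so each detail subband satisfies `f_c / BW = Q`. At the
   working point *Q* = *r* = 3, *J* = 26, a record splits into 27 subbands
   (26 details + 1 approximation); the deepest admissible level for a
   differenced 20 s record is `⌊log(βn/8)/log(1/α)⌋ = 35`.
3. **Entropy features** — per subband: log-energy (LE), log of total
   energy (LL2), Stein-risk entropy (SURE) and threshold entropy (TH),
   the latter two at threshold ε = 0.2; 4 × 27 = 108 features per record.
   A Kruskal–Wallis rank test optionally screens features at p < 0.05.
4. **Wrapper feature selection** — six binary metaheuristics (bat
   algorithm, differential evolution, firefly, genetic algorithm, grey
   wolf, particle swarm) search the mask space, scored by a classifier's
   cross-validated accuracy; an exhaustive-search oracle validates them
   on small landscapes.
5. **Classification** — KNN (city-block, K = 1..9), RBF-kernel SVM
   (σ = 0.1..1.5), feed-forward / cascade-forward / Elman networks
   (10 tan-sigmoid hidden units), and a generalized regression network
   (spread 1), evaluated by stratified ten-fold cross-validation with
   confusion counts pooled over folds before computing

   `ACC = (TP+TN)/(TP+TN+FP+FN)·100, SEN = TP/(TP+FN)·100, SPE = TN/(TN+FP)·100`

   where focal is the positive class.

A seeded synthetic generator produces focal-like (rhythmic, low-entropy)
and nonfocal-like (broadband, noisy) records in the same two-column ASCII
format, so the full pipeline is testable without any data download.

## Worked example

Run the pipeline on synthetic data (20 records per class, 2 s each) with
PSO wrapper selection driving a KNN classifier:

```sh
eegfocus run --n 20 --duration 2 --selector pso --classifier knn \
             --fitness-folds 3 --folds 5 --seed 1
```

```
features: 19/92 (selector=pso)
knn    ACC=100.00  SEN=100.00  SPE=100.00
```

At 2 s the record length caps the decomposition at *J* = 22, hence
4 × 23 = 92 features; PSO kept 19 of them, and the pooled 5-fold
cross-validation classified every record correctly (ACC — overall
accuracy; SEN — focal detection rate; SPE — nonfocal detection rate, all
in percent). The synthetic classes are deliberately well separated; on
real recordings the same pipeline reports the honest pooled metrics.

Checking a selector against exhaustive search on an 8-feature benchmark:

```sh
eegfocus oracle --method gwo --dim 8 --seed 3
```

```
{
  "method": "gwo",
  "optimum_fitness": 8.0,
  "selector_fitness": 8.0,
  "optimum_reached": true,
  ...
}
```

Other entry points: `eegfocus synth` writes a labeled synthetic dataset;
`eegfocus sweep --step {1,2,3}` runs the three-step TQWT parameter
selection (rank classifiers at Q = r = 2, J = 5; scan Q ∈ 2..10 × r ∈
2..5; scan J up to the admissible maximum). The same functionality is
available as a library (`eegfocus.run_pipeline`, `eegfocus.decompose`,
`eegfocus.select_pso`, ...).

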