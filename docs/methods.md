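# Methods

`leukoswarm` implements a dual-level gene-selection and classification
pipeline for two-class microarray expression data, of the kind used to
discriminate acute lymphoblastic from acute myeloid leukemia (ALL vs
AML) on a 7129-gene, 47+25-sample matrix. This note records the models,
the parameters that matter, the numerical choices, and the known limits
of what the test suite demonstrates.

## Pipeline model

1. **Filter shortlist.** All p genes are scored and the best
   `pool_size` (default 2000) retained by one of four statistics.
2. **Metaheuristic refinement.** A fixed-size subset (k = 50/100/200 by
   convention) is drawn from the shortlist by maximizing a
   cross-validated wrapper objective with one of five population
   metaheuristics.
3. **Classification.** The final subset is scored with PNN/NBC/SVM/RF
   under stratified 10-fold cross-validation, reported as PC/MC/FA
   counts and derived percent metrics.

## Filter statistics

**F-test (MRMR relevance).** For gene j with class means μ_jk, overall
mean μ_j, class sizes n_k and class variances s_k² (sample, n_k−1 form):

    F_j = Σ_k n_k (μ_jk − μ_j)² / [(m−1) σ²],   σ² = Σ_k (n_k−1) s_k² / (n−1)

Note the pooled variance uses an (n−1) denominator, not the conventional
ANOVA (n−m); the two differ by a constant factor and give the same
ranking. Zero pooled variance (a constant gene) scores 0 with a warning.

**MRMR.** Greedy selection: the first gene is argmax F; each later pick
maximizes `F_j · mean_d(j,T)` (FDM, multiplicative) or
`F_j / mean(1/d(j,T))` (FSQ, quotient), with d the Euclidean distance
between gene expression vectors and T the already-selected set. Distances
are clamped at 1e-12 so duplicated probes (d = 0) leave FSQ finite and
drive its criterion to ~0, which keeps exact duplicates of a selected
gene from being picked.

**SNR.** `(mean₀ − mean₁)/(sd₀ + sd₁)`; genes ranked by |SNR| (the sign
only marks the overexpressing class). A variant dividing by
`(sd₀ − sd₁)` is available as `convention="as_printed"`, but the sum is
the default: the difference form is unbounded and sign-unstable when
the class spreads are similar, and the sum is the form the original SNR
screening literature uses.

**EWUSC.** Three stages reconstructed from the standard
shrunken-centroid construction: (SC) standardized centroid deviations
d_jk = (μ_jk − μ_j)/(m_k (s_j + s₀)) with m_k = √(1/n_k − 1/n), s_j the
pooled within-class SD and s₀ the median of s_j, soft-thresholded by
(|d| − Δ)₊ with sign; Δ is picked from `ewusc_delta_grid` (default 0 to
3 in steps of 0.5) by internal 5-fold CV accuracy of the
nearest-shrunken-centroid rule, ties going to the smaller Δ. (USC)
Survivors are scanned in descending score order and dropped when their
|Pearson correlation| with an already-kept gene exceeds
`ewusc_rho_threshold` (default 0.9). (EW) Scores are multiplied by an
error weight 1/(s_j² + 1e-8), down-weighting noisy genes. If the stages
leave fewer than k genes the shrinkage falls back (with a warning) and
remaining slots are padded by the unshrunken weighted score.

**CFS.** Subset merit `s·r̄_cf / √(s + s(s−1)·r̄_ff)` where r̄_cf is the
mean |Pearson correlation| of member genes with the 0/1 label and r̄_ff
the mean pairwise |correlation| within the subset. The search is
best-first (beam over the five best single-gene additions per
expansion, stall limit 5) or plain forward selection; because the merit
typically peaks at small subsets, the result is padded to exactly k by
class-correlation rank. Constant genes contribute correlation 0.

All selectors break score ties by ascending gene index and are
deterministic given dataset and parameters.

## Metaheuristics

All five optimizers share one contract: box-bounded real vectors,
clipping after every move, a single seeded `numpy` Generator (bit-
identical reruns), and elitist tracking of the best-ever solution (the
recorded history is monotone). Defaults: population 30, 100 iterations.

* **ABO** — buffaloes carry a location v and momentum f;
  f ← f + lq1(herd best − v) + lq2(personal best − v), v ← v + f ± 0.5
  (the ±0.5 sign drawn per buffalo per iteration; a uniform-jitter
  variant is available). lq1 = 0.6, lq2 = 0.4; the herd restarts
  (keeping the best-ever) after 20 stagnant iterations.
* **ABC** — food sources with trial counters. Employed bees (60% of
  sources per cycle) perturb a source toward/away from a random partner
  by φ ∈ [−z, z] per dimension (z = 1) with greedy acceptance;
  onlookers (50%) pick sources with nectar-proportional probability
  (min-shifted to handle negative fitness, uniform on ties); one scout
  re-seeds the most-exhausted source past the trial limit (0.5·D·N).
* **CSO** — chase-swarming toward the local best within a Euclidean
  visual radius (default 0.15 of the box diagonal) or toward the global
  best when a cockroach is its own local optimum, with step
  coefficient 2.0 (overshooting moves, the literature's constant-step
  convention); a dispersal kick of ±0.25·range every 10 iterations; a
  ruthless step that overwrites one random individual with the best
  (or the zero vector, by option).
* **ICA** — empires of colonies. Assimilation moves each colony a
  distance ε ~ U(0, c·d) toward its imperialist (c = 1.5) with bounded
  per-dimension deviation (φ = π/8); 10% revolution; colony/imperialist
  swap on improvement; competition computes empire total cost
  AT_q = t_q + ζ·mean(colony costs) (ζ = 0.1), normalizes
  NAT_q = max AT − AT_q, powers EP_q = NAT_q/ΣNAT, and hands the
  weakest empire's worst colony to the empire maximizing EP_q − U(0,1);
  empty empires collapse into the winner.
* **SSO** — spiders weighted w = (worst − cost)/(worst − best) (all 1
  on a flat landscape); vibrations w_b·e^(−d²). Females (a fraction
  drawn U(0.6, 0.7) unless fixed) attract/repel toward the nearest
  heavier spider and the population best with probability P = 0.7;
  dominant males (weight ≥ male median) court the nearest female,
  non-dominant ones drift to the weighted male centre; mating within a
  radius of half the mean dimension range produces a roulette-weighted
  offspring that replaces the worst individual only if fitter.

## Wrapper encoding and objective

A k-subset of the pool is encoded as k real coordinates in
[0, pool_size): each floors to a pool rank and collisions advance
cyclically to the next unused rank, so decoding is total, deterministic,
always yields exactly k unique genes, and every subset has a preimage.
The objective is the inner cross-validated accuracy of a fast surrogate
classifier (PNN by default, 5 stratified folds), on the percent scale of
the evaluation metrics below; subset scores are memoized per run. In
`nested` mode the pipeline repeats the entire selection inside each
outer training fold; `paper_faithful` mode selects once on the full
dataset before cross-validating, matching how summary tables in this
literature are usually produced, at the cost of optimistic bias.

## Classifiers

**PNN** (implemented here): stores the training patterns in one pass;
the class score of a query x is the Parzen density
(1/n_c)·Σ exp(−‖x−x_i‖²/2σ²), computed in log space via logsumexp;
σ defaults to the median pairwise training distance/√2. Optional prior
weighting; without it, duplicating a class's patterns is a no-op.
**NBC/SVM/RF** delegate to scikit-learn (GaussianNB with its 1e-9
variance smoothing; SVC, linear kernel, C = 1; RandomForest, 100 trees)
with pinned seeds behind the same train/predict contract.

## Evaluation metrics

With PC = all correctly classified samples, MC = positive-class samples
predicted negative, FA = negative-class samples predicted positive
(positive class defaults to the minority class, i.e. AML):

    sensitivity = PC/(PC+FA)·100      specificity = PC/(PC+MC)·100
    accuracy    = (sensitivity+specificity)/2
    PI          = (PC−MC−FA)/PC·100   (negative when errors exceed hits)

These are screening-style conventions, not the textbook true-positive
rates; the conventional TP-based values are reported alongside as
`conv_*`. One consequence matters for interpreting null experiments:
the PC-based accuracy is **not** centred at 50 under class imbalance
(an all-majority predictor on a 47/25 split already scores ≈82.6), so
chance-level checks in the test suite use `conv_accuracy`, which is.
Counts are pooled over folds by default (`fold_mean` averaging is
available); PC = 0 yields a −inf performance index with a warning, and
zero denominators yield 0.

Fold plans deal each shuffled class round-robin across folds, so fold
sizes and per-fold class counts stay within 1 of exact stratification,
and k may be as large as n (leave-one-out), with a warning when folds
must miss a class.

## Synthetic data

The generator emulates the dimensions of the classic two-class leukemia
matrix (defaults p = 7129, 47 vs 25 samples) with i.i.d. Gaussian
within-class noise (sd `noise_sd` = 1). Planted informative genes get a
symmetric class-mean shift of ±effect_size/2·noise_sd with a random
overexpressing class; redundant blocks mix a standardized
class-informative latent with fresh noise as √ρ·u + √(1−ρ)·ε, so the
empirical within-block correlation is ≈ `block_rho` and redundancy-aware
selectors (MRMR, USC, CFS) have something real to penalize. Defaults
chosen once as typical of strong microarray signatures: 50 informative
genes, 5 blocks of 10 at ρ = 0.8, effect size 2. What it does **not**
emulate: probe/batch effects, intensity-dependent variance, heavy-tailed
expression, or gene-gene correlation outside the planted blocks — so a
passing recovery test shows the machinery is correct, not that real
arrays are this easy.

## Experiment sizes and known limitations

The heavier validation experiments use deliberately modest sizes, chosen
once as this package's defaults for single-CPU runs: planted-gene
recovery uses p = 500, a 200-gene pool, k = 50, optimizer budget
N = 16 × 20 iterations; the design-grid smoke run uses a 300-gene
dataset with a 250-gene pool and N = 8 × 8; the analytic convergence
benchmark uses the 2-D sphere with N = 30 × 200.

**Wrapper selection bias is the central limitation.** At 72 samples a
200-gene shortlist consists, by construction, of the genes most
correlated with the labels *in this sample* — including noise genes
that correlate by chance. Inner cross-validation re-uses those same
samples, so at moderate planted effect sizes (≥ 2 within-class SDs)
virtually every 50-gene subset of the pool reaches ~100% inner
accuracy: the wrapper objective is flat at its maximum, and no search
algorithm can prefer the truly informative genes over the
selection-biased ones on that signal. The test suite documents this
honestly: the planted-recovery acceptance test asserts high recovery
and fails at chance-level recovery, while the exhaustive-oracle test
(where attaining the *fitness optimum* is the criterion) passes. For
real data the practical consequences are the usual ones: trust nested
protocols for error estimates, and treat gene lists from
select-then-validate protocols as unstable under resampling.

Other limits: the Eq-form metrics above are reported as defined even
where they deviate from textbook definitions; EWUSC is a faithful
reconstruction of the shrunken-centroid/uncorrelated/error-weight
pipeline rather than a reference port; the metaheuristics follow their
published update rules with unstated constants filled from common
practice (all exposed in the config dataclasses).
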