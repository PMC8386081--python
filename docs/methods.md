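# Methods

## Model

The package prioritizes disease-associated genes by integrating
per-gene differential-expression scores from multiple two-group
contrasts with one sigmoid neuron.

For gene *g* with feature vector x_g = (p_g1, …, p_gn):

    z_g  = Σ_i w_i p_gi + b
    ŷ_g  = σ(z_g) = 1 / (1 + e^{−z_g})
    L    = Σ_g ½ (y_g − ŷ_g)²,   y_g ∈ {+1, −1}
    Δw_i = −Σ_g (y_g − ŷ_g) σ′(z_g) p_gi
    Δb   = −Σ_g (y_g − ŷ_g) σ′(z_g)
    θ ← θ − η Δθ   (full-batch gradient descent)

After training, every gene is ranked by the integrative enrichment
score E_g = Σ_i w_i p_gi; the bias is excluded because it shifts all
genes equally and cannot change the ranking (asserted as a property
test).

**Targets.** The ±1 label coding sits outside the sigmoid's (0,1)
range, so the negative-class loss has a positive floor (½ at ŷ→0) and
full convergence to zero loss is impossible by construction. This
coding is the model's stated design and is the default; a
`targets="01"` option remaps −1→0 for users who prefer a realizable
target. The gradient formulas hold for either coding.

**Initialization.** w_i is preset to feature *i*'s AUC against the
labels when that AUC exceeds 0.5, else 0; b = 0. This starts the model
at an already-informative linear combination and implicitly performs
feature selection (see *In-sample bias* below).

**Optimization parameters.** η = 1e−3, max_iter = 10000, tol = 1e−8
(stop when |L(k) − L(k−1)| < tol), all configurable and logged. These
are conservative: on raw fold-change features (scale 1–50) the sigmoid
saturates for most genes and gradients are small, so training refines
rather than replaces the AUC initialization. σ′ is computed as
ŷ(1−ŷ), algebraically identical to e^{−z}/(1+e^{−z})², and the
sigmoid uses scipy's branch-stable `expit`, so pre-activations of any
magnitude neither overflow nor lose monotonicity. A non-finite loss
aborts with an error naming η as the likely cause.

## Differential-expression scores

**Fold change (primary).** p_gi = mean over all |A|×|B| cross pairs
(a, b) of max(a/b, b/a). Requires strictly positive values (the zero
filter guarantees this); always ≥ 1, with equality iff every pair is
equal. The implementation canonicalizes the group order internally so
that swapping the groups returns a bit-identical vector. FC is
computed on the linear (per-sample-total) scale: ratios of
log-transformed values are not fold changes.

**Welch |t| (comparator).** The unequal-variance two-sample t
statistic in absolute value, so larger is always more differential.
Zero-variance degenerate genes score 0 when the group means are equal;
an infinite statistic is replaced by the largest finite score in the
vector and logged. Both groups need ≥ 2 samples.

**Contrast grid.** Per tissue one intra-tissue normal-vs-case contrast
(all case genotypes pooled); per unordered tissue pair one
normal–normal and one case–case contrast. T tissues give T + 2·C(T,2)
contrasts — 9 for the canonical three-tissue design. Contrasts whose
groups cannot be formed are omitted with a warning.

## Filtering

1. Zero filter: keep exactly the genes positive in every sample.
2. Per-sample total normalization to 1e6 (counts-per-million
   convention).
3. Per tissue, rank genes by unbiased variance (divisor n−1) over that
   tissue's samples and keep the top k (default 4000); ties at the
   cutoff break by lexicographic gene id.
4. Retain the union across tissues.

Variance ranking runs on the log2 scale (`variance_normalize="both"`)
so it is library-size- and scale-stable, while the returned matrix is
on the linear per-sample-total scale that fold-change scoring needs.
These two scales are deliberately decoupled parameters of
`select_genes`: a single shared scale would either distort variance
ranking (raw scale) or break fold-change semantics (log scale).

## Evaluation conventions

* **AUC** is the Mann–Whitney probability P(score_pos > score_neg)
  with half credit for ties, computed from average ranks; identical to
  the trapezoidal area under the tie-aware ROC polyline. Verified
  against exhaustive pair counting.
* **AUPR** is average precision — the mean of the precision at each
  positive's rank, with ties broken by ascending gene id before
  ranking. No PR-curve interpolation, which is optimistically biased.
  The summation uses compensated (fsum) accumulation.
* **Overlap degree** of two rankings at depth N is
  |top-N(a) ∩ top-N(b)| / N (denominator N, not the union size).
* Ranked lists break score ties by ascending lexicographic gene id, so
  all outputs are deterministic.

**In-sample bias.** Because the initialization thresholds each
feature's *training-label* AUC at 0.5, features that correlate with
the labels by chance are kept and anti-correlated ones dropped;
evaluating on those same labels therefore yields AUC > 0.5 even on
label-free data (≈0.56 with 178 labeled genes and 9 features, ≈0.66
with 24 — the bias grows as labeled sets shrink). The stratified
k-fold mode (`cross_fit_scores`) trains each fold's model without the
held-out genes and scores them out of fold; on null data its AUC
averages 0.5 as it should. Reported in-sample metrics on small labeled
sets should be read with this bias in mind.

## Robustness experiment

For each of n_repeats (default 5): remove drop_count (default 2)
samples uniformly at random from every tissue-genotype replicate group
(a global-drop variant exists behind `per_group=False`), rebuild the
contrast grid and fold-change features on the survivors, re-initialize
and retrain the neuron, and re-rank. The report contains every
pairwise top-N overlap (default N = 500) and their mean; drop_count = 0
forces a mean of exactly 1. Each repeat's randomness comes from a
spawned child of one seed, so reports are bit-reproducible.
Retraining happens per repeat; weights are never reused across
repeats.

## Synthetic data generator

Expression is log-normal:

    value(g, s) = exp(μ_g + τ_{g,tissue(s)} + δ_{g,genotype(s)} + ε_{g,s})

| parameter | default | meaning (log_e units) |
|---|---|---|
| baseline_log_mean / sd | 3.0 / 1.0 | gene baseline μ_g ~ N |
| tissue_effect_sd | 0.5 | per-gene per-tissue offset τ ~ N(0, ·²) |
| disease_intertissue_effect | 1.5 | added to τ of planted genes in the designated disease tissue |
| disease_case_effect | 0.5 | max case shift δ of planted genes |
| noise_sd | 0.3 | per-value noise ε ~ N(0, ·²) |
| layout | 3×6×8 | tissues × genotypes × replicates = 144 samples |
| n_genes / n_disease | 2000 / 89 | genes / planted disease genes |

Design choices:

* **Log-normal, not counts.** Fold-change scoring operates on
  continuous positive values as processed expression data do;
  log-normality gives strict positivity and a natural additive
  log-scale effect algebra. No read-level or dispersion modelling.
* **Tissue-selective disease signature.** All planted genes carry the
  inter-tissue offset in one designated tissue (default the first),
  emulating a disease whose signature concentrates in a primary
  affected tissue. This makes the corresponding inter-tissue
  normal–normal contrasts the informative features by construction.
* **Heterogeneous case response.** δ is scaled per planted gene by a
  half-normal responsiveness m_g ~ |N(0,1)| and grows linearly with
  genotype severity (an allelic-series analogue). Without m_g, a
  uniform case effect makes the intra-tissue normal-vs-case comparator
  perfectly separating at low noise — the opposite of the
  weak-case-signal regime the method targets.
* **Labels** mark planted genes +1 and an equal-sized random
  background subset −1; the rest stay unlabeled, so ranking operates
  on a superset of the labeled genes.

What the generator does **not** emulate: library-size variation, batch
effects, gene–gene correlation, count noise, and realistic effect-size
distributions. Passing tests on synthetic data therefore demonstrate
algorithmic correctness and qualitative behaviour (signal recovery,
inter- vs intra-tissue ordering, stability), not quantitative
performance on any real dataset.

**Composition effects.** Per-sample-total normalization couples genes
through the library total: if a large fraction of genes is strongly
shifted in one tissue, every other gene in that tissue appears shifted
the opposite way after normalization. At realistic planted fractions
(a few percent or less, as in real genomes) the artifact is
negligible; synthetic benchmarks in the test suite therefore use a
~2 % planted fraction.

## Problem sizes

The test suite and the acceptance script run on simulated data scaled
to desk size, chosen as the package's own benchmark sizes: unit and
property tests use 80–500 genes; the seed-averaged Monte-Carlo checks
use 20 seeds at 300–400 genes; the acceptance script uses 2000 genes ×
144 samples, per-tissue top-800 filtering, 9 contrasts, 10000 training
iterations, and a 5-repeat drop-2 robustness run. The full-genome
configuration (23351 genes, top-4000 filtering) is available through
the same interfaces.

## Known limitations

* The ±1-target sigmoid model cannot drive the loss to zero; loss
  values are comparable only within a run.
* In-sample evaluation is biased upward by the AUC-thresholded
  initialization (see above); use the k-fold mode when the metric
  matters.
* Mean pairwise fold change is sensitive to outlier samples (no
  trimming or moderation is applied, by design).
* No multiple-testing machinery: scores are ranking statistics, not
  calibrated significance measures.
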