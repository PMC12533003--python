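# Methods

This note documents the models, algorithms and design choices behind
`multipcr`, in the order the pipeline runs them.

## The amplification model

In multi-template PCR all templates share terminal adapters, so per-cycle
duplication probabilities differ only through template-internal sequence
features. Writing `x_i(c)` for the mean-normalised coverage of template `i`
after `c` cumulative cycles, the package uses the two-parameter exponential
model

    x_i(c) = x_i(0) · ε_i^c

with `x_i(0)` the relative initial abundance left by array synthesis and
`ε_i` the relative per-cycle amplification efficiency. Because the model is
exponential, tiny deficits compound: ε = 0.95 gives a 0.95¹² ≈ 0.54 relative
abundance after 12 cycles (≈ two-fold underrepresentation), and the halving
time in cycles is ln(½)/ln(ε) — ≈ 3 cycles at ε = 0.80 and ≈ 14 cycles at
ε = 0.952. These identities are exposed as `fold_change` and
`cycles_to_halve`.

### Estimation

Taking logs linearises the model: `log x_i(c_j) = log x_i(0) + c_j·log ε_i`
over the serial-amplification observation points `c_j = 15, 30, …, 90`. The
global least-squares system over all sequences is block-diagonal (no
parameter is shared between sequences), so the implementation solves one
closed-form two-parameter ordinary least squares per sequence;
`fit_global_sparse` keeps the literal sparse global solve as an equivalence
check. Numerical choices:

- Zero-coverage observations are dropped (their log is undefined). A
  sequence with fewer than two positive observations is *unestimable* and
  reported as NaN rather than imputed.
- Sequences observed in fewer than two sequencing runs are excluded before
  fitting (`min_runs = 2`). Such dropouts are plausibly very poor
  amplifiers, but their parameters cannot be estimated; a flag
  (`include_dropouts`) can force-label them positive.
- Both parameter vectors are divided by their mean over estimable sequences
  (linear scale), making `ε` and `x0` relative quantities with mean 1.
- The rounded halving time uses round-half-to-even.

The low-efficiency label takes the bottom 2% of estimable sequences by ε
(ties broken by (ε, id) so labelling is deterministic); 2% reflects the size
of the poorly amplifying tail seen in random-sequence pools, and the
fraction is a parameter.

## The digital twin

`multipcr.twin` simulates the serial dilute–amplify–sequence protocol as a
Galton–Watson branching process: each molecule duplicates per cycle with
probability `p_i`, iterations comprise a 3800× dilution (multinomial
subsample), 15 PCR cycles, and a multinomial draw of the read budget.
Defaults and their provenance:

- `cycles_per_iteration = 15`, `n_iterations = 6`, `dilution_factor = 3800`
  (7600× is the plateau-avoidance variant, selectable): the serial protocol
  constants.
- `molecules_per_design = 5e4`: a 0.1 ng template aliquot of 149-mers spread
  over ~12,000 designs contains a few times 10⁴ molecules per design; the
  twin's bottleneck noise then matches the protocol's rather than being
  artificially inflated by a tiny budget.
- `synthesis_bias_sigma = 0.30`: lognormal spread of initial abundances,
  the typical synthesis-bias dispersion of array-synthesised pools. The
  distribution family is configurable.
- `relative_efficiency_sigma = 0.01` plus a 2% tail with deficits of
  5–20%: templates in real pools differ by a few percent in efficiency,
  with a small subset as low as ~80% of the pool mean.
- Absolute efficiency 0.90 per cycle. A requested relative efficiency ε is
  realised as duplication probability `p_i = ε·(1 + p̄) − 1`, so the
  *per-cycle growth factors* `1 + p_i` have the requested ratios.
- The plateau cap scales duplication probabilities down linearly near a
  resource ceiling; the default protocol avoids the plateau by dilution, so
  the cap is off by default.

A noiseless mode (`noiseless_trajectory`) evaluates the model identity
exactly and serves as the estimator's oracle: on such data the fit recovers
the parameters to ~1e−9 after normalisation.

What the twin does *not* model: polymerase errors and per-base sequencing
errors, primer-dimer and chimera formation, paired-end read structure, and
thermodynamic cycle-level kinetics. Tests passing on twin data therefore
demonstrate estimator/classifier correctness under realistic sampling and
branching noise, not robustness to base-level artefacts.

## Classifiers

Inserts (108 nt; the constant adapters carry no label information) are
one-hot encoded (A, C, G, T). The main model projects the one-hot input to
`d` channels (default 64; 32 in the fast benchmark configuration), adds the
sinusoidal positional encoding

    PE(p, 2i) = sin(p / 10000^(2i/d)),   PE(p, 2i+1) = cos(p / 10000^(2i/d)),

element-wise, then applies 1–3 blocks of (1-D convolution, batch
normalisation, ReLU), global mean or max pooling, and a linear logit.
Training minimises class-weighted binary cross-entropy (positive-class
weight = negatives/positives) with Adam; the search grid covers layer count
{1,2,3}, filters {32,64,128}, filter length {4,8,12}, learning rate
{1e−3,1e−4,1e−5}, pooling {mean,max}, batch size {64,128,256} and weight
decay {0,1e−3,1e−4}. Training defaults to 50 epochs with early stopping on
validation average precision (patience 10); a dropout rate is exposed on the
model builder but defaults to 0 and sits outside the search grid. The default configuration (1 layer, 32 filters of length 8,
lr 1e−3, **max** pooling) is what a small randomised search selects on the
planted-motif benchmark — max pooling suits detection of a single localised
motif far better than mean pooling, which dilutes the signal by the sequence
length.

The network stack (layers, backpropagation, Adam, batch-norm, bidirectional
recurrent layer) is implemented in numpy inside `multipcr.nn`; gradients are
verified against finite differences in the test suite, and a full backward
pass returns input gradients, which the attribution step reuses.

Baselines: the same CNN without the positional-encoding addition; a small
bidirectional tanh recurrent network over the one-hot input (a deliberately
simple stand-in for a gated recurrent baseline); LightGBM on positional
k-mer indicator features (one column per (offset, k-mer), k ∈ {3,4,5}, the
4-mer model being the strongest); and an L1-regularised logistic regression
on the five composition features (four base frequencies + GC content).

Evaluation uses stratified 5-fold nested cross-validation: 10% of each
fold's training data is carved out for hyperparameter selection, sampled
configurations are ranked by mean validation AUPRC across folds, and the
winner is retrained per fold and scored on the held-out fold (AUROC and
AUPRC, mean ± sd). AUROC/AUPRC are computed with scikit-learn and pinned
against brute-force pair-counting / rank-integration oracles in the tests.

## CluMo: motif discovery via attribution and clustering

Step 1 — attribution. Integrated Gradients against the uniform "average
sequence" reference (0.25 per channel), computed on the model logit with a
midpoint-rule path integral (32 steps by default). The backend is pluggable;
any method yielding per-nucleotide scores fits. Channel scores at a position
are summed (preserving the completeness property, checked in tests); taking
only the observed base's channel is available as an option.

Step 2 — candidates. For each low-efficiency sequence and each window size
w ∈ [4,12], the window with the highest cumulative attribution is the
candidate k-mer; ties go to the leftmost window. Candidates come from the
low-efficiency set only.

Step 3 — clustering. Per window size: pairwise Hamming distances between
unique candidates, t-SNE embedding of the distance matrix into 2-D
(perplexity min(30, (n−1)/3), seeded), then weighted k-means with
multiplicity weights. The cluster count C ∈ [2,12] (truncated to n−1)
maximises the multiplicity-weighted mean silhouette in the embedded space.
Each cluster yields a position weight matrix of weighted per-position base
frequencies (no pseudocounts for scoring; a 1e−3 pseudocount is applied only
for log-odds export).

Step 4 — presence and enrichment. The presence score of PWM `P` in a
sequence is `max_i ⟨P, W_i⟩ / k` over all one-hot windows `W_i`; a score
≥ 0.5 calls the motif present. Presence/absence against low/normal
membership forms a 2×2 table tested with Pearson's chi-squared *without*
continuity correction (a flag restores Yates); p-values are
Bonferroni-corrected over all PWMs tested across all window sizes.
Zero-margin tables are skipped with a flag, and tables violating Cochran's
rule (any expected cell count below 5) are flagged invalid rather than
called significant — the chi-squared approximation is anti-conservative
there, and such tables arise precisely for rare-presence PWMs whose only
matches are the sequences that contributed their own member k-mers (the
selection circularity of testing enrichment on the candidate-source set).
Genuinely enriched motifs have presence counts far above this floor.

Step 5 — substitution. Significant motifs, most significant first, are
cumulatively substituted in held-out sequences: the best-matching window per
sequence (when called present) is replaced by the average one-hot element
(0.25 per channel; deterministic default) or by random bases behind a seeded
flag. Only the argmax window is substituted and already-substituted regions
are not re-scanned. The model is re-scored after each prefix, tracing
AUROC/AUPRC against the number of substituted motifs.

Coordinates everywhere are 0-based, half-open, relative to the insert start.

## Screening

- `adapter_complement_scan` reports maximal exact reverse-complement matches
  (stem ≥ 4 nt) between the insert and the 5'-terminal 8 nt of the 5'
  adapter or the 3'-terminal 8 nt of the 3' adapter — the stems of
  self-priming hairpins. Loop lengths grow as the motif moves away from its
  adapter, which destabilises the hairpin; this is why inhibitory motifs
  concentrate near the adapters.
- The constraint filter removes inserts outside 40–60% GC, with
  homopolymers longer than 4, or with hairpin free energy below
  −15 kcal/mol. The default free-energy backend is a deliberately simple
  stem-counting heuristic (−2 kcal/mol per G:C pair, −1 per A:T, logarithmic
  loop penalty); any full secondary-structure predictor can be plugged in
  behind the same interface, and conclusions drawn from the default backend
  are limited to screening-grade discrimination.
- The model filter removes the same *number* of designs as the constraint
  filter, ranked by classifier score, making the two directly comparable.
- `depth_recovery_curve` downsamples a read-count column multinomially
  (30 replicates by default), reports mean recovery (fraction of designs
  with ≥ 1 read; the read threshold is configurable) per depth, and linearly
  interpolates the minimum depth reaching a 99% recovery target.

## The benchmark generator

`multipcr.benchmark` builds fully offline study conditions: a random pool in
which any insert carrying a CGTG-family motif (CGTG, CGTGT, TCGTGT) starting
within 10 nt of the 5' end is penalised by the motif's base deficit (8, 12,
16% respectively) decayed by exp(−offset/25 nt). Motifs are additionally
planted into 2% of designs to raise carrier prevalence, and chance carriers
among the random designs are penalised by exactly the same rule — the
penalty is a deterministic function of the sequence, as a physical mechanism
must be. Ground truth (true ε, carrier motif and offset) is returned
alongside twin coverage, fitted estimates and labels, so recovery can be
measured end to end. Labels are derived from the *fitted* efficiencies, so
label noise from estimation is part of the benchmark by construction;
dropouts are excluded from classifier data rather than mislabelled negative.

Problem sizes used in the shipped tests — 5,000-design pools for end-to-end
discovery, 2,000 designs for estimator-recovery and screening properties,
10 replicate seeds for stochastic claims — keep the full suite comfortably
on one CPU while leaving all signals far from threshold.

## Known limitations

- The twin's branching-process PCR omits plateau chemistry except via the
  optional resource cap, and its synthesis-bias family (lognormal) is an
  assumption, not a measurement.
- The free-energy backend is a heuristic; absolute ΔG values are not
  comparable to secondary-structure predictors, only the induced ordering
  is used.
- The recurrent baseline is a vanilla bidirectional tanh network, simpler
  than gated architectures; it serves as an architecture-class baseline,
  not a tuned competitor.
- Attribution uses Integrated Gradients; other backends (e.g.
  reference-propagation methods) may attribute differently near batch-norm
  layers, though the clustering and enrichment stages are agnostic to the
  backend.
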