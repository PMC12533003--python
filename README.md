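# multipcr

Tools for quantifying, predicting and explaining **sequence-specific
amplification efficiency in multi-template PCR** — the situation in amplicon
sequencing, metabarcoding and DNA data storage where thousands of templates
sharing constant terminal adapters are amplified together, and small
per-template efficiency differences compound exponentially into severe
coverage skew and dropout.

## Who this is for

Anyone designing or analysing pooled amplicon libraries: DNA-data-storage
codecs screening candidate sequences, sequencing facilities diagnosing
coverage skew, and method developers who need a reproducible, fully
synthetic test bed for efficiency estimation and motif discovery.

## The model

Relative coverage of template *i* after *c* cumulative PCR cycles follows

```
x_i(c) = x_i(0) · ε_i^c
```

where `x_i(0)` is the synthesis bias (relative initial abundance) and `ε_i`
the relative per-cycle amplification efficiency (pool mean 1). Taking logs
gives a linear system solved by per-sequence least squares; both parameter
vectors are normalised to their mean. The exponential form is what makes
small deficits matter: a template at ε = 0.95 is ~2× underrepresented after
just 12 cycles, and ε = 0.80 halves relative abundance every ~3 cycles.

On top of the estimator the package provides:

- **`pool`** — synthetic 149 nt oligo design (20 nt 5' adapter + 108 nt
  insert + 21 nt 3' adapter), unconstrained (`GCall`) or exact-50%-GC
  (`GCfix`) inserts, and motif-insertion pools for validation.
- **`twin`** — a stochastic digital twin of the serial
  dilute–amplify–sequence protocol (6 × 15 cycles, 3800× dilutions,
  multinomial sequencing) with per-molecule branching-process PCR.
- **`efficiency`** — the two-parameter fit, occurrence filtering, 2%
  low-efficiency labelling, and the analytic fold-change/halving-time
  helpers.
- **`classify`** — a numpy 1-D CNN with sinusoidal positional encoding,
  baselines (CNN without PE, bidirectional RNN, positional-k-mer LightGBM,
  composition-only lasso logistic regression), class-weighted training and
  stratified nested cross-validation with randomised hyperparameter search.
- **`clumo`** — CluMo, global motif discovery from a trained model:
  attribution (Integrated Gradients by default), per-window candidate
  k-mers, Hamming/t-SNE/weighted-k-means clustering into position weight
  matrices, χ² presence-enrichment with Bonferroni correction, positional
  profiles, and cumulative motif-substitution analysis.
- **`screening`** — adapter-complementarity (self-priming hairpin) scans,
  the classical GC/homopolymer/ΔG constraint filter, matched-count
  model-score filtering, and sequencing-depth recovery curves.
- **`benchmark`** — fully offline study conditions: CGTG-family motifs near
  the insert 5' end convey efficiency penalties through a deterministic
  sequence rule, providing ground truth for every stage.

## Worked example

Generate a 1,000-design benchmark pool in which any insert carrying a
CGTG-family motif within 10 nt of the 5' adapter amplifies poorly, simulate
the serial protocol, and fit the model:

```python
import numpy as np
from multipcr import efficiency
from multipcr.benchmark import BenchmarkScenario, make_benchmark

bundle = make_benchmark(BenchmarkScenario(n_designs=1000), seed=0)
est = bundle.estimates
m = est["estimable"].to_numpy()
r = np.corrcoef(bundle.truth["eps_true"].to_numpy()[m], est["eps"].to_numpy()[m])[0, 1]
print(f"estimable sequences : {int(m.sum())} / {len(est)}")
print(f"labelled low-eff    : {int(bundle.labels.sum())}")
print(f"Pearson r(eps_true, eps_hat) = {r:.3f}")
for sid, row in est[m].sort_values("eps").head(3).iterrows():
    tr = bundle.truth.loc[sid]
    print(f"  {sid}: eps_hat={row.eps:.3f}  true={tr.eps_true:.3f}  motif={tr.motif}@{tr.offset}")
```

prints

```
estimable sequences : 992 / 1000
labelled low-eff    : 19
Pearson r(eps_true, eps_hat) = 0.915
  SEQ_00186: eps_hat=0.854  true=0.883  motif=TCGTGT@5
  SEQ_00226: eps_hat=0.854  true=0.901  motif=CGTGT@5
  SEQ_00250: eps_hat=0.865  true=0.914  motif=CGTG@0
```

Eight designs dropped out of sequencing entirely (unestimable), the bottom
2% of the rest are labelled low-efficiency, the fitted efficiencies track
the planted truth (r ≈ 0.92), and the worst performers are exactly the
designs carrying a CGTG-family motif adjacent to the 5' adapter — the
self-priming signature. The analytic helpers put numbers on the damage:
`efficiency.cycles_to_halve(0.80)` → `3.11` cycles and
`efficiency.fold_change(0.95, 12)` → `0.540` (≈ 2× underrepresentation).

From the shell, the same stages are available as subcommands:

```bash
multipcr design-pool --n 1000 --gc-mode GCfix --seed 1 --out pool.fasta
multipcr simulate --pool pool.fasta --seed 2 --out-prefix run
multipcr fit --coverage run.coverage.tsv --label-fraction 0.02 --out estimates.tsv
multipcr train --pool pool.fasta --labels estimates.tsv --arch cnn_pe --out pred.tsv
```

## Layout

```
src/multipcr/        library (pool, twin, efficiency, classify, nn, clumo,
                     screening, benchmark, config, io, cli)
tests/               pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md      models, parameter provenance, design choices, limits
```
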