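# agedrift

Aging as a dissipative process, measured in the embedding space of a
masked-language model (MLM) over single-cell expression tokens.

In a dynamical-systems view of aging, the transcriptomic state of a cell
decomposes into a *conservative* part — recurrent, measure-preserving,
returning to the same states — and a *dissipative* part that wanders and
never comes back.  `agedrift` operationalizes that decomposition for gene
expression: cells are tokenized (metadata tokens for age bin, tissue, cell
type and disease status, plus one rank-binned expression token per gene),
a small transformer is trained by masked-token prediction, and aging
metrics are read off the embeddings:

* **Embedding drift** of gene *g* at age *t*:
  `D_g(t) = || E_{g,t} − E_{g,t0} ||`, the distance between the gene's mean
  contextual embedding at age *t* and at the earliest (baseline) bin.
* **Conservative / dissipative classification**:
  `G_C = { g : max_t D_g(t) ≤ δ }`, `G_D = G \ G_C`, with δ a percentile
  (default 80th) of the max-drift distribution; plus the per-gene embedding
  variance `σ_g² = (1/N) Σ_i ||E_{g,t_i} − Ē_g||²`.
* **Similarity trajectories**: cosine similarity between gene embeddings
  and the age-token trajectory across the lifespan, and a ranking of
  tissues/cell types by similarity of their static token embeddings to the
  age-token centroid.
* **Aging clock**: mask the age token, restrict the predictive
  distribution to age tokens, and take the expectation of bin midpoints;
  age gaps (predicted − true) are z-scored across the evaluation set.
* **Masked-token entropy**: `H(x) = −Σ_i p(x_i | context) ln p(x_i | context)`,
  the model's uncertainty about a masked token, conditioned on the age
  token — a disorder metric that should rise where transcriptional noise
  rises.
* **Lipschitz estimate**: the empirical ratio `||ΔE|| / (||Δx|| + |Δt|)`
  under one-token perturbations, checking that the embedding is a stable
  proxy for the state.

Real aging atlases are far beyond desk scale, so the package ships a
seeded synthetic corpus generator (`agedrift.synthetic_corpus`) that
plants exactly the structures the metrics are meant to find: genes whose
module loading rotates across age breakpoints (dissipative) vs stays fixed
(conservative), conservative genes that destabilize only under disease,
and tissues whose negative-binomial dispersion ramps with age.  Every
analysis is validated by recovering those planted labels.  A user-supplied
study (MatrixMarket counts + TSV metadata) can be run through the same
pipeline.

The intended audience is computational-biology researchers who want a
tested, fully reproducible reference implementation of these metrics at a
scale that runs on a laptop CPU.

## Worked example

The numbered scripts under `analysis/` run the whole study end to end and
write their tables under `results/artifacts/`:

```sh
python analysis/01_simulate_corpus.py    # synthetic study + planted truth
python analysis/02_train_mlm.py          # tokenize + train the MLM
python analysis/03_aging_clock.py        # age prediction + z-scored gaps
python analysis/04_drift_classification.py
python analysis/05_entropy_by_age.py
python analysis/06_disease_contrast.py
```

Equivalently, the CLI runs individual stages or everything:
`agedrift all --outdir results/artifacts --seed 1`.

On the default corpus (200 genes x 5000 cells x 10 age bins, seed 1) the
scripts print, among other output:

```
simulated 5000 cells x 200 genes, 10 age bins
planted dissipative genes: 40; disease-flipped conservative genes: 40; noise-ramp tissues: [0]
vocabulary: 30 tokens; uniform baseline ln k = 3.401
final held-out masked-token cross-entropy: 1.738 (below the uniform baseline)
clock evaluated on 1000 cells: Pearson r = 0.843
drift threshold delta = 1.5877 at q = 80; 40 genes called dissipative
balanced accuracy vs planted labels: 0.859
empirical Lipschitz ratios over 200 perturbations: L_min = 0.1625, L_max = 7.8611
Spearman rho of mean entropy vs age bin: pooled = 0.7576, healthy = 0.7576, diseased = 0.8061
diseased minus healthy mean entropy in matched bins: +0.0110 nats
planted flipped genes among C->D calls: 12 of 14; log odds = +3.33 (positive association)
```

Read: the model predicts held-out masked tokens far better than chance
(cross-entropy 1.74 vs ln k = 3.40); the masked-age-token clock tracks
chronological age (r ≈ 0.84 here; 0.84–0.94 across seeds); thresholding
max drift at the 80th percentile recovers the planted dissipative genes
well above chance (balanced accuracy ≈ 0.86); per-bin mean entropy rises
with age in the noise-ramp tissue and is higher in diseased cells in every
matched bin; and genes planted to destabilize under disease are strongly
enriched among conservative-to-dissipative label flips (12 of the 14
flips are planted flip genes).

## Layout

```
src/agedrift/        library: synthetic_corpus, tokenizer, nn, mlm,
                     embeddings, clock, dissipation, entropy, recovery,
                     pipeline, cli
analysis/            numbered narrative drivers over the pipeline
scripts/acceptance.py  from-scratch recomputation of the headline metrics
tests/               pytest suite (unit, property, recovery acceptance)
docs/methods.md      model, assumptions, parameter choices, limitations
```
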