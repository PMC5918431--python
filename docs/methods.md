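# Methods

## Model

`mutembed` learns a d-dimensional vector per gene from a cohort of
tumour mutation profiles.  The modelling assumption is distributional:
genes whose mutations co-occur across samples share biology, the way
words sharing sentences share meaning.  Three sources of signal
compose:

1. **Cohort co-occurrence** (always).  Skip-gram with negative
   sampling over (center, context) gene pairs drawn from samples.
2. **Literature context** (`PI` variants).  Word vectors trained on
   biomedical text initialize the embedding lookup matrix for matching
   gene symbols, importing contextual knowledge (driver genes are
   discussed with therapeutic/oncogenic vocabulary) that the cohort
   alone cannot supply.
3. **Interaction structure** (`R` variants).  A quadratic retrofitting
   step pulls each vector toward its one-hop protein-interaction
   neighbours while anchoring it to its trained position.

### Context construction

Mutation sets are unordered, so positional windows are meaningless; a
window shifted across an arbitrary serialization of a set would encode
the serialization, not biology.  Instead each sample yields
`draws_per_sample = 10` independent subsets of `draw_size = 10` genes
(uniform, without replacement within a draw; the whole sample when it
has fewer genes), and every ordered pair within a subset is emitted.
Consequences:

* a sample with ≥ 10 mutations contributes exactly 900 pairs, so
  hypermutated samples are used *less* per mutation — a deliberate
  robustness property, since extreme mutation counts are dominated by
  noise;
* a sample with few mutations is used in full on every draw, so sparse
  (information-dense) samples are weighted up;
* forming **all ordered pairs** within a drawn subset (rather than
  sliding any window inside it) treats the subset as mutual context;
  this is the only reading consistent with the unordered-set argument
  above.

Samples with fewer than two in-vocabulary genes are skipped with a
warning: no pair is derivable.

### SGNS

Loss per pair (i, j) with noise set D_i:
`−log σ(u_iᵀv_j) − Σ_{l∈D_i} log(1 − σ(u_iᵀv_l))`, computed
overflow-safe via `log(1+e^{−x})`.  Defaults and reasons:

| parameter | default | why |
|---|---|---|
| `dim` | 300 | matches literature-scale word vectors so pre-initialization is dimension-compatible |
| `negatives_per_pair` | 5 | the standard small-corpus word2vec choice; the noise-set size is fixed per pair |
| noise power | 0.75 | unigram^(3/4) noise distribution |
| `epochs` | 5 | word2vec convention |
| learning rate | 0.025 → 1e-4 linear | word2vec convention; no schedule is canonical for mutation data |
| `min_count` | 1 | cohort vocabularies (~2e4 genes at most) are tiny by text standards |

Initialization is U ~ uniform(−0.5/d, +0.5/d), V = 0 (word2vec
convention; it also makes the zero-parameter loss exactly 2·ln 2 per
pair with one negative).  Negatives are drawn i.i.d. from the noise
distribution with rejection of the current positive context (the noise
set is a subset of the non-context complement in expectation); a
negative may repeat within a pair, and its gradient contribution is
then applied twice — updates are applied row-sequentially precisely so
that this multiset semantics is exact.

Training is single-threaded, traverses the pair stream in its given
order every epoch, and is bit-reproducible under a fixed seed.  Any
non-finite parameter aborts with a learning-rate diagnostic rather
than propagating NaNs.  The exact softmax objective
`J(U,V) = mean log softmax(u_iᵀV)_j` is implemented as a testing
oracle; on desk-scale vocabularies SGNS training must (and does)
increase it.

### Retrofitting

Objective: `J(Q,Q̃) = Σ_i [α_i‖q_i−q̃_i‖² + Σ_{j∈S_i} β_ij‖q_i−q_j‖²]`
with α_i = 1 and β_ij = |S_i|⁻¹, S_i the graph neighbours intersected
with the embedding vocabulary (degrees computed after intersection;
graph nodes without vectors are ignored).  The solver is the classic
in-place iteration

    q_i ← (α_i q̃_i + Σ_{j∈S_i} β_ij q_j) / (α_i + Σ_{j∈S_i} β_ij),

10 sweeps by default, early exit when no vector moves more than
`tol = 1e-6`.

A point of honesty about the numerics: with the degree-based
(asymmetric) weights, this update map is **not** coordinate descent on
J.  It is exact coordinate descent on the degree-weighted energy

    G(Q) = Σ_i |S_i|·α_i‖q_i−q̃_i‖² + Σ_{{i,j} edge} ‖q_i−q_j‖²

(for a constant β: G = Σ_i α_i‖q_i−q̃_i‖² + β Σ_edges ‖q_i−q_j‖²).
G decreases strictly every sweep and the iteration converges to its
minimizer — which is the stationary point of the update map but not,
in general, the minimizer of J.  J always ends below its starting
value when starting from Q = Q̃, but can fluctuate slightly between
sweeps; the two-node example with unit weights converges to J = 8/9
after passing through J = 0.875.  The package exposes both
`retrofit_objective` (J, as defined) and `retrofit_energy` (G, the
quantity the iteration actually minimizes); tests assert monotonicity
of G and overall decrease of J.  The update map itself is kept as the
field's standard retrofitting procedure — its fixed point, not the
J-minimizer, is the published post-processing.

Genes with no in-vocabulary neighbour are left exactly at q̃_i.
Negative (absence-of-interaction) edges are out of scope: the
quadratic pulls vectors together only.

### Evaluation

* **NMI** = MI(Ω,C) / [(H(Ω)+H(C))/2], natural logs (base-invariant),
  0·log 0 ≡ 0.  If both partitions are single-block the measure is
  degenerate; 1.0 is returned (they are identical) with a warning.
* **k-means** runs on the full-dimensional vectors (PCA is display
  only): Lloyd's algorithm, k-means++ seeding, best inertia of 10
  restarts, seeded.
* The driver/passenger check clusters the driver-labelled genes plus a
  random passenger sample with k = 2.  The passenger sample size
  defaults to the driver count — balanced classes make NMI
  interpretable; the CLI exposes `--passenger-sample-size`.  For this
  class-separation check the vectors are L2-normalized first: skip-gram
  embedding norms grow with token frequency, so raw-space k-means can
  latch onto a single high-frequency tight clique (one driver module)
  and split it against everything else, whereas the class signal lives
  in vector direction (cosine similarity, the standard comparison for
  such embeddings).  The identification clustering over the whole
  vocabulary is left in raw space.
* **PCA** applies a deterministic sign convention (largest-|loading|
  coordinate of each axis made positive) so projections are
  reproducible across runs and solvers.
* The binary gene×sample incidence matrix is the no-learning baseline
  representation.

### Enrichment

The driver-identification clustering uses k-means over the whole
vocabulary (k = 200 at cohort scale; k = 20 on the 500-gene synthetic
cohort, keeping the expected cluster size comparable).  "Most
enriched" is the cluster with the **most** driver-labelled members —
a count, not a p-value, criterion — with ties broken by smaller
hypergeometric p, then lower cluster id.  The test population N is the
set of embedded genes (not all human genes), K the driver-labelled
genes among them.  `hypergeom_sf` delegates to scipy's log-space
implementation; an exhaustive-enumeration oracle covers every
parameter combination with N ≤ 25 in the tests.  One-sided Fisher
tests (over-representation; the identity with the hypergeometric tail
is tested against scipy) plus Benjamini–Hochberg step-up (via
statsmodels) handle gene-set enrichment; the background defaults to
the embedded vocabulary and is overridable, because hosted enrichment
platforms use their own backgrounds and produce numerically different
tables on the same input.

## Synthetic data

The generator produces the three inputs with planted ground truth:

* **Cohort** (`n_samples = 400`, `n_genes = 500`, two disjoint 20-gene
  driver modules): a sample expresses each module with penetrance 0.5,
  carrying each module gene with probability 0.9 when it does;
  passenger counts are `round(3.0 · Pareto(α = 2))` (x_m = 1), giving
  the heavy-tailed burden spread of real cohorts — a typical sample
  carries a handful of passengers, rare samples carry hundreds — with
  finite mean.  A sample that would come out empty receives one
  uniform passenger (profiles must be non-empty).  Labels mark module
  genes `known_driver`, the rest `predicted_passenger`.
* **PPI**: stochastic block model, intra-module edge probability 0.8
  (curated complexes are dense), background 0.005.
* **Corpus** (1000 sentences): alternating driver-/passenger-themed
  sentences of 3 gene mentions + 5 filler words; each gene slot is
  from the theme's pool with probability 0.85.  Driver genes therefore
  co-occur with each other and with "driver vocabulary" far more than
  with passengers — the contextual signal literature initialization is
  meant to import.

What the generator does **not** emulate: mutational signatures,
trinucleotide context, per-cancer-type heterogeneity, gene length or
replication-timing covariates of passenger rates, and curation noise
in driver labels.  Passing the planted-recovery tests therefore shows
the pipeline recovers co-occurrence + network + literature structure
when it exists; it does not certify performance on real cohorts,
where driver co-occurrence is weaker and confounded.

## Experiment problem sizes

The packaged experiments (`mutembed.experiments`) run the full
pipeline at d = 300, 5 epochs on the canonical 400-sample cohort: the
driver/passenger recovery over 5 seeds (PI+R vs basic vs random
vectors) and the k = 20 enrichment recovery.  These sizes are the
package's standing study conditions; larger cohorts scale linearly in
samples and epochs.

## Known limitations

* Training is pure-Python/numpy SGD (~25 µs per pair-update); cohorts
  beyond ~10⁵ samples call for a compiled or batched trainer.
* Retrofitting supports positive interactions only.
* The MAF reader consumes only the two columns it needs; variant-level
  filtering (e.g. restricting to protein-altering consequences) is the
  caller's responsibility, upstream.
* Gene identity is by upper-cased symbol; no alias resolution is
  attempted, so inputs drawn from different symbol vintages should be
  harmonized first.
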