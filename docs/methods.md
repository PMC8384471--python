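# Methods

## Model

`mirwalker` predicts unobserved miRNA–disease associations by network
propagation on a two-layer heterogeneous graph. The working assumption
is the standard one in this literature: functionally similar miRNAs
tend to associate with phenotypically similar diseases, so probability
mass seeded at a disease and its known miRNAs should, after diffusion,
accumulate on plausible new partners.

### Similarity layers

**Disease semantic similarity.** Each disease is identified with a term
in a directed acyclic ontology; its DAG is the term plus all ancestors.
Two complementary scores are computed for every term `t` in a disease
`D`'s DAG:

- *Model 1 (depth decay)*: `C_D(t) = max over downward paths from D to
  t of Δ^len(path)`, with `C_D(D) = 1`. The decay `Δ ∈ (0,1)` makes
  distant ancestors matter less. The max (not the sum) over paths is
  used, so a diamond-shaped DAG does not double-count an ancestor.
- *Model 2 (corpus specificity)*: `C(t) = −log(n_t / n_d)` where `n_t`
  is the number of disease DAGs containing `t`. A term present in every
  DAG (the root) contributes 0; rare terms contribute most. The log
  base is a global parameter (natural log by default); since it scales
  numerator and denominator of the similarity alike, the pairwise score
  is base-invariant as long as one base is used throughout.

Either model yields `SS(i,j) = Σ_{t shared} (C_i(t) + C_j(t)) /
(DV_i + DV_j)` with `DV` the sum of a disease's own contributions. The
score is 1 for identical DAGs and 0 for disjoint ones.

**GIP kernels.** The Gaussian interaction profile kernel compares
binary association profiles (matrix rows for diseases, columns for
miRNAs): `K(u,v) = exp(−γ ‖IP(u) − IP(v)‖²)` with `γ = γ′ / mean
squared profile norm`. The normalisation adapts the bandwidth to how
dense the association matrix is. `γ′ = 1` for both node types by
default. If every profile is zero the bandwidth is undefined and the
computation raises rather than guessing.

**Integration.** `SD(u,v)` is the arithmetic mean of the two semantic
models when both diseases have a nonempty DAG, otherwise `KD(u,v)`.
`SM(i,j)` is the supplied functional similarity when the pair is
covered by the input matrix, otherwise `KM(i,j)`. "Has semantic
similarity" is deliberately defined pairwise-by-coverage: it is the
only interpretation that is decidable from the inputs alone.

### Degree-biased transition matrix

With `W = [[SD, A], [Aᵀ, SM]]`, the walker at node `i` picks target `j`
with probability proportional to `W(i,j)·f_j`, where the bias `f_j` is
the target's degree *in the block being traversed*: column sums of
`SD`/`SM` within a layer, column/row sums of `A` across layers. Rows of
nodes that possess at least one association split their mass `(1−λ)`
within-layer / `λ` cross-layer; nodes without associations keep all
mass within their layer, so every row sums to exactly 1. Degree bias
steers the walk toward hubs; with a constant bias the construction
reduces exactly to the unbiased similarity-proportional walk (the
constant cancels), which the test suite asserts.

Similarity self-loops (the unit diagonals of `SD`/`SM`) are retained in
`W` — the within-layer normalisation makes no exclusion of `i = j` —
and also guarantee positive within-layer row mass. A `zero_diagonal`
option removes them; with it, an isolated node can produce a row with
no outgoing mass, which is reported as an error naming the node.

A definitional subtlety: the miRNA-layer branch condition ("does miRNA
`i` have any associated disease") reads the association block by
column, mirroring the disease-layer row test. Both cross-layer blocks
vanish for nodes that fail their test, and no smoothing is applied to
zero-degree targets inside a nonzero row — their probability is simply
0.

### Restart walk and ranking

The seed vector puts `α` on the query disease and spreads `1−α`
uniformly over its known miRNAs; a disease with no known miRNAs cannot
be seeded and is rejected (the model has no cold-start story, by
design). The iteration

    p_{t+1} = (1 − δ)·Mᵀ p_t + δ·p0

is a contraction with factor `(1−δ)` in L1, so it converges
geometrically to `δ·(I − (1−δ)Mᵀ)⁻¹ p0`; both the iterative and the
closed-form route are implemented and cross-checked against each other
(the solver is the oracle for the iterator, never the production path —
the iterator is kept because it scales better and mirrors the
procedure's definition). `M` is defined row-wise (row `i` = moves out
of node `i`), so forward propagation multiplies by `Mᵀ`; a
`literal_orientation` switch propagates with `M` itself for comparison
with formulations written the other way, and is off by default because
it walks the graph backwards. Candidates are the query disease's
unobserved miRNAs, ranked by stationary probability, ties broken by id
for determinism.

## Parameters

| name | meaning | default | rationale |
|------|---------|---------|-----------|
| `Δ` (`decay`) | per-level semantic decay, model 1 | 0.5 | convention of the DAG-similarity literature |
| `log_base` | model-2 logarithm base | e | pairwise score is base-invariant |
| `γ′_d`, `γ′_m` | raw GIP bandwidths | 1.0 | convention of the GIP-kernel literature |
| `λ` | layer-jump probability | 0.5 | no preference between layers |
| `δ` | restart probability | 0.7 | common RWR choice; keeps mass near seeds |
| `α` | disease-layer seed weight | 0.5 | equal trust in both seed types |
| `tol` | L1 convergence tolerance | 1e-6 | ≪ score gaps at these network sizes |
| `max_iter` | iteration cap | 1000 | ≈60 iterations suffice at δ=0.7 |

None of these defaults is privileged; all are exposed as flags and
echoed by every CLI run.

## Evaluation protocol

Local leave-one-out cross-validation: every known association `(d, m)`
with `d` having ≥ 2 known miRNAs is masked in turn (diseases with a
single association are skipped and reported — masking would leave no
seed), the model is refit on the masked matrix, and `m` is ranked among
all miRNAs unobserved for `d` plus itself. Average (mid-)ranks handle
score ties. The per-fold AUC `(N − r)/(N − 1)` equals the fraction of
negatives beaten, ties counting ½, and the reported AUC is its mean
over folds — each fold weighted equally regardless of its candidate
count. This "per-fold-uniform" pooling is also how the ROC is drawn:
the threshold sweeps a normalised rank percentile, so folds of
different sizes are commensurable; the trapezoidal area under that
curve agrees with the mean per-fold AUC up to discretisation.

By default the GIP kernels (and hence `SD`/`SM`) are recomputed from
each masked matrix, honouring the fact that interaction profiles change
when an edge is removed; `recompute_gip=False` freezes the similarity
layers for speed. When the ontology and functional-similarity inputs
cover all nodes the two modes coincide exactly (the kernels never enter
the integrated matrices), which the tests exploit as a consistency
check.

## Synthetic benchmark

The generator plants `k` co-clusters: associations are
Bernoulli(`p_in`) within a cluster and Bernoulli(`p_out`) across;
each cluster's diseases hang off a shared ancestor chain of depth
`dag_depth` under a global root (so same-cluster diseases have high,
hand-computable semantic similarity and cross-cluster pairs share only
the root); the functional-similarity matrix is `fs_signal` on
within-cluster pairs plus symmetric Gaussian noise of scale `fs_noise`,
clipped to [0,1] with unit diagonal. Chains rather than random DAGs
keep the semantic layer hand-derivable; diamond-shaped DAGs are
exercised separately by the unit tests' path-max oracle. All
randomness flows from a single `numpy` generator seed; the same seed
reproduces the dataset bit-for-bit.

The benchmark configuration is 40 diseases and 60 miRNAs in 4 clusters
with `p_in=0.5`, `p_out=0.02`, `fs_signal=0.8`, `fs_noise=0.1`,
`dag_depth=3`: roughly 340 associations, i.e. a sparse matrix with a
strong planted block structure. Recovery is measured by holding out 10%
of associations (never orphaning a disease) and ranking them back; the
structureless control sets `p_in = p_out = 0.1` and `fs_signal = 0`.
Measured under these conditions, held-out recovery reaches a mean AUC
of ≈ 0.87 over five seeds and the control stays at ≈ 0.50 — the signal
the acceptance script re-derives on every run.

What the generator does *not* emulate: the heavy-tailed degree
distributions of curated association databases, ontology DAGs with
multiple inheritance, or realistic similarity score distributions.
Passing the planted-recovery test therefore demonstrates that the
pipeline propagates block structure correctly, not that any particular
AUC will be attained on real catalogues; real-data performance
additionally depends on curation density and on the unprinted
hyperparameters above.

## Numerical choices and degenerate inputs

- Row-stochasticity is asserted at build time (tolerance 1e-9 against
  drift; observed drift is at machine precision) and mass conservation
  of the iterates follows from it.
- Convergence is declared on an L1 change below `tol`; at `δ = 0.7`
  the contraction guarantees convergence within
  `ceil(log tol / log(1−δ))` steps.
- Score ties in rankings are broken lexicographically by miRNA id;
  evaluation uses midranks instead, so a tie contributes ½ win.
- Duplicate association rows collapse with a warning; cyclic ontology
  edges, all-zero GIP profiles, empty inputs, ragged or non-numeric
  matrix files, unknown diseases, and diseases with no known miRNAs all
  raise with specific messages rather than propagating NaNs.
- Identifiers are sorted lexicographically at load, making every output
  independent of input row order.

## Known limitations

- Local ranking only: one disease per query; no global simultaneous
  prediction and no disease-ranking-for-a-miRNA mode.
- No cold start: a disease with zero known miRNAs cannot be queried.
- The ontology reader expects a prepared child→parent TSV; converting
  MeSH XML or OBO releases (and choosing a disease-name→term mapping)
  is out of scope.
- Dense linear algebra throughout: fine for thousands of nodes, not
  engineered for much larger graphs.
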