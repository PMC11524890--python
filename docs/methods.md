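# Methods

This note records the model, the data conventions, the synthetic data
generator, and the numerical/design choices behind `dualsyn`, at the
level of detail a maintainer needs to modify them.

## Data model and preprocessing

**Triplets.** The supervised unit is (drug1, drug2, cell line) with a
LOEWE synergy score. Pairs are unordered: (A, B, c) and (B, A, c) are
the same triplet and are merged before any modeling.

**Replicate filter.** A triplet is excluded when any two replicates
have strictly opposite signs, or when the sample coefficient of
variation sd/|mean| (ddof = 1, computed only for ≥ 2 replicates)
exceeds 0.5. Conventions at the edges: a replicate of exactly 0 is
sign-compatible with either sign; |mean| < 1e−8 with unequal replicates
counts as infinite CV (excluded); a singleton replicate is always kept.
Survivors get the median replicate as their score.

**Class labels.** Regression is the primary task. For classification,
scores above `pos_thr` are *synergistic*, below `neg_thr`
*antagonistic*, and the additive deadband in between is dropped.
The thresholds default to ±10 LOEWE units — a conventional deadband,
configurable, and not a claim about any particular screen.

**Expression.** Cell lines are represented by z-scores per gene of
log2(TPM + 1) over a fixed gene panel. The scaler is fitted on training
cells only and its statistics are frozen into the checkpoint, so
prediction-time cells (including never-seen ones) are transformed
consistently. Zero-variance genes map to 0. Z-scoring is per gene (not
per cell); per-gene is the variant that keeps each gene's dynamic range
comparable across the panel. Panel genes missing from a matrix are
dropped with a warning; an empty panel∩matrix intersection is an error.

## Drug featurization

Atoms are heavy atoms only (implicit hydrogens are encoded as counts).
The 78-dim atom feature row is: atom-symbol one-hot over 43 named
symbols + 1 out-of-vocabulary slot (44), degree one-hot 0–10 (11),
total-H one-hot 0–10 (11), implicit-valence one-hot 0–10 (11), and an
aromaticity flag (1). This layout follows the convention shared by
graph-based drug-response models; the exact recipe is an assumption of
this package and is documented here rather than inferred from any
single source. Out-of-range degree/valence values leave their block
all-zero. Rows are not normalized.

Fingerprints are Morgan/circular, radius 6, default 1024 bits
(configurable; the synthetic experiments use 256 bits for speed).
Radius 6 is unusually wide for Morgan fingerprints but is the
convention this model family uses; the wide radius makes the bit vector
sensitive to large substructures shared between drugs.

## Joint graphs

Drug B's atom indices are offset by n_A; both drugs' bond sets are
preserved verbatim; no join ever creates self-loops or duplicate edges.
Edge-count identities per join: Super-Edge +1, All-nodes +n_A·n_B,
One-super-node +(n_A+n_B), Three-super-nodes +(n_A+n_B+2).

Betweenness centrality uses unordered pairs, endpoints excluded,
unnormalized, unit edge weights (networkx `normalized=False`); for
disconnected molecules (salts) unreachable pairs contribute zero and
the argmax runs over all atoms. Argmax ties break to the lowest atom
index, making anchor selection deterministic. The super edge is an
ordinary undirected edge with no special type; super nodes carry an
all-zero feature row — their role is purely topological, which keeps
featurization model-free (a learned super-node embedding was considered
and rejected for that reason).

## Network

* **GAT (view 1):** three layers, multi-head, heads concatenated after
  every layer (including the last, as the update equation is written),
  LeakyReLU slope 0.2 in the attention logits, self-loops added so a
  node attends to itself, ReLU on layer outputs. Global pooling is max
  by default (mean available). Depth 3 is structural: it lets atomic
  information cross the drug boundary and return.
* **Cell encoder:** two Linear+ReLU layers, default widths 512→256 at
  full panel scale.
* **View 2:** one shared Linear+ReLU drug-on-cell encoder applied to
  [z_cell ‖ fingerprint] for each drug (one weight matrix — the
  equations use a single symbol, so the encoder is shared; this also
  halves the parameters), then a fusion Linear+ReLU over the
  A-then-B concatenation.
* **Prediction net:** three Linear+ReLU layers, then a separate linear
  or softmax head. The defaults are widths (256, 128, 64) at full
  scale. The three-ReLU-layer depth follows the update equations; a
  shallower two-hidden-layer reading of the same chain exists, and the
  deeper form was chosen.
* **Drug-order symmetry:** view 2 and the joint-graph node order are
  order-sensitive while synergy is not, so every training triplet is
  fed in both orders and inference averages both orders. The averaged
  prediction is bitwise symmetric because both calls evaluate the same
  two forward passes. The joint graph itself is built once per
  unordered pair (the GAT is permutation-invariant, so one orientation
  suffices for view 1).

Default hyperparameters (heads = 4, 64 per head, embedding width 256,
dropout 0.2, Adam lr 1e−4, batch 128, early stopping patience 10 on a
10% validation split) are this package's own defaults, chosen as
mainstream values for this architecture family — not reproductions of
any published setting. Everything is exposed as an estimator parameter.
The synthetic-data experiments in the tests and the acceptance script
use a scaled-down configuration (2 heads × 16, widths 64/32, 256-bit
fingerprints, lr 1e−3) so that the whole pipeline trains in minutes on
one CPU; the scaled model is the same architecture at smaller width.

**Numerical backend.** The network runs on a small in-repo reverse-mode
autodiff engine over float64 NumPy arrays (`dualsyn.nn`), with segment
operations (sum / mean / max / softmax over ragged node sets) as the
graph primitives; mini-batches of joint graphs are concatenated into
one disjoint graph with per-node graph ids. Gradients of every
operation are tested against central finite differences. Weight init is
Glorot-uniform from a single `numpy.random.Generator`, so construction,
shuffling and dropout — hence entire training runs — are reproducible
from one seed on CPU. A non-finite loss aborts training with a
diagnostic rather than continuing silently.

## Splits and few-shot adaptation

* `random`: triplets shuffled into 5 folds.
* `pair_out` / `cell_out`: unordered pairs / cell lines partitioned;
  a triplet inherits its entity's fold.
* `drug_out`: drugs partitioned; a triplet is a *test* example of a
  fold when **either** drug is held out there and a *training* example
  only when **neither** is. This keeps train+test = all records per
  fold while guaranteeing no training triplet touches a held-out drug.
  The stricter variant (test requires both drugs held out;
  one-in-one-out triplets are dropped entirely) is available as
  `drug_out_strict`.

The cross-validation harness re-asserts the disjointness contract
inside the loop for every fold, so leakage cannot pass silently.
Repeated CV reports per-fold metrics with mean ± 1.96·sd/√n as the 95%
confidence interval (normal approximation over the fold values).

K-shot adaptation moves k test measurements of one held-out entity
(a cell line's drug combinations under `cell_out`, a pair's cell lines
under `pair_out`) into training, sampled without replacement under a
seed; k exceeding the available measurements moves everything with a
warning. `fine_tune` then continues Adam on all layers at a reduced
learning rate (default 1e−5, i.e. 10× below the training default); an
empty shot set is a strict no-op. Freezing lower layers was considered
and rejected: the models are small enough that full fine-tuning is
stable at the reduced rate.

Degenerate-case policies: Pearson correlation of a zero-variance
prediction (or target) is reported as 0 with a warning rather than NaN;
classification metrics treat the lexicographically larger label
(*synergistic* over *antagonistic*) as the positive class.

## Synthetic data generator

The generator emulates the statistical structure the method assumes,
not any real screen:

* **Drugs:** sampled from ~100 curated real small-molecule SMILES
  (valid chemistry, no network access), padded with generated alkanes
  and alcohols when more are requested.
* **Expression:** log-normal TPM. Log2-scale expression is
  μ_g + √ρ·f_b(g),c + √(1−ρ)·ε with four gene blocks and ρ = 0.7, so
  within-block correlation is ~0.7 and between-block ~0 — a coarse
  stand-in for co-expression modules.
* **Scores:** scale·(0.6·z[fp-AND term] + 0.4·z[structure×expression
  term]) + N(0, noise_sd), scale 15 LOEWE-like units. The first term
  projects the AND of the pair's fingerprints onto fixed random
  coefficients (shared-substructure synergy, the information view 2
  consumes); the second couples the cell's block means to
  pair coefficients derived from the OR of the fingerprints via a fixed
  random map (sample-specific synergy, requiring a structure ×
  expression interaction). Both terms are symmetric in the pair by
  construction. noise_sd defaults to 1.0, i.e. a high-ceiling signal:
  the learnability checks ask whether the architecture *can* recover
  this mechanism, not whether it matches real-screen noise.
* **Replicates:** 3 per triplet at replicate_sd 0.1. A corrupt fraction
  (default 5%) gets either a sign-flipped replicate or a same-sign
  spread with CV > 0.5, exercising both halves of the reliability
  filter. Near-zero true scores can also fail the CV filter naturally —
  as in real screens — so the observed exclusion rate slightly exceeds
  the planted fraction.
* **Domain shift:** on designated cells, a pair-specific offset (a
  third fingerprint projection, scaled by `domain_shift`) is added —
  a systematic, structure-linked lab effect that zero-shot models miss
  and fine-tuning can partially learn from few shots.

What passing these tests shows: the implementation is internally
consistent and the architecture can recover a planted
fingerprint×expression mechanism at desk scale. What it does not show:
performance on real screens, where noise is heteroscedastic,
dose–response surfaces are truncated, and chemistry/expression are far
more diverse than the generator emulates.

## Problem sizes

Training-based checks run at deliberately small scale, chosen as this
package's desk-scale defaults: the learnability check trains on ~1900
filtered triplets (20 drugs, 30 cells) for ≤ 60 epochs; the
fine-tuning check trains three seeds on ~880 triplets each for ≤ 30
epochs and fine-tunes 10 epochs on 50 shots; the overfit check drives
64 noiseless triplets below 1% of the initial training loss (an early
exit on reaching a target loss — `tol` — stops that run once converged).
The acceptance script uses the same sizes and finishes in a few minutes
on one CPU.

## Known limitations

* No bond/edge features; cross edges are typeless.
* No stereochemistry, charges, conformers, or drug–target priors.
* The NumPy backend is CPU-only and unsuited to datasets of >10⁵
  triplets at full model width.
* `cross_validate` refits per fold sequentially; no parallelism.
* Checkpoints store the drug table and scaler but not the expression
  matrix; prediction requires re-supplying expression for the cells to
  be scored.
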