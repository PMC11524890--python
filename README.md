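# dualsyn

Dual-view joint-graph deep learning for predicting the synergy of a
drug combination on a cancer cell line.

## The problem

High-throughput screens measure how pairs of drugs interact on cancer
cell lines: a Loewe-additivity (LOEWE) synergy score per
*(drug1, drug2, cell line)* triplet, positive when the pair does better
than additivity predicts, negative when it antagonizes. Exhaustively
screening all pairs on all samples is infeasible, so models that
predict synergy from drug structure and tumor transcriptome are used to
prioritize experiments. `dualsyn` is for computational pharmacologists
who want such a model together with the evaluation machinery that makes
its numbers believable: replicate-level quality filtering, splits that
actually hold out pairs / cells / drugs, and few-shot fine-tuning for
new samples or laboratories.

## The model

A triplet is embedded through two complementary views:

**View 1 — the drug combination on the cell.** The two drugs' molecular
graphs (heavy atoms, 78 one-hot features per atom) are merged into one
*joint graph* G_AB so that message passing crosses the drug boundary.
The default join, *Super-Edge*, adds a single virtual bond between the
atom of highest betweenness centrality

&nbsp;&nbsp;&nbsp;&nbsp;C_B(v) = Σ_{s≠v≠t} σ_st(v)/σ_st

of each drug (σ_st = number of shortest s–t paths). Alternatives:
*All-nodes* (full bipartite cross-connection), *One-super-node* and
*Three-super-nodes* (virtual hub nodes). A three-layer multi-head graph
attention network with softmax-normalized coefficients

&nbsp;&nbsp;&nbsp;&nbsp;α_ij = softmax_j( LeakyReLU(aᵀ[W h_i ‖ W h_j]) )

encodes the joint graph; global pooling gives the combination embedding
**z**_AB, which is fused with a two-layer MLP embedding **z**_cell of
the cell's z-scored log₂(TPM+1) expression panel:
**z**_ec = ReLU(W [**z**_AB ‖ **z**_cell]).

**View 2 — the combination of per-drug embeddings on the cell.** Each
drug's radius-6 Morgan fingerprint passes, with **z**_cell, through a
*shared* drug-on-cell encoder; the two results are fused:
**z**_ce = ReLU(W [**z**_dcA ‖ **z**_dcB]).

A three-layer MLP over [**z**_ec ‖ **z**_ce] with a linear (regression)
or two-class softmax (classification) head produces the prediction.
Because synergy is symmetric in drug order, training feeds every
triplet in both orders and inference averages the two — predictions are
exactly order-symmetric. The network runs on an in-repo NumPy
reverse-mode autodiff core (no GPU framework required); training is
mini-batch Adam with early stopping, fully reproducible from one seed.

## Worked example

Everything below runs offline on synthetic study data with a *planted*
signal: scores are generated from the AND of the two drugs'
fingerprints plus a fingerprint-weighted interaction with the cell's
co-expression blocks, which is exactly the kind of structure the two
views are designed to capture.

```python
import numpy as np, pandas as pd
from dualsyn import (FixtureSpec, DualSynRegressor, aggregate_triplets,
                     compute_metrics, make_fixture, make_splits)

spec = FixtureSpec(n_drugs=12, n_cells=10, n_genes=32, n_triplets=300,
                   corrupt_fraction=0.1, seed=7)
drugs, expr, syn = make_fixture(spec)      # 900 replicate rows (3 per triplet)
records = aggregate_triplets(syn)          # sign/CV filter + median -> 275 kept

plan = make_splits(records, "random", n_folds=5, seed=0)
X = pd.DataFrame([(r.drug1, r.drug2, r.cell) for r in records],
                 columns=["drug1", "drug2", "cell"])
y = np.array([r.score for r in records])
tr, te = plan.train_mask(0), plan.test_mask(0)

est = DualSynRegressor(
    drug_smiles=dict(zip(drugs.drug_name, drugs.smiles)), expression=expr,
    fp_bits=256, heads=2, gat_hidden=16, cell_hidden=(64, 32), embed_dim=64,
    prednet_dims=(64, 32, 16), epochs=40, batch_size=128, lr=1e-3, seed=1)
est.fit(X[tr], y[tr])
print(compute_metrics(y[te], est.predict(X[te])))
```

Output:

```
{'pcc': 0.844, 'r2': 0.687, 'mse': 31.853, 'rmse': 5.644}
```

275 of 300 triplets survive filtering (the ~10% with corrupted
replicates plus a few naturally unreliable near-zero scores are
dropped), and on the held-out fold the model recovers the planted
signal at Pearson r = 0.84 — most of the score variance, with the rest
lost to mechanism noise and the small training set. Estimators follow
scikit-learn conventions (`get_params`/`set_params`, clone-safe), and a
CLI covers the same pipeline from the shell:

```bash
dualsyn fixtures --out inputs/
dualsyn train --triplets inputs/triplets.csv --drugs inputs/drugs.csv \
              --expression inputs/expression.csv --out model.npz
dualsyn predict --checkpoint model.npz --triplets inputs/triplets.csv \
                --expression inputs/expression.csv --out pred.csv
```

`DualSynRegressor.fine_tune` adapts a trained model to a new cell line
or dataset from k measurements; `make_splits` + `kshot_augment`
implement the matching evaluation bookkeeping.

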