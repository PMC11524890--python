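import numpy as np
import pandas as pd
import pytest

from dualsyn import FixtureSpec, aggregate_triplets, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Small but fully structured synthetic study (drugs, expression, synergy)."""
    spec = FixtureSpec(n_drugs=12, n_cells=10, n_genes=32, n_triplets=250,
                       corrupt_fraction=0.1, seed=7)
    drugs, expr, syn = make_fixture(spec)
    return spec, drugs, expr, syn


@pytest.fixture(scope="session")
def small_records(small_fixture):
    _, _, _, syn = small_fixture
    return aggregate_triplets(syn)


@pytest.fixture(scope="session")
def small_xy(small_records):
    X = pd.DataFrame([(r.drug1, r.drug2, r.cell) for r in small_records],
                     columns=["drug1", "drug2", "cell"])
    y = np.array([r.score for r in small_records])
    return X, y


def tiny_estimator_kwargs(drugs, expr, **overrides):
    """Desk-scale hyperparameters shared across model tests."""
    kwargs = dict(
        drug_smiles=dict(zip(drugs["drug_name"], drugs["smiles"])),
        expression=expr, fp_bits=128, heads=2, gat_hidden=8,
        cell_hidden=(32, 16), embed_dim=32, prednet_dims=(32, 16, 8),
        epochs=3, batch_size=64, lr=1e-3, patience=5, seed=0,
    )
    kwargs.update(overrides)
    return kwargs
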