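"""The dual-view synergy network and its scikit-learn style estimators.

The network predicts the synergy of a drug pair on a cancer cell line
from two complementary embeddings:

* **View 1 — drug-combination-on-cell.** The pair's joint molecular
  graph is encoded by a three-layer multi-head graph attention network
  (GAT) followed by global pooling, giving a combination embedding
  ``z_AB``; the cell line's expression profile passes through a
  two-layer MLP giving ``z_cell``; ``z_ec = ReLU(W [z_AB || z_cell])``.
* **View 2 — combination-of-drug-embeddings-on-cell.** Each drug's
  Morgan fingerprint is concatenated with ``z_cell`` and encoded by a
  shared drug-on-cell layer (same weights for both drugs), and the two
  results are fused: ``z_ce = ReLU(W [z_dcA || z_dcB])``.

A three-layer MLP over ``[z_ec || z_ce]`` plus a linear (regression) or
two-class softmax (classification) head produces the prediction.

Synergy is symmetric in drug order while view 2 is order-sensitive, so
training examples are fed in both drug orders and predictions average
the two orders — making :meth:`predict` exactly symmetric.

Estimators follow scikit-learn conventions: hyperparameters in
``__init__``, ``fit``/``predict`` (/``predict_proba``), fitted
attributes with trailing underscores, ``get_params``/``set_params``
inherited from :class:`~sklearn.base.BaseEstimator`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .chem import DEFAULT_FP_BITS, DEFAULT_FP_RADIUS, DrugLibrary
from .expression import ExpressionScaler
from .graphs import JoinMethod, JointGraph, build_joint_graph

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The GAT depth (3), cell-MLP depth (2) and prediction-MLP depth (3)
    are structural constants of the method; widths, heads, pooling and
    dropout are tunable.
    """

    n_genes: int
    fp_bits: int = DEFAULT_FP_BITS
    node_dim: int = 78
    heads: int = 4
    gat_hidden: int = 64            # per-head width
    pool: str = "max"               # {"max", "mean"} global pooling
    cell_hidden: tuple[int, int] = (512, 256)
    embed_dim: int = 256            # width of z_ec and z_ce
    prednet_dims: tuple[int, int, int] = (256, 128, 64)
    dropout: float = 0.2
    task: str = "regression"        # {"regression", "classification"}
    gat_layers: int = field(default=3, init=False)

    def __post_init__(self):
        if self.pool not in ("max", "mean"):
            raise ValueError("pool must be 'max' or 'mean'")
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")
        if len(self.prednet_dims) != 3:
            raise ValueError("prediction net has exactly three hidden layers")
        if len(self.cell_hidden) != 2:
            raise ValueError("cell encoder has exactly two layers")


class DualViewNetwork(nn.Module):
    """Forward network over an assembled mini-batch (see ``Batch``)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c = self.config = config
        width = c.heads * c.gat_hidden
        self.gats = [
            nn.GATConv(c.node_dim if i == 0 else width, c.gat_hidden, c.heads, rng)
            for i in range(c.gat_layers)
        ]
        self.cell_mlp = nn.MLP([c.n_genes, *c.cell_hidden], rng)
        self.fuse_ec = nn.Linear(width + c.cell_hidden[-1], c.embed_dim, rng)
        self.drug_cell = nn.Linear(c.cell_hidden[-1] + c.fp_bits, c.embed_dim, rng)
        self.fuse_ce = nn.Linear(2 * c.embed_dim, c.embed_dim, rng)
        self.prednet = nn.MLP([2 * c.embed_dim, *c.prednet_dims], rng)
        out_dim = 2 if c.task == "classification" else 1
        self.head = nn.Linear(c.prednet_dims[-1], out_dim, rng)
        self.dropout = nn.Dropout(c.dropout)

    # -- pieces, exposed for inspection/tests --------------------------------
    def encode_graph(self, nodes, edge_src, edge_dst, graph_ids, n_graphs,
                     rng=None, training=False, return_alpha=False):
        """View-1 GAT encoder: joint graphs -> pooled z_AB (B, width)."""
        h = nodes if isinstance(nodes, nn.Tensor) else nn.Tensor(nodes)
        n_nodes = h.data.shape[0]
        alphas = []
        for gat in self.gats:
            if return_alpha:
                h, alpha = gat(h, edge_src, edge_dst, n_nodes, return_alpha=True)
                alphas.append(alpha)
            else:
                h = gat(h, edge_src, edge_dst, n_nodes)
            h = h.relu()
            if training:
                h = self.dropout(h, rng, training)
        if self.config.pool == "max":
            z = nn.segment_max(h, graph_ids, n_graphs)
        else:
            z = nn.segment_mean(h, graph_ids, n_graphs)
        return (z, alphas) if return_alpha else z

    def encode_cell(self, cells, rng=None, training=False):
        z = self.cell_mlp(cells if isinstance(cells, nn.Tensor) else nn.Tensor(cells))
        if training:
            z = self.dropout(z, rng, training)
        return z

    def encode_view1(self, z_ab, z_cell):
        return self.fuse_ec(nn.concat([z_ab, z_cell])).relu()

    def encode_view2(self, fp_a, fp_b, z_cell):
        fa = fp_a if isinstance(fp_a, nn.Tensor) else nn.Tensor(fp_a)
        fb = fp_b if isinstance(fp_b, nn.Tensor) else nn.Tensor(fp_b)
        z_dca = self.drug_cell(nn.concat([z_cell, fa])).relu()
        z_dcb = self.drug_cell(nn.concat([z_cell, fb])).relu()
        return self.fuse_ce(nn.concat([z_dca, z_dcb])).relu()

    def predict_head(self, z_ec, z_ce, rng=None, training=False):
        z = self.prednet(nn.concat([z_ec, z_ce]))
        if training:
            z = self.dropout(z, rng, training)
        return self.head(z)

    def forward(self, batch: dict, rng=None, training=False) -> nn.Tensor:
        z_ab = self.encode_graph(batch["nodes"], batch["edge_src"],
                                 batch["edge_dst"], batch["graph_ids"],
                                 batch["n_graphs"], rng, training)
        z_cell = self.encode_cell(batch["cells"], rng, training)
        z_ec = self.encode_view1(z_ab, z_cell)
        z_ce = self.encode_view2(batch["fp_a"], batch["fp_b"], z_cell)
        return self.predict_head(z_ec, z_ce, rng, training)


def _as_triplet_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        if {"drug1", "drug2", "cell"}.issubset(X.columns):
            return X[["drug1", "drug2", "cell"]].reset_index(drop=True)
        X = X.to_numpy()
    arr = np.asarray(X)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("X must be (n, 3): drug1, drug2, cell")
    return pd.DataFrame(arr, columns=["drug1", "drug2", "cell"])


class _DualSynBase(BaseEstimator):
    """Shared fit/predict machinery for the regressor and classifier."""

    _task = "regression"

    def __init__(self, drug_smiles=None, expression=None, gene_panel=None,
                 join_method="super_edge", fp_bits=DEFAULT_FP_BITS,
                 fp_radius=DEFAULT_FP_RADIUS, heads=4, gat_hidden=64,
                 pool="max", cell_hidden=(512, 256), embed_dim=256,
                 prednet_dims=(256, 128, 64), dropout=0.2, lr=1e-4,
                 epochs=100, batch_size=128, patience=10, val_fraction=0.1,
                 tol=None, seed=0, verbose=False):
        self.drug_smiles = drug_smiles
        self.expression = expression
        self.gene_panel = gene_panel
        self.join_method = join_method
        self.fp_bits = fp_bits
        self.fp_radius = fp_radius
        self.heads = heads
        self.gat_hidden = gat_hidden
        self.pool = pool
        self.cell_hidden = cell_hidden
        self.embed_dim = embed_dim
        self.prednet_dims = prednet_dims
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.tol = tol
        self.seed = seed
        self.verbose = verbose

    # -- featurization cache --------------------------------------------------
    def _setup_features(self, frame: pd.DataFrame) -> None:
        if self.drug_smiles is None or self.expression is None:
            raise ValueError("drug_smiles and expression are required to fit")
        self.library_ = DrugLibrary(dict(self.drug_smiles), self.fp_bits,
                                    self.fp_radius)
        train_cells = sorted(set(frame["cell"]))
        self.scaler_ = ExpressionScaler(panel=self.gene_panel)
        self.scaler_.fit(self.expression[train_cells])
        self._profiles = self.scaler_.profiles(self.expression)
        self._graphs: dict[tuple[str, str], JointGraph] = {}
        self._fps: dict[str, np.ndarray] = {}

    def _joint_graph(self, d1: str, d2: str) -> JointGraph:
        key = tuple(sorted((d1, d2)))
        if key not in self._graphs:
            self._graphs[key] = build_joint_graph(
                self.library_.graph(key[0]), self.library_.graph(key[1]),
                JoinMethod(self.join_method),
            )
        return self._graphs[key]

    def _fingerprint(self, drug: str) -> np.ndarray:
        if drug not in self._fps:
            self._fps[drug] = self.library_.fingerprint(drug)
        return self._fps[drug]

    def _cell_profile(self, cell: str) -> np.ndarray:
        try:
            return self._profiles[cell]
        except KeyError:
            raise KeyError(f"cell line {cell!r} not in the expression matrix")

    def _assemble(self, rows: list[tuple[str, str, str]]) -> dict:
        """Concatenate per-triplet graphs/vectors into one batch."""
        graphs = [self._joint_graph(d1, d2) for d1, d2, _ in rows]
        sizes = np.array([g.n_nodes for g in graphs])
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        nodes = np.concatenate([g.node_features for g in graphs])
        srcs, dsts = [], []
        for g, off in zip(graphs, offsets):
            s, d = g.edge_arrays()
            srcs.append(s + off)
            dsts.append(d + off)
        return {
            "nodes": nodes,
            "edge_src": np.concatenate(srcs),
            "edge_dst": np.concatenate(dsts),
            "graph_ids": np.repeat(np.arange(len(graphs)), sizes),
            "n_graphs": len(graphs),
            "cells": np.stack([self._cell_profile(c) for _, _, c in rows]),
            "fp_a": np.stack([self._fingerprint(d1) for d1, _, _ in rows]),
            "fp_b": np.stack([self._fingerprint(d2) for _, d2, _ in rows]),
        }

    # -- training -------------------------------------------------------------
    def _loss(self, out: nn.Tensor, y: np.ndarray) -> nn.Tensor:
        if self._task == "classification":
            return nn.cross_entropy_loss(out, y)
        return nn.mse_loss(out.reshape(-1), y)

    def _eval_loss(self, rows, y) -> float:
        total, n = 0.0, 0
        for lo in range(0, len(rows), self.batch_size):
            batch_rows = rows[lo:lo + self.batch_size]
            out = self.network_.forward(self._assemble(batch_rows))
            loss = self._loss(out, y[lo:lo + len(batch_rows)])
            total += float(loss.data) * len(batch_rows)
            n += len(batch_rows)
        return total / max(n, 1)

    def _run_training(self, rows, y, lr: float, epochs: int, rng,
                      patience: int | None, history: list) -> None:
        """Mini-batch Adam loop with optional early stopping."""
        n = len(rows)
        n_val = int(round(self.val_fraction * n)) if patience is not None else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        tr_rows = [rows[i] for i in tr_idx]
        tr_y = y[tr_idx]
        val_rows = [rows[i] for i in val_idx]
        val_y = y[val_idx]
        opt = nn.Adam(self.network_.parameters(), lr=lr)
        best_val, best_state, since_best = np.inf, None, 0
        for epoch in range(epochs):
            order = rng.permutation(len(tr_rows))
            ep_loss, seen = 0.0, 0
            for lo in range(0, len(order), self.batch_size):
                idx = order[lo:lo + self.batch_size]
                batch = self._assemble([tr_rows[i] for i in idx])
                out = self.network_.forward(batch, rng=rng, training=True)
                loss = self._loss(out, tr_y[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "reduce the learning rate or check the inputs"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += float(loss.data) * len(idx)
                seen += len(idx)
            train_loss = ep_loss / max(seen, 1)
            entry = {"epoch": epoch, "train_loss": train_loss}
            if n_val:
                val_loss = self._eval_loss(val_rows, val_y)
                entry["val_loss"] = val_loss
                if val_loss < best_val - 1e-12:
                    best_val, best_state, since_best = val_loss, self.network_.state(), 0
                else:
                    since_best += 1
            history.append(entry)
            if self.verbose:
                logger.info("epoch %d: %s", epoch, entry)
            if self.tol is not None and train_loss < self.tol:
                break  # converged to the requested training loss
            if n_val and patience is not None and since_best > patience:
                break
        if best_state is not None:
            self.network_.load_state(best_state)

    def _symmetrized(self, frame: pd.DataFrame, y: np.ndarray):
        """Duplicate every triplet in both drug orders (adjacent rows)."""
        rows, ys = [], []
        for (d1, d2, c), yi in zip(frame.itertuples(index=False), y):
            rows.append((d1, d2, c))
            rows.append((d2, d1, c))
            ys.extend([yi, yi])
        return rows, np.asarray(ys)

    def fit(self, X, y):
        """Train from scratch on triplets X = (drug1, drug2, cell) and y."""
        frame = _as_triplet_frame(X)
        y = self._validate_target(np.asarray(y))
        if len(frame) != len(y):
            raise ValueError("X and y length mismatch")
        self._setup_features(frame)
        rng = np.random.default_rng(self.seed)
        config = ModelConfig(
            n_genes=len(self.scaler_.genes_), fp_bits=self.fp_bits,
            heads=self.heads, gat_hidden=self.gat_hidden, pool=self.pool,
            cell_hidden=tuple(self.cell_hidden), embed_dim=self.embed_dim,
            prednet_dims=tuple(self.prednet_dims), dropout=self.dropout,
            task=self._task,
        )
        self.config_ = config
        self.network_ = DualViewNetwork(config, rng)
        rows, ys = self._symmetrized(frame, y)
        self.history_ = []
        self._run_training(rows, ys, self.lr, self.epochs, rng,
                           self.patience, self.history_)
        self.n_features_in_ = 3
        return self

    def fine_tune(self, X, y, lr: float = 1e-5, epochs: int = 30,
                  patience: int | None = 10, seed: int | None = None):
        """Continue training on new measurements at a reduced rate.

        All layers are updated. An empty ``X`` is a strict no-op (the
        weights are untouched). New cell lines are allowed: their
        profiles are transformed with the frozen scaler statistics.
        """
        check_is_fitted(self, "network_")
        frame = _as_triplet_frame(X)
        if len(frame) == 0:
            return self
        y = self._validate_target(np.asarray(y), refit=False)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        rows, ys = self._symmetrized(frame, y)
        self._run_training(rows, ys, lr, epochs, rng, patience, self.history_)
        return self

    # -- inference ------------------------------------------------------------
    def _forward_scores(self, X) -> np.ndarray:
        """Raw head outputs averaged over both drug orders."""
        check_is_fitted(self, "network_")
        frame = _as_triplet_frame(X)
        outs = []
        for lo in range(0, len(frame), self.batch_size):
            chunk = frame.iloc[lo:lo + self.batch_size]
            rows_ab = [(r.drug1, r.drug2, r.cell)
                       for r in chunk.itertuples(index=False)]
            rows_ba = [(d2, d1, c) for d1, d2, c in rows_ab]
            out_ab = self.network_.forward(self._assemble(rows_ab)).data
            out_ba = self.network_.forward(self._assemble(rows_ba)).data
            outs.append(0.5 * (out_ab + out_ba))
        return np.concatenate(outs) if outs else np.empty((0, 1))

    def get_weights(self) -> list[np.ndarray]:
        check_is_fitted(self, "network_")
        return self.network_.state()

    def set_weights(self, state: list[np.ndarray]) -> None:
        check_is_fitted(self, "network_")
        self.network_.load_state(state)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Serialize weights + config + panel + scaler to one ``.npz``."""
        check_is_fitted(self, "network_")
        meta = {
            "estimator": type(self).__name__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config_).items()},
            "join_method": str(JoinMethod(self.join_method).value),
            "fp_bits": self.fp_bits,
            "fp_radius": self.fp_radius,
            "genes": self.scaler_.genes_,
            "drug_smiles": dict(self.drug_smiles),
        }
        arrays = {f"w{i}": a for i, a in enumerate(self.network_.state())}
        arrays["scaler_mean"] = self.scaler_.mean_
        arrays["scaler_scale"] = self.scaler_.scale_
        if self._task == "classification":
            meta["classes"] = [str(c) for c in self.classes_]
        arrays["meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    def _restore(self, path, expression) -> None:
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            if meta["estimator"] != type(self).__name__:
                raise ValueError(
                    f"checkpoint was written by {meta['estimator']}, "
                    f"not {type(self).__name__}"
                )
            cfg = meta["config"]
            cfg.pop("gat_layers", None)
            for key in ("cell_hidden", "prednet_dims"):
                cfg[key] = tuple(cfg[key])
            config = ModelConfig(**cfg)
            self.drug_smiles = meta["drug_smiles"]
            self.expression = expression
            self.join_method = meta["join_method"]
            self.fp_bits = meta["fp_bits"]
            self.fp_radius = meta["fp_radius"]
            self.config_ = config
            self.scaler_ = ExpressionScaler(panel=meta["genes"])
            self.scaler_.genes_ = meta["genes"]
            self.scaler_.mean_ = z["scaler_mean"]
            self.scaler_.scale_ = z["scaler_scale"]
            self.scaler_.zero_variance_ = self.scaler_.scale_ == 1.0
            if "classes" in meta:
                self.classes_ = np.array(meta["classes"])
            self.network_ = DualViewNetwork(config,
                                            np.random.default_rng(0))
            self.network_.load_state(
                [z[f"w{i}"] for i in range(len(self.network_.parameters()))]
            )
        self.library_ = DrugLibrary(dict(self.drug_smiles), self.fp_bits,
                                    self.fp_radius)
        if expression is not None:
            self._profiles = self.scaler_.profiles(expression)
        else:
            self._profiles = {}
        self._graphs, self._fps = {}, {}
        self.history_ = []

    @classmethod
    def load(cls, path, expression=None):
        """Restore an estimator saved with :meth:`save`.

        ``expression`` supplies profiles for the cells to be scored; the
        frozen scaler statistics from training are reused.
        """
        est = cls()
        est._restore(path, expression)
        return est


class DualSynRegressor(RegressorMixin, _DualSynBase):
    """Dual-view synergy-score regressor (mean-squared-error loss)."""

    _task = "regression"

    def _validate_target(self, y, refit=True):
        y = np.asarray(y, dtype=float)
        if y.ndim != 1:
            raise ValueError("y must be 1-dimensional scores")
        return y

    def predict(self, X) -> np.ndarray:
        """Predicted synergy scores, exactly symmetric in drug order."""
        return self._forward_scores(X).reshape(-1)


class DualSynClassifier(ClassifierMixin, _DualSynBase):
    """Dual-view synergistic-vs-antagonistic classifier (softmax head)."""

    _task = "classification"

    def _validate_target(self, y, refit=True):
        if refit:
            self.classes_, encoded = np.unique(y, return_inverse=True)
            if len(self.classes_) != 2:
                raise ValueError("classifier expects exactly two classes")
            return encoded
        encoded = np.searchsorted(self.classes_, y)
        if not np.array_equal(self.classes_[encoded], np.asarray(y)):
            raise ValueError("y contains labels unseen at fit time")
        return encoded

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities (rows sum to 1), symmetric in drug order."""
        logits = self._forward_scores(X)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
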