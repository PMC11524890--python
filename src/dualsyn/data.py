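"""Synergy triplet handling: replicate filtering, labels, splits, k-shot.

The atomic supervised example is the *triplet* (drug1, drug2, cell line)
with a Loewe-additivity synergy score. Raw screens carry replicate
measurements per triplet; replicates that disagree in sign or vary too
much (coefficient of variation > 0.5) are considered unreliable and the
whole triplet is excluded, otherwise the median replicate becomes the
triplet's score.

Cross-validation supports four strategies with increasing difficulty:

* ``random``   — triplets shuffled into folds;
* ``pair_out`` — whole drug pairs held out;
* ``cell_out`` — whole cell lines held out;
* ``drug_out`` — whole drugs held out: a triplet is a test example of a
  fold when either of its drugs is in that fold, and a training example
  only when neither is (so no training triplet touches a test drug).

``kshot_augment`` implements few-shot adaptation bookkeeping: moving k
measurements of a held-out entity from test into training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel returned by filter_replicates for unreliable triplets
EXCLUDED = "EXCLUDED"
#: sentinel for scores inside the additive deadband
UNLABELED = "UNLABELED"
SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"

DEFAULT_POS_THRESHOLD = 10.0
DEFAULT_NEG_THRESHOLD = -10.0
CV_THRESHOLD = 0.5


class SplitStrategy(str, Enum):
    RANDOM = "random"
    PAIR_OUT = "pair_out"
    CELL_OUT = "cell_out"
    DRUG_OUT = "drug_out"


@dataclass(frozen=True)
class TripletRecord:
    drug1: str
    drug2: str
    cell: str
    score: float
    label: str | None = None

    def __post_init__(self):
        if self.drug1 == self.drug2:
            raise ValueError(f"degenerate pair ({self.drug1},{self.drug2})")

    @property
    def pair(self) -> tuple[str, str]:
        """Order-free pair identity used for deduplication and splits."""
        return tuple(sorted((self.drug1, self.drug2)))


def filter_replicates(scores) -> float | str:
    """Aggregate replicate synergy scores for one triplet.

    Returns the median score, or :data:`EXCLUDED` when the replicates
    are unreliable: any two replicates with strictly opposite signs
    (zero is compatible with either sign), or a sample coefficient of
    variation sd/|mean| above 0.5 (only defined for >= 2 replicates; a
    mean of ~0 with unequal replicates counts as infinite CV).
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty replicate list")
    if (scores > 0).any() and (scores < 0).any():
        return EXCLUDED
    if scores.size >= 2:
        mean = scores.mean()
        sd = scores.std(ddof=1)
        if abs(mean) < 1e-8:
            if sd > 0:
                return EXCLUDED  # CV undefined at zero mean, unequal replicates
        elif sd / abs(mean) > CV_THRESHOLD:
            return EXCLUDED
    return float(np.median(scores))


def label_classes(score: float, pos_thr: float = DEFAULT_POS_THRESHOLD,
                  neg_thr: float = DEFAULT_NEG_THRESHOLD) -> str:
    """Map a synergy score to synergistic / antagonistic / UNLABELED.

    Scores inside the additive deadband [neg_thr, pos_thr] are
    :data:`UNLABELED` and dropped from the classification task.
    """
    if score > pos_thr:
        return SYNERGISTIC
    if score < neg_thr:
        return ANTAGONISTIC
    return UNLABELED


def aggregate_triplets(raw: pd.DataFrame, pos_thr: float = DEFAULT_POS_THRESHOLD,
                       neg_thr: float = DEFAULT_NEG_THRESHOLD) -> list[TripletRecord]:
    """Collapse a replicate-level table into filtered TripletRecords.

    ``raw`` needs columns ``drug1, drug2, cell, score``; multiple rows of
    the same unordered (pair, cell) are replicates. Unreliable triplets
    are dropped; survivors carry the median score and a class label
    (``None`` when inside the additive band).
    """
    required = {"drug1", "drug2", "cell", "score"}
    if not required.issubset(raw.columns):
        raise ValueError(f"triplet table needs columns {sorted(required)}")
    records = []
    key = [tuple(sorted((a, b))) + (c,)
           for a, b, c in zip(raw["drug1"], raw["drug2"], raw["cell"])]
    grouped = raw.assign(_key=key).groupby("_key", sort=True)
    n_excluded = 0
    for (d1, d2, cell), grp in grouped:
        agg = filter_replicates(grp["score"].to_numpy())
        if agg == EXCLUDED:
            n_excluded += 1
            continue
        lab = label_classes(agg, pos_thr, neg_thr)
        records.append(TripletRecord(d1, d2, cell, agg,
                                     None if lab == UNLABELED else lab))
    logger.info("aggregated %d triplets, excluded %d unreliable",
                len(records), n_excluded)
    return records


@dataclass(frozen=True)
class SplitPlan:
    """Fold assignment for one split strategy.

    ``folds[i]`` is the fold of ``records[i]``: the record is a test
    example of that fold and (except under drug_out contamination rules)
    a training example of every other fold. ``train_mask(f)`` /
    ``test_mask(f)`` express the final contract per fold.
    """

    strategy: SplitStrategy
    records: tuple[TripletRecord, ...]
    folds: np.ndarray
    n_folds: int
    seed: int
    drug_folds: dict[str, int] | None = None  # only for drug_out
    drug_out_strict: bool = False             # test requires both drugs held out

    def _touches_fold(self, fold: int) -> np.ndarray:
        return np.array([
            self.drug_folds[r.drug1] == fold or self.drug_folds[r.drug2] == fold
            for r in self.records
        ])

    def test_mask(self, fold: int) -> np.ndarray:
        if self.strategy is SplitStrategy.DRUG_OUT:
            if self.drug_out_strict:
                return np.array([
                    self.drug_folds[r.drug1] == fold
                    and self.drug_folds[r.drug2] == fold
                    for r in self.records
                ])
            # one held-out drug suffices for test membership
            return self._touches_fold(fold)
        return self.folds == fold

    def train_mask(self, fold: int) -> np.ndarray:
        if self.strategy is SplitStrategy.DRUG_OUT:
            # never train on a triplet touching a held-out drug; in the
            # strict variant one-in-one-out triplets are dropped entirely
            return ~self._touches_fold(fold)
        return ~self.test_mask(fold)

    def iter_folds(self):
        for f in range(self.n_folds):
            yield f, self.train_mask(f), self.test_mask(f)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in range(self.n_folds):
            te, tr = self.test_mask(f), self.train_mask(f)
            for i, r in enumerate(self.records):
                if te[i]:
                    rows.append((r.drug1, r.drug2, r.cell, f, "test"))
                elif tr[i]:
                    rows.append((r.drug1, r.drug2, r.cell, f, "train"))
        return pd.DataFrame(rows, columns=["drug1", "drug2", "cell", "fold", "role"])


def _partition(entities: list, n_folds: int, rng: np.random.Generator) -> dict:
    entities = sorted(entities)
    if len(entities) < n_folds:
        raise ValueError(
            f"cannot split {len(entities)} entities into {n_folds} folds"
        )
    perm = rng.permutation(len(entities))
    return {entities[i]: int(f % n_folds) for f, i in enumerate(perm)}


def make_splits(records: list[TripletRecord], strategy: SplitStrategy | str,
                n_folds: int = 5, seed: int = 0,
                drug_out_strict: bool = False) -> SplitPlan:
    """Assign every triplet to a cross-validation fold.

    The grouping entity depends on the strategy (triplet, unordered
    pair, cell line, or drug); identical seeds yield identical plans.
    Under ``drug_out`` a triplet is a test example of a fold when either
    drug is held out there (``drug_out_strict=True`` requires both) and
    a training example only when neither is.
    """
    strategy = SplitStrategy(strategy)
    rng = np.random.default_rng(seed)
    records = tuple(records)
    drug_folds = None
    if strategy is SplitStrategy.RANDOM:
        if len(records) < n_folds:
            raise ValueError("fewer records than folds")
        perm = rng.permutation(len(records))
        folds = np.empty(len(records), dtype=int)
        folds[perm] = np.arange(len(records)) % n_folds
    elif strategy is SplitStrategy.PAIR_OUT:
        assign = _partition(sorted({r.pair for r in records}), n_folds, rng)
        folds = np.array([assign[r.pair] for r in records])
    elif strategy is SplitStrategy.CELL_OUT:
        assign = _partition(sorted({r.cell for r in records}), n_folds, rng)
        folds = np.array([assign[r.cell] for r in records])
    else:  # DRUG_OUT
        drugs = sorted({d for r in records for d in (r.drug1, r.drug2)})
        drug_folds = _partition(drugs, n_folds, rng)
        # fold array records drug1's fold for serialization; membership
        # is derived from drug_folds in test_mask/train_mask
        folds = np.array([drug_folds[r.drug1] for r in records])
    return SplitPlan(strategy, records, folds, n_folds, seed, drug_folds,
                     drug_out_strict)


def kshot_augment(plan: SplitPlan, fold: int, held_out_entity: str, k: int,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Move k test measurements of a held-out entity into training.

    For a ``cell_out`` plan the entity is a cell line and k of its drug
    combinations move from the fold's test set into training; for a
    ``pair_out`` plan the entity is a drug pair (``"drug1+drug2"``, any
    order) and k of its cell lines move. Sampling is without
    replacement; asking for more shots than exist moves everything with
    a warning. Returns (train_mask, test_mask) for the augmented fold.
    """
    if plan.strategy is SplitStrategy.CELL_OUT:
        member = np.array([r.cell == held_out_entity for r in plan.records])
    elif plan.strategy is SplitStrategy.PAIR_OUT:
        pair = tuple(sorted(held_out_entity.split("+")))
        member = np.array([r.pair == pair for r in plan.records])
    else:
        raise ValueError("k-shot augmentation applies to cell_out or pair_out plans")
    train, test = plan.train_mask(fold).copy(), plan.test_mask(fold).copy()
    candidates = np.flatnonzero(member & test)
    if k > len(candidates):
        logger.warning("requested k=%d shots but only %d available; moving all",
                       k, len(candidates))
        k = len(candidates)
    if k > 0:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(candidates, size=k, replace=False)
        test[chosen] = False
        train[chosen] = True
    return train, test
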