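"""Replicate filtering, labels, split plans and k-shot augmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualsyn import (
    EXCLUDED,
    SplitStrategy,
    TripletRecord,
    UNLABELED,
    aggregate_triplets,
    filter_replicates,
    kshot_augment,
    label_classes,
    make_splits,
)


class TestFilterReplicates:
    @pytest.mark.parametrize("scores,expected", [
        ([10, -5], EXCLUDED),              # opposite strict signs
        ([10, 30], EXCLUDED),              # sample CV = 14.14/20 ~ 0.707 > 0.5
        ([10, 12, 14], 12.0),              # CV = 2/12 ~ 0.167, median kept
        ([5.0], 5.0),                      # singleton: CV rule never fires
        ([-3, -4, -5], -4.0),
        ([0, 10], EXCLUDED),               # zero passes the sign rule but
                                           # CV = 7.07/5 ~ 1.41 excludes it
        ([1.0, -1.0], EXCLUDED),           # mean 0, unequal -> infinite CV
        ([2.0, 2.0, 2.0], 2.0),            # equal replicates always kept
    ])
    def test_truth_table(self, scores, expected):
        assert filter_replicates(scores) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            filter_replicates([])

    @given(st.lists(st.floats(min_value=-100, max_value=100,
                              allow_nan=False), min_size=1, max_size=6),
           st.floats(min_value=0.5, max_value=10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_decision_invariant_to_positive_scaling(self, scores, factor):
        """CV and sign consistency are scale-free, so multiplying all
        replicates by a positive constant preserves the keep/exclude
        decision, and a kept score scales along."""
        a = filter_replicates(scores)
        b = filter_replicates([s * factor for s in scores])
        if a == EXCLUDED:
            assert b == EXCLUDED
        else:
            assert b != EXCLUDED
            assert b == pytest.approx(a * factor, rel=1e-9, abs=1e-12)

    @given(st.lists(st.floats(min_value=0.5, max_value=100,
                              allow_nan=False), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_kept_score_is_replicate_median(self, scores):
        result = filter_replicates(scores)
        if result != EXCLUDED:
            assert result == float(np.median(scores))


class TestLabels:
    @pytest.mark.parametrize("score,expected", [
        (50.0, "synergistic"), (0.0, UNLABELED), (-20.0, "antagonistic"),
        (10.0, UNLABELED), (-10.0, UNLABELED),  # thresholds are strict
    ])
    def test_default_band(self, score, expected):
        assert label_classes(score, 10.0, -10.0) == expected


class TestAggregate:
    def test_unordered_pair_dedup(self):
        raw = pd.DataFrame({
            "drug1": ["A", "B", "A"], "drug2": ["B", "A", "C"],
            "cell": ["c", "c", "c"], "score": [10.0, 12.0, 14.0],
        })
        records = aggregate_triplets(raw)
        assert len(records) == 2  # (A,B,c) and (B,A,c) collapse
        ab = [r for r in records if r.pair == ("A", "B")][0]
        assert ab.score == 11.0  # median of the merged replicates

    def test_degenerate_pair_rejected(self):
        with pytest.raises(ValueError):
            TripletRecord("A", "A", "c", 1.0)


def _records(n_drugs=8, n_cells=6, seed=0):
    rng = np.random.default_rng(seed)
    drugs = [f"D{i}" for i in range(n_drugs)]
    cells = [f"C{i}" for i in range(n_cells)]
    recs = []
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            for c in cells:
                if rng.random() < 0.7:
                    recs.append(TripletRecord(drugs[i], drugs[j], c,
                                              float(rng.normal())))
    return recs


class TestSplits:
    @pytest.mark.parametrize("strategy", list(SplitStrategy))
    @pytest.mark.parametrize("seed", range(10))
    def test_disjointness_contracts(self, strategy, seed):
        """No drug pair / cell / drug is shared between a fold's train
        and test sets, per the chosen strategy."""
        recs = _records(seed=seed)
        plan = make_splits(recs, strategy, n_folds=5, seed=seed)
        for fold, tr_mask, te_mask in plan.iter_folds():
            tr = [r for r, m in zip(recs, tr_mask) if m]
            te = [r for r, m in zip(recs, te_mask) if m]
            assert not (np.asarray(tr_mask) & np.asarray(te_mask)).any()
            if strategy is SplitStrategy.PAIR_OUT:
                assert not ({r.pair for r in tr} & {r.pair for r in te})
            elif strategy is SplitStrategy.CELL_OUT:
                assert not ({r.cell for r in tr} & {r.cell for r in te})
            elif strategy is SplitStrategy.DRUG_OUT:
                held_out = {d for d, f in plan.drug_folds.items() if f == fold}
                tr_drugs = {d for r in tr for d in (r.drug1, r.drug2)}
                # no held-out drug leaks into training, and every test
                # triplet contains at least one held-out drug
                assert not (held_out & tr_drugs)
                assert all(r.drug1 in held_out or r.drug2 in held_out
                           for r in te)

    @pytest.mark.parametrize("strategy", list(SplitStrategy))
    def test_record_conservation(self, strategy):
        """Every record is in train or test of every fold, never both."""
        recs = _records()
        plan = make_splits(recs, strategy, n_folds=5, seed=3)
        for fold, tr, te in plan.iter_folds():
            assert (tr | te).all()
            assert not (tr & te).any()

    @pytest.mark.parametrize("strategy", list(SplitStrategy))
    def test_same_seed_same_plan(self, strategy):
        recs = _records()
        a = make_splits(recs, strategy, seed=5)
        b = make_splits(recs, strategy, seed=5)
        assert np.array_equal(a.folds, b.folds)
        for f in range(5):
            assert np.array_equal(a.test_mask(f), b.test_mask(f))

    def test_too_few_entities_errors(self):
        recs = _records(n_drugs=3, n_cells=2)
        with pytest.raises(ValueError):
            make_splits(recs, "drug_out", n_folds=5, seed=0)

    def test_plan_serialization_roundtrip(self):
        recs = _records()
        frame = make_splits(recs, "pair_out", seed=1).to_frame()
        assert set(frame.columns) == {"drug1", "drug2", "cell", "fold", "role"}
        assert set(frame["role"]) == {"train", "test"}


class TestKShot:
    def _cellout_plan(self):
        recs = _records(n_drugs=8, n_cells=10, seed=2)
        plan = make_splits(recs, "cell_out", n_folds=5, seed=2)
        fold = 0
        cell = next(r.cell for r, m in zip(recs, plan.test_mask(fold)) if m)
        return recs, plan, fold, cell

    def test_k_zero_is_identity(self):
        recs, plan, fold, cell = self._cellout_plan()
        tr, te = kshot_augment(plan, fold, cell, k=0)
        assert np.array_equal(tr, plan.train_mask(fold))
        assert np.array_equal(te, plan.test_mask(fold))

    def test_moved_records_change_side_and_conserve(self):
        recs, plan, fold, cell = self._cellout_plan()
        tr0, te0 = plan.train_mask(fold), plan.test_mask(fold)
        tr, te = kshot_augment(plan, fold, cell, k=3, seed=1)
        moved = tr & ~tr0
        assert moved.sum() == 3
        assert not (te & moved).any()
        assert np.array_equal(tr | te, tr0 | te0)
        assert all(recs[i].cell == cell for i in np.flatnonzero(moved))

    def test_k_exceeds_available_moves_all_with_warning(self, caplog):
        recs, plan, fold, cell = self._cellout_plan()
        n_avail = int((np.array([r.cell == cell for r in recs])
                       & plan.test_mask(fold)).sum())
        with caplog.at_level("WARNING"):
            tr, te = kshot_augment(plan, fold, cell, k=10_000)
        assert "moving all" in caplog.text
        assert not (np.array([r.cell == cell for r in recs]) & te).any()
        assert (tr & np.array([r.cell == cell for r in recs])).sum() >= n_avail

    def test_pairout_moves_cells_of_held_out_pair(self):
        recs = _records(n_drugs=8, n_cells=10, seed=4)
        plan = make_splits(recs, "pair_out", n_folds=5, seed=4)
        r0 = next(r for r, m in zip(recs, plan.test_mask(0)) if m)
        entity = f"{r0.pair[0]}+{r0.pair[1]}"
        tr, te = kshot_augment(plan, 0, entity, k=2, seed=0)
        moved = tr & ~plan.train_mask(0)
        assert moved.sum() == 2
        assert all(recs[i].pair == r0.pair for i in np.flatnonzero(moved))

    def test_wrong_strategy_rejected(self):
        recs = _records()
        plan = make_splits(recs, "random", seed=0)
        with pytest.raises(ValueError):
            kshot_augment(plan, 0, "C0", k=1)
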