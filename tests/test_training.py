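import copy

import numpy as np
import pytest

from amfgnn.config import TrainConfig
from amfgnn.datasets import AssociationMatrix
from amfgnn.training import (MetricsError, compute_metrics, make_folds,
                             make_folds_disease_cold, top_candidates,
                             train_fold, train_full)


# --------------------------------------------------------------------------
# folds
# --------------------------------------------------------------------------

def test_folds_partition_all_pairs_4x5():
    folds = make_folds(4, 5, n_folds=10, seed=0)
    assert len(folds) == 10
    test_sets = [set(f.test_pairs) for f in folds]
    assert all(len(s) == 2 for s in test_sets)
    union = set().union(*test_sets)
    assert union == set(range(20))
    for f in folds:
        assert set(f.train_pairs) | set(f.test_pairs) == set(range(20))
        assert set(f.train_pairs) & set(f.test_pairs) == set()


def test_folds_deterministic_given_seed():
    a = make_folds(6, 7, n_folds=5, seed=3)
    b = make_folds(6, 7, n_folds=5, seed=3)
    for fa, fb in zip(a, b):
        np.testing.assert_array_equal(fa.test_pairs, fb.test_pairs)
    c = make_folds(6, 7, n_folds=5, seed=4)
    assert any((x.test_pairs != y.test_pairs).any() for x, y in zip(a, c))


def test_folds_sizes_differ_by_at_most_one():
    folds = make_folds(7, 9, n_folds=10, seed=1)
    sizes = {f.test_pairs.size for f in folds}
    assert max(sizes) - min(sizes) <= 1


def test_folds_argument_errors():
    with pytest.raises(ValueError):
        make_folds(2, 2, n_folds=10, seed=0)
    with pytest.raises(ValueError):
        make_folds(5, 5, n_folds=1, seed=0)


def test_disease_cold_folds_hold_out_whole_columns():
    folds = make_folds_disease_cold(5, 8, n_folds=4, seed=0)
    for f in folds:
        cols = {p % 8 for p in f.test_pairs}
        assert len(f.test_pairs) == 5 * len(cols)
        train_cols = {p % 8 for p in f.train_pairs}
        assert cols & train_cols == set()
    union = set().union(*[{p % 8 for p in f.test_pairs} for f in folds])
    assert union == set(range(8))


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def test_metrics_perfect_separation():
    labels = np.array([1, 1, 0, 0])
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    m = compute_metrics(scores, labels)
    assert m["auc"] == 1.0 and m["recall"] == 1.0 and m["f1"] == 1.0


def test_metrics_anti_separation():
    m = compute_metrics(np.array([0.1, 0.9]), np.array([1, 0]))
    assert m["auc"] == 0.0


def test_metrics_auc_hand_oracle():
    # positives 0.9, 0.7 vs negatives 0.8, 0.1: 3 of 4 pairs concordant
    m = compute_metrics(np.array([0.9, 0.8, 0.7, 0.1]),
                        np.array([1, 0, 1, 0]))
    assert m["auc"] == pytest.approx(0.75)


def test_metrics_invariant_under_monotone_transform(rng):
    labels = (rng.random(40) < 0.3).astype(int)
    labels[:2] = [0, 1]
    scores = rng.random(40)
    a = compute_metrics(scores, labels)["auc"]
    b = compute_metrics(1 / (1 + np.exp(-5 * scores)), labels)["auc"]
    assert a == pytest.approx(b)


def test_metrics_single_class_error_names_fold():
    with pytest.raises(MetricsError, match="fold 3"):
        compute_metrics(np.array([0.1, 0.2]), np.array([1, 1]), fold_id=3)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _first_fold(bundle, cfg):
    return make_folds(bundle.associations.n_drugs,
                      bundle.associations.n_diseases,
                      cfg.n_folds, cfg.seed)[0]


def test_train_fold_deterministic_given_seed(tiny_bundle, tiny_cfg):
    fold = _first_fold(tiny_bundle, tiny_cfg)
    _, s1, y1 = train_fold(tiny_bundle, fold, tiny_cfg)
    _, s2, y2 = train_fold(tiny_bundle, fold, tiny_cfg)
    np.testing.assert_array_equal(s1, s2)
    np.testing.assert_array_equal(y1, y2)


def test_no_leakage_test_labels_do_not_influence_training(tiny_bundle,
                                                          tiny_cfg):
    """Zeroing every held-out pair's label leaves training untouched."""
    fold = _first_fold(tiny_bundle, tiny_cfg)
    _, s_ref, _ = train_fold(tiny_bundle, fold, tiny_cfg)
    censored = copy.deepcopy(tiny_bundle)
    vals = censored.associations.values.copy()
    vals.reshape(-1)[fold.test_pairs] = 0
    censored.associations = AssociationMatrix(
        censored.associations.drug_ids, censored.associations.disease_ids,
        vals,
    )
    _, s_censored, _ = train_fold(censored, fold, tiny_cfg)
    np.testing.assert_array_equal(s_ref, s_censored)


def test_scoring_is_pure_at_fixed_parameters(tiny_bundle, tiny_cfg):
    cfg = tiny_cfg.replace(epochs=0)
    fold = _first_fold(tiny_bundle, cfg)
    _, s1, _ = train_fold(tiny_bundle, fold, cfg)
    _, s2, _ = train_fold(tiny_bundle, fold, cfg)
    np.testing.assert_array_equal(s1, s2)


def test_untrained_model_scores_near_chance(tiny_bundle, tiny_cfg):
    """With random parameters the scorer should sit near AUC 0.5."""
    cfg = tiny_cfg.replace(epochs=0)
    aucs = []
    for fold in make_folds(20, 15, cfg.n_folds, cfg.seed):
        _, s, y = train_fold(tiny_bundle, fold, cfg)
        aucs.append(compute_metrics(s, y)["auc"])
    assert abs(np.mean(aucs) - 0.5) < 0.15


def test_degenerate_fold_without_positives_raises(tiny_bundle, tiny_cfg):
    from amfgnn.training import FoldSplit

    vals = tiny_bundle.associations.values
    negatives = np.flatnonzero(vals.reshape(-1) == 0)[:10]
    fold = FoldSplit(0, negatives,
                     np.setdiff1d(np.arange(vals.size), negatives))
    with pytest.raises(ValueError, match="positives"):
        train_fold(tiny_bundle, fold, tiny_cfg)


def test_ablation_variants_share_interface(tiny_bundle, tiny_cfg):
    fold = _first_fold(tiny_bundle, tiny_cfg)
    for head, contrastive in (("mlp", False), ("dot", True)):
        cfg = tiny_cfg.replace(epochs=1, head_kind=head,
                               contrastive=contrastive)
        _, s, y = train_fold(tiny_bundle, fold, cfg)
        assert s.shape == y.shape
        assert ((0 < s) & (s < 1)).all()


def test_train_full_scores_every_pair(tiny_bundle, tiny_cfg):
    scores = train_full(tiny_bundle, tiny_cfg.replace(epochs=1))
    assert scores.shape == tiny_bundle.associations.values.shape
    assert ((0 < scores) & (scores < 1)).all()


def test_top_candidates_ordering_and_tie_break():
    mat = np.array([[0.9, 0.2], [0.9, 0.5], [0.3, 0.8]])
    ranked = top_candidates(mat, ["b", "a", "c"], disease_index=0, k=5)
    assert [r[0] for r in ranked] == ["a", "b", "c"]  # tie 0.9 broken by id
    assert ranked[0][1] == pytest.approx(0.9)
    assert len(top_candidates(mat, ["b", "a", "c"], 1, k=2)) == 2
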