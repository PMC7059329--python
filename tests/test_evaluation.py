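"""Metric formulas against independent oracles, CV fold machinery, and
cluster cross-validation properties."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcrpqsar import evaluation as ev


# ---------------------------------------------------------------------------
# confusion counts and the three confusion-matrix statistics
# ---------------------------------------------------------------------------

def test_confusion_counts_by_enumeration():
    y = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 1]
    p = [1, 0, 1, 0, 1, 0, 1, 1, 0, 0, 1, 1, 0, 1, 1, 0, 0, 0, 1, 1]
    tp = sum(1 for a, b in zip(y, p) if a == 1 and b == 1)
    tn = sum(1 for a, b in zip(y, p) if a == 0 and b == 0)
    fp = sum(1 for a, b in zip(y, p) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(y, p) if a == 1 and b == 0)
    assert ev.confusion(y, p) == (tp, tn, fp, fn)


def test_confusion_edge_cases():
    assert ev.confusion([1] * 10 + [0] * 10, [1] * 10 + [0] * 10) == (10, 10, 0, 0)
    assert ev.confusion([1] * 10 + [0] * 10, [1] * 20) == (10, 0, 10, 0)
    with pytest.raises(ValueError):
        ev.confusion([1, 0], [1])


def _oracle_ga(tp, tn, fp, fn):
    return Fraction(tp + tn, tp + tn + fp + fn)


def _oracle_ba(tp, tn, fp, fn):
    return Fraction(1, 2) * (Fraction(tp, tp + fn) + Fraction(tn, tn + fp))


def _oracle_mcc(tp, tn, fp, fn):
    denom = (tp + fn) * (tp + fp) * (fn + tn) * (tn + fp)
    if denom == 0:
        return 0.0
    return (tp * tn - fn * fp) / math.sqrt(denom)


def test_metrics_agree_with_exact_arithmetic_on_all_small_matrices():
    """GA, BA, MCC equal the exact rational / high-precision formulas on an
    exhaustive scan of small confusion matrices."""
    for tp, tn, fp, fn in product(range(7), repeat=4):
        if tp + tn + fp + fn == 0:
            continue
        assert ev.global_accuracy(tp, tn, fp, fn) == pytest.approx(
            float(_oracle_ga(tp, tn, fp, fn)), abs=1e-12)
        assert ev.mcc(tp, tn, fp, fn) == pytest.approx(
            _oracle_mcc(tp, tn, fp, fn), abs=1e-12)
        if tp + fn > 0 and tn + fp > 0:
            assert ev.balanced_accuracy(tp, tn, fp, fn) == pytest.approx(
                float(_oracle_ba(tp, tn, fp, fn)), abs=1e-12)
        else:
            with pytest.raises(ValueError):
                ev.balanced_accuracy(tp, tn, fp, fn)


def test_mcc_worked_values():
    assert ev.mcc(10, 10, 0, 0) == 1.0
    assert ev.mcc(10, 0, 10, 0) == 0.0  # zero-denominator convention
    assert ev.mcc(200, 320, 20, 19) == pytest.approx(0.8537308188609863, abs=1e-12)


def test_ga_ba_worked_values():
    assert ev.balanced_accuracy(50, 90, 10, 50) == pytest.approx(0.70)
    assert ev.global_accuracy(50, 90, 10, 50) == pytest.approx(0.70)


@given(tp=st.integers(0, 30), tn=st.integers(0, 30),
       fp=st.integers(0, 30), fn=st.integers(0, 30))
@settings(max_examples=200, derandomize=True)
def test_mcc_and_ba_invariant_under_class_flip(tp, tn, fp, fn):
    """Swapping the positive and negative classes (and predictions with
    them) leaves MCC and BA unchanged."""
    assert ev.mcc(tp, tn, fp, fn) == pytest.approx(ev.mcc(tn, tp, fn, fp), abs=1e-12)
    if tp + fn > 0 and tn + fp > 0:
        assert ev.balanced_accuracy(tp, tn, fp, fn) == pytest.approx(
            ev.balanced_accuracy(tn, tp, fn, fp), abs=1e-12)


# ---------------------------------------------------------------------------
# AUC against a pair-counting oracle
# ---------------------------------------------------------------------------

def _auc_pair_counting(y, p):
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    score = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                score += 1.0
            elif a == b:
                score += 0.5
    return score / (len(pos) * len(neg))


def test_auc_perfect_and_random():
    y = [0] * 50 + [1] * 50
    p = np.linspace(0, 1, 100)
    assert ev.auc(y, p) == 1.0
    rng = np.random.default_rng(0)
    y2 = rng.integers(0, 2, 4000)
    p2 = rng.random(4000)
    assert abs(ev.auc(y2, p2) - 0.5) < 0.03


def test_auc_with_ties_matches_pair_counting_oracle():
    y = [1, 1, 1, 1, 0, 0, 0, 0, 1, 0]
    p = [0.9, 0.8, 0.8, 0.5, 0.8, 0.5, 0.3, 0.1, 0.5, 0.9]
    assert ev.auc(y, p) == pytest.approx(_auc_pair_counting(y, p), abs=1e-12)


@given(st.lists(st.tuples(st.integers(0, 1),
                          st.sampled_from([0.1, 0.25, 0.5, 0.5, 0.75, 0.9])),
                min_size=4, max_size=40))
@settings(max_examples=100, derandomize=True)
def test_auc_equals_normalized_mannwhitney_u(pairs):
    y = [a for a, _ in pairs]
    p = [b for _, b in pairs]
    if len(set(y)) < 2:
        with pytest.raises(ValueError):
            ev.auc(y, p)
        return
    assert ev.auc(y, p) == pytest.approx(_auc_pair_counting(y, p), abs=1e-12)


# ---------------------------------------------------------------------------
# cross-entropy residuals and exceedance curves
# ---------------------------------------------------------------------------

def test_cross_entropy_closed_forms():
    assert ev.cross_entropy_residual(1, 1.0)[()] == pytest.approx(0.0, abs=1e-12)
    assert ev.cross_entropy_residual(1, 0.5)[()] == pytest.approx(math.log(2), abs=1e-12)
    with pytest.raises(ValueError):
        ev.cross_entropy_residual(1, 1.5)


def test_sharper_probabilities_give_smaller_residuals():
    """A model placing 0.9 on the true class beats one placing 0.6 even
    though both classify correctly."""
    assert (ev.cross_entropy_residual(1, 0.6)[()]
            > ev.cross_entropy_residual(1, 0.9)[()])


def test_residual_distribution_against_sorted_oracle(rng):
    r = rng.exponential(0.5, size=300)
    grid = np.linspace(0, 3, 31)
    curve = ev.residual_distribution(r, grid)
    ecdf = np.array([np.mean(np.sort(r) <= t) for t in grid])
    assert np.allclose(curve["fraction_above"], 1 - ecdf)
    assert (np.diff(curve["fraction_above"]) <= 1e-12).all()


def test_residual_distribution_small_cases():
    curve = ev.residual_distribution([0.2, 0.8], [0.5])
    assert curve["fraction_above"].iloc[0] == 0.5
    curve0 = ev.residual_distribution([0.0, 0.0], [0.1, 1.0])
    assert (curve0["fraction_above"] == 0).all()
    with pytest.raises(ValueError):
        ev.residual_distribution([], [0.5])


# ---------------------------------------------------------------------------
# fold assignment
# ---------------------------------------------------------------------------

def test_random_kfold_stratified_sizes_and_determinism():
    y = [1] * 50 + [0] * 50
    a1 = ev.random_kfold(y, k=5, seed=3)[0]
    a2 = ev.random_kfold(y, k=5, seed=3)[0]
    assert (a1.fold == a2.fold).all()
    y_arr = np.asarray(y)
    for j in range(1, 6):
        idx = a1.fold_indices(j)
        assert len(idx) == 20
        assert y_arr[idx].sum() == 10
    # folds partition the dataset
    assert sorted(np.concatenate([a1.fold_indices(j) for j in range(1, 6)])) \
        == list(range(100))
    with pytest.raises(ValueError):
        ev.random_kfold(y, k=1)


# ---------------------------------------------------------------------------
# Tanimoto and cluster folds
# ---------------------------------------------------------------------------

def test_tanimoto_direct_counts():
    assert ev.tanimoto([1, 1, 1, 0], [1, 1, 1, 0]) == 1.0
    assert ev.tanimoto([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0
    # bit sets {1,2,3} vs {2,3,4} -> 2/4
    assert ev.tanimoto([0, 1, 1, 1, 0], [0, 0, 1, 1, 1]) == 0.5
    assert ev.tanimoto([0, 0], [0, 0]) == 1.0  # empty-vs-empty convention
    with pytest.raises(ValueError):
        ev.tanimoto([1, 0], [1, 0, 1])


def test_cluster_folds_keep_identical_compounds_together():
    fp = np.vstack([np.tile([1, 0, 1, 0, 1, 1, 0, 0], (2, 1)),
                    np.eye(8, dtype=int)])
    a = ev.cluster_folds(fp, k=5, seed=0)
    assert a.fold[0] == a.fold[1]
    assert a.cluster_id[0] == a.cluster_id[1]


def test_cluster_folds_singletons_balance():
    fp = np.eye(20, dtype=int)  # all pairwise disjoint: distance 1
    a = ev.cluster_folds(fp, k=5, seed=1)
    assert len(np.unique(a.cluster_id)) == 20
    assert max(a.fold_sizes) - min(a.fold_sizes) <= 1


def test_cluster_folds_complete_linkage_bound(scaffold_library):
    """Every cluster's maximum intra-cluster Tanimoto distance stays at or
    below the dendrogram cut, verified by exhaustive pair scan."""
    from bcrpqsar.featurization import binary_fingerprints
    library, _ = scaffold_library
    fp = binary_fingerprints(library["smiles"])
    a = ev.cluster_folds(fp, k=5, distance_threshold=0.7, seed=0)
    dist = ev.tanimoto_distance_matrix(fp)
    for c in np.unique(a.cluster_id):
        members = np.flatnonzero(a.cluster_id == c)
        for i in members:
            for j in members:
                assert dist[i, j] <= 0.7 + 1e-12
        # whole cluster shares one fold
        assert len(set(a.fold[members])) == 1


def test_cluster_folds_error_when_too_few_clusters():
    fp = np.tile([1, 0, 1, 0], (6, 1))  # all identical: one cluster
    with pytest.raises(ValueError):
        ev.cluster_folds(fp, k=5)
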