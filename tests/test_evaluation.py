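"""ROC/AUC, cutoff optimization, classifier metrics and descriptive stats.

Oracles: the AUC is checked against exhaustive pairwise Mann-Whitney
counting; cutoff selectors are checked against the full set of achievable
classifications (every "predict the top k scores Amplified" rule).
"""

import numpy as np
import pytest

from primeramp.dataset import AMPLIFIED, UNAMPLIFIED, LabeledPTP, synthesize_dataset
from primeramp.evaluation import (
    classify,
    confusion_metrics,
    cv_cutoff,
    group_rank_test,
    high_specificity_cutoff,
    rate_by_mismatch_table,
    roc_auc,
    youden_cutoff,
)
from primeramp.features import FeatureVector
from primeramp.models import TMM_TERMS

A, U = AMPLIFIED, UNAMPLIFIED


def _pairwise_auc(scores, labels):
    """Exhaustive Mann-Whitney probability, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == A]
    neg = [s for s, l in zip(scores, labels) if l == U]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


def _all_achievable(scores, labels):
    """(sens, spec) of every threshold rule 'top k scores are Amplified'."""
    y = np.array([1.0 if l == A else 0.0 for l in labels])
    s = np.asarray(scores, dtype=float)
    out = []
    for cut in np.concatenate([np.unique(s), [np.inf, -np.inf]]):
        pred = s > cut
        out.append((pred[y == 1].mean(), (~pred)[y == 0].mean()))
    return out


def test_auc_trivial_cases():
    assert roc_auc([1, 2, 3, 10, 11, 12], [U, U, U, A, A, A]) == 1.0
    assert roc_auc([5, 5, 5, 5], [A, U, A, U]) == 0.5
    with pytest.raises(ValueError):
        roc_auc([1, 2], [A, A])


def test_auc_matches_pairwise_enumeration():
    rng = np.random.default_rng(71)
    for _ in range(30):
        n = int(rng.integers(6, 200))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = [A if rng.random() < 0.4 else U for _ in range(n)]
        if len(set(labels)) < 2:
            continue
        assert roc_auc(scores, labels, "greater") == pytest.approx(
            _pairwise_auc(scores, labels), abs=1e-12
        )
        # 'less' direction: low scores indicate amplification
        assert roc_auc(-scores, labels, "less") == pytest.approx(
            _pairwise_auc(scores, labels), abs=1e-12
        )


def test_youden_cutoff_matches_exhaustive_scan():
    rng = np.random.default_rng(73)
    for _ in range(25):
        n = int(rng.integers(8, 120))
        scores = np.round(rng.normal(size=n), 1)
        labels = [A if rng.random() < 0.45 else U for _ in range(n)]
        if len(set(labels)) < 2:
            continue
        cut = youden_cutoff(scores, labels, "greater")
        preds = classify(scores, cut, "greater")
        m = confusion_metrics(preds, labels)
        best_j = max(se + sp - 1 for se, sp in _all_achievable(scores, labels))
        assert m.youden == pytest.approx(best_j, abs=1e-12)


def test_youden_perfect_separation_achieves_one():
    cut = youden_cutoff([0.1, 0.2, 0.8, 0.9], [U, U, A, A], "greater")
    m = confusion_metrics(classify([0.1, 0.2, 0.8, 0.9], cut, "greater"),
                          [U, U, A, A])
    assert m.youden == 1.0


def test_high_specificity_cutoff_matches_exhaustive_scan():
    rng = np.random.default_rng(79)
    for _ in range(25):
        n = int(rng.integers(20, 150))
        scores = np.round(rng.normal(size=n), 1)
        labels = [A if rng.random() < 0.45 else U for _ in range(n)]
        if len(set(labels)) < 2:
            continue
        cut = high_specificity_cutoff(scores, labels, "greater", min_specificity=0.9)
        m = confusion_metrics(classify(scores, cut, "greater"), labels)
        assert m.specificity >= 0.9
        best_sens = max(se for se, sp in _all_achievable(scores, labels) if sp >= 0.9)
        assert m.sensitivity == pytest.approx(best_sens, abs=1e-12)


def test_high_specificity_top_score_unamplified():
    # specificity floor is honored even if it costs all sensitivity
    scores = [0.1, 0.5, 0.99]
    labels = [A, A, U]
    cut = high_specificity_cutoff(scores, labels, "greater", min_specificity=1.0)
    m = confusion_metrics(classify(scores, cut, "greater"), labels)
    assert m.specificity == 1.0
    assert m.sensitivity == 0.0


def test_high_specificity_degenerate_floor_maximizes_sensitivity():
    scores = [0.2, 0.4, 0.6, 0.8]
    labels = [U, A, U, A]
    cut = high_specificity_cutoff(scores, labels, "greater", min_specificity=0.0)
    m = confusion_metrics(classify(scores, cut, "greater"), labels)
    assert m.sensitivity == 1.0


def test_direction_consistency():
    """Negating scores and flipping the direction leaves everything unchanged."""
    rng = np.random.default_rng(83)
    scores = rng.normal(size=60)
    labels = [A if rng.random() < 0.5 else U for _ in range(60)]
    auc_g = roc_auc(scores, labels, "greater")
    auc_l = roc_auc(-scores, labels, "less")
    assert auc_g == pytest.approx(auc_l, abs=1e-12)
    cut_g = youden_cutoff(scores, labels, "greater")
    cut_l = youden_cutoff(-scores, labels, "less")
    mg = confusion_metrics(classify(scores, cut_g, "greater"), labels)
    ml = confusion_metrics(classify(-scores, cut_l, "less"), labels)
    assert mg == ml


def test_confusion_metrics_all_correct():
    m = confusion_metrics([A, U, A], [A, U, A])
    assert (m.sensitivity, m.specificity, m.f1) == (1.0, 1.0, 1.0)
    assert m.youden == pytest.approx(1.0)


def test_confusion_metrics_known_table():
    preds = [A] * 76 + [U] * 24 + [U] * 99 + [A] * 1
    labels = [A] * 100 + [U] * 100
    m = confusion_metrics(preds, labels)
    assert m.sensitivity == pytest.approx(0.76)
    assert m.specificity == pytest.approx(0.99)
    assert m.youden == pytest.approx(0.75)
    assert m.f1 == pytest.approx(2 * 76 / (2 * 76 + 1 + 24))


def test_confusion_metrics_random_vs_hand_tally():
    rng = np.random.default_rng(89)
    preds = [A if rng.random() < 0.5 else U for _ in range(40)]
    labels = [A if rng.random() < 0.5 else U for _ in range(40)]
    tp = sum(p == A and l == A for p, l in zip(preds, labels))
    fn = sum(p == U and l == A for p, l in zip(preds, labels))
    tn = sum(p == U and l == U for p, l in zip(preds, labels))
    fp = sum(p == A and l == U for p, l in zip(preds, labels))
    m = confusion_metrics(preds, labels)
    assert m.sensitivity == pytest.approx(tp / (tp + fn))
    assert m.specificity == pytest.approx(tn / (tn + fp))


def test_confusion_metrics_undefined_is_none_and_mismatch_rejected():
    m = confusion_metrics([U, U], [U, U])
    assert m.sensitivity is None and m.f1 is None and m.youden is None
    with pytest.raises(ValueError):
        confusion_metrics([A], [A, U])


def test_cv_cutoff_reproducible_under_seed():
    data = synthesize_dataset(400, seed=97)
    a = cv_cutoff(TMM_TERMS, data, runs=3, folds=5, seed=12)
    b = cv_cutoff(TMM_TERMS, data, runs=3, folds=5, seed=12)
    assert (a.cutoff_s, a.cutoff_y) == (b.cutoff_s, b.cutoff_y)
    assert a.direction == "greater"


def test_cv_cutoff_leave_one_out_executes():
    # moderate-probability regime so the tiny training folds stay non-separable
    data = synthesize_dataset(40, delta_g_range=(-4.0, -1.0), seed=101)
    cuts = cv_cutoff(TMM_TERMS, data, runs=1, folds=len(data), seed=3)
    assert 0.0 < cuts.cutoff_y < 1.0


def test_cv_youden_cutoff_near_population_optimum():
    """With the generative law known, the population-optimal Youden threshold
    is computable on a dense grid; the CV estimate must land nearby."""
    from primeramp.dataset import DEFAULT_IX_DISTRIBUTION, PUBLISHED_TMM_COEFFICIENTS

    b0, b1, b2, b3 = PUBLISHED_TMM_COEFFICIENTS
    dg = np.linspace(-20.0, -1.0, 2000)
    w_ix = np.asarray(DEFAULT_IX_DISTRIBUTION)
    probs, weights = [], []
    for ix in range(7):
        p = 1 / (1 + np.exp(-(b0 + b1 * dg + b2 * ix + b3 * dg * ix)))
        probs.append(p)
        weights.append(np.full_like(p, w_ix[ix] / len(dg)))
    p = np.concatenate(probs)
    w = np.concatenate(weights)
    grid = np.linspace(0.01, 0.99, 197)
    j = [
        np.sum(w * p * (p > c)) / np.sum(w * p)
        + np.sum(w * (1 - p) * (p <= c)) / np.sum(w * (1 - p))
        - 1.0
        for c in grid
    ]
    population_cutoff = float(grid[int(np.argmax(j))])
    data = synthesize_dataset(4_000, seed=103)
    cuts = cv_cutoff(TMM_TERMS, data, runs=3, folds=5, seed=29)
    assert cuts.cutoff_y == pytest.approx(population_cutoff, abs=0.1)


def test_rate_by_mismatch_table_hand_tally():
    def mk(i, n_mm, label, set_name):
        z = [False] * 6
        if n_mm:
            z[5] = True
        return LabeledPTP(
            primer_id=f"p{i}", template_id=f"t{i}", label=label,
            features=FeatureVector(
                primer_id=f"p{i}", template_id=f"t{i}", delta_g=-4.0 - i,
                z=tuple(z), x_n=int(n_mm > 0), i_x=6 if n_mm else 0,
                n_mismatches_total=n_mm, primer_set=set_name,
            ),
        )

    pairs = [mk(0, 0, A, "Set 1"), mk(1, 0, A, "Set 1"),
             mk(2, 2, A, "Set 2"), mk(3, 2, U, "Set 2")]
    table = rate_by_mismatch_table(pairs)
    overall = table[table.primer_set == "Overall"].set_index("n_mismatches")
    assert overall.loc[0, "amplification_rate"] == 1.0
    assert overall.loc[2, "amplification_rate"] == 0.5
    set2 = table[(table.primer_set == "Set 2") & (table.n_mismatches == 2)]
    assert float(set2["amplification_rate"].iloc[0]) == 0.5
    assert int(overall.loc[0, "n_pairs"]) == 2


def test_rank_test_exact_disjoint_supports():
    # all of one group below all of the other, n = 5 vs 5: p = 2 * 1/252
    p = group_rank_test([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
    assert p == pytest.approx(2 / 252, rel=1e-9)


def test_rank_test_identical_groups_and_symmetry():
    rng = np.random.default_rng(107)
    a = rng.normal(size=30)
    assert group_rank_test(a, a) == pytest.approx(1.0, abs=0.02)
    b = rng.normal(size=25)
    assert group_rank_test(a, b) == pytest.approx(group_rank_test(b, a), rel=1e-12)
    with pytest.raises(ValueError):
        group_rank_test([], [1.0])
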