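"""Model and classifier evaluation.

Scores are turned into classifiers by thresholding: a model's ``direction``
says which side of the cutoff is called Amplified ("greater" for
probability-type scores, "less" for free-energy scores, where more negative
dG means more stable binding).  Two operating points are selected per
model: the cutoff maximizing Youden's index J = sensitivity + specificity
- 1, and the most sensitive cutoff whose empiric specificity still reaches
a floor (0.99 by default).  Candidate cutoffs are midpoints between
adjacent distinct scores plus sentinels half a gap beyond the extremes, so
the optimum over all distinct classifications is found exactly.

The AUC is the Mann-Whitney probability that a random Amplified score
outranks a random Unamplified one (ties count half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .dataset import AMPLIFIED, UNAMPLIFIED, LabeledPTP

__all__ = [
    "ClassifierCutoffs",
    "MetricReport",
    "roc_auc",
    "youden_cutoff",
    "high_specificity_cutoff",
    "classify",
    "confusion_metrics",
    "cv_cutoff",
    "rate_by_mismatch_table",
    "group_rank_test",
]


def _as_binary(labels: Sequence) -> np.ndarray:
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab in (AMPLIFIED, 1, True):
            out[i] = 1.0
        elif lab in (UNAMPLIFIED, 0, False):
            out[i] = 0.0
        else:
            raise ValueError(f"unrecognized label {lab!r}")
    return out


def _oriented(scores: Sequence[float], direction: str) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    if direction == "greater":
        return s
    if direction == "less":
        return -s
    raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")


@dataclass(frozen=True)
class MetricReport:
    """Classifier metrics; undefined ratios (zero denominators) are None."""

    sensitivity: float | None
    specificity: float | None
    f1: float | None
    youden: float | None
    auc: float | None = None


@dataclass(frozen=True)
class ClassifierCutoffs:
    """Selected operating points for one model, with the selection trace."""

    model_name: str
    cutoff_s: float
    cutoff_y: float
    direction: str
    min_specificity: float = 0.99
    trace: tuple = ()


def roc_auc(scores: Sequence[float], labels: Sequence, direction: str = "greater") -> float:
    """Area under the ROC curve (Mann-Whitney probability, ties half)."""
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return float(roc_auc_score(y, _oriented(scores, direction)))


def _candidate_cutoffs(s: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct oriented scores plus sentinels."""
    u = np.unique(s)
    gap = (u[-1] - u[0]) / max(len(u) - 1, 1) or 1.0
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] - gap / 2.0], mids, [u[-1] + gap / 2.0]))


def _sens_spec(s: np.ndarray, y: np.ndarray, cut: float) -> tuple[float, float]:
    pred = s > cut
    pos, neg = y == 1, y == 0
    return float(pred[pos].mean()), float((~pred[neg]).mean())


def youden_cutoff(scores: Sequence[float], labels: Sequence, direction: str = "greater") -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties break toward higher specificity (fewer false positives), the
    conservative choice for multiplex primer design.
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("cutoff selection requires both classes")
    s = _oriented(scores, direction)
    best = None
    for cut in _candidate_cutoffs(s):
        sens, spec = _sens_spec(s, y, cut)
        key = (sens + spec - 1.0, spec)
        if best is None or key > best[0]:
            best = (key, cut)
    cut = best[1]
    return float(cut if direction == "greater" else -cut)


def high_specificity_cutoff(
    scores: Sequence[float],
    labels: Sequence,
    direction: str = "greater",
    min_specificity: float = 0.99,
) -> float:
    """Most sensitive cutoff with empiric specificity >= ``min_specificity``.

    Always attainable: the all-Unamplified cutoff has specificity 1.
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("cutoff selection requires both classes")
    s = _oriented(scores, direction)
    best = None
    for cut in _candidate_cutoffs(s):
        sens, spec = _sens_spec(s, y, cut)
        if spec < min_specificity:
            continue
        key = (sens, spec)
        if best is None or key > best[0]:
            best = (key, cut)
    cut = best[1]
    return float(cut if direction == "greater" else -cut)


def classify(scores: Sequence[float], cutoff: float, direction: str = "greater") -> list[str]:
    """Threshold scores into labels (strict inequality on the stated side)."""
    s = np.asarray(scores, dtype=float)
    amp = s > cutoff if direction == "greater" else s < cutoff
    return [AMPLIFIED if a else UNAMPLIFIED for a in amp]


def confusion_metrics(predictions: Sequence, labels: Sequence) -> MetricReport:
    """Sensitivity, specificity, F1 and Youden's index from aligned calls."""
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must align")
    p = _as_binary(predictions)
    y = _as_binary(labels)
    tp = float(np.sum((p == 1) & (y == 1)))
    tn = float(np.sum((p == 0) & (y == 0)))
    fp = float(np.sum((p == 1) & (y == 0)))
    fn = float(np.sum((p == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
    youden = sens + spec - 1.0 if sens is not None and spec is not None else None
    return MetricReport(sensitivity=sens, specificity=spec, f1=f1, youden=youden)


def cv_cutoff(
    model_spec: Sequence[str],
    validation_data: Sequence[LabeledPTP],
    runs: int = 10,
    folds: int = 5,
    seed: int = 0,
    min_specificity: float = 0.99,
    model_name: str = "TMM",
) -> ClassifierCutoffs:
    """Cross-validated cutoff selection for a probability model.

    Per run, the validation data are split into ``folds`` folds; the model
    (term list ``model_spec``) is fitted on the held-in folds and scores
    the held-out fold.  Pooled held-out scores of each run yield one
    Youden and one high-specificity cutoff; the final cutoffs are the
    across-run means.  A fold whose training part is single-class triggers
    a refold under a fresh seed (logged in the trace).
    """
    from .models import fit_logistic, FitDiagnosticError  # local import: avoid cycle

    y_all = _as_binary([p.label for p in validation_data])
    if len(np.unique(y_all)) < 2:
        raise ValueError("validation data must contain both classes")
    n = len(validation_data)
    rng = np.random.default_rng(seed)
    per_run: list[tuple[float, float]] = []
    trace: list[dict] = []
    for run in range(runs):
        attempts = 0
        while True:
            run_seed = int(rng.integers(0, 2**31 - 1))
            kf = KFold(n_splits=folds, shuffle=True, random_state=run_seed)
            pooled = np.empty(n)
            try:
                for train_idx, test_idx in kf.split(np.arange(n)):
                    train = [validation_data[i] for i in train_idx]
                    model = fit_logistic(train, model_spec)
                    for i in test_idx:
                        pooled[i] = model.predict(_values_of(validation_data[i]))
                break
            except FitDiagnosticError:
                attempts += 1
                trace.append({"run": run, "event": "refold", "attempt": attempts})
                if attempts > 20:
                    raise
        cs = high_specificity_cutoff(pooled, y_all, "greater", min_specificity)
        cy = youden_cutoff(pooled, y_all, "greater")
        per_run.append((cs, cy))
        trace.append({"run": run, "cutoff_s": cs, "cutoff_y": cy, "fold_seed": run_seed})
    cutoff_s = float(np.mean([c[0] for c in per_run]))
    cutoff_y = float(np.mean([c[1] for c in per_run]))
    return ClassifierCutoffs(
        model_name=model_name,
        cutoff_s=cutoff_s,
        cutoff_y=cutoff_y,
        direction="greater",
        min_specificity=min_specificity,
        trace=tuple(trace),
    )


def _values_of(pair: LabeledPTP) -> dict[str, float]:
    from .models import _pair_values

    return _pair_values(pair)


def rate_by_mismatch_table(pairs: Sequence[LabeledPTP]) -> pd.DataFrame:
    """Amplification rate and i_X / dG inter-quartile ranges per mismatch count.

    One block of rows per primer set plus an Overall block, one row per
    observed total mismatch count.
    """
    rows = []
    df = pd.DataFrame(
        {
            "n_mismatches": [p.features.n_mismatches_total for p in pairs],
            "i_x": [p.features.i_x for p in pairs],
            "delta_g": [p.features.delta_g for p in pairs],
            "amplified": [1.0 if p.label == AMPLIFIED else 0.0 for p in pairs],
            "primer_set": [p.features.primer_set or "unlabeled" for p in pairs],
        }
    )
    sets = ["Overall"] + sorted(df["primer_set"].unique())
    for set_name in sets:
        sub = df if set_name == "Overall" else df[df["primer_set"] == set_name]
        for n_mm, grp in sub.groupby("n_mismatches"):
            rows.append(
                {
                    "primer_set": set_name,
                    "n_mismatches": int(n_mm),
                    "n_pairs": len(grp),
                    "amplification_rate": float(grp["amplified"].mean()),
                    "i_x_q1": float(grp["i_x"].quantile(0.25)),
                    "i_x_q3": float(grp["i_x"].quantile(0.75)),
                    "delta_g_q1": float(grp["delta_g"].quantile(0.25)),
                    "delta_g_q3": float(grp["delta_g"].quantile(0.75)),
                }
            )
    return pd.DataFrame(rows)


def group_rank_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration for small tie-free samples (both n <= 50), normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 50 and len(b) <= 50 and not ties) else "asymptotic"
    return float(
        _stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
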