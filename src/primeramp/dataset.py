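"""Labeled data-set construction.

Amplification labels are consensus calls: each of three replicate gel lanes
is called Amplified/Unamplified per reviewer; a reviewer's call for a pair
is Amplified iff at least two of the three replicates amplified; the pair's
label is Amplified iff a strict majority of reviewers called it Amplified
(ties fall to Unamplified).

Pairs with more than 12 mismatches are excluded before modeling — the
annealing site is too uncertain at that divergence.  Retained pairs are
split 25% validation / 50% training / 25% testing.

The synthetic generator draws labeled pairs whose Bernoulli amplification
labels follow the logistic law

    logit p = b0 + b1*dG + b2*i_X + b3*dG*i_X

at configurable coefficients, for offline model validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FeatureVector

__all__ = [
    "AMPLIFIED",
    "UNAMPLIFIED",
    "MeasurementRecord",
    "LabeledPTP",
    "DatasetSplit",
    "reviewer_label",
    "consensus_label",
    "filter_by_mismatches",
    "split_dataset",
    "read_feature_matrix",
    "read_measurements",
    "synthesize_dataset",
    "write_split_manifest",
    "read_split_manifest",
]

AMPLIFIED = "Amplified"
UNAMPLIFIED = "Unamplified"
_CALLS = (AMPLIFIED, UNAMPLIFIED)


def _check_call(call: str) -> str:
    if call not in _CALLS:
        raise ValueError(f"band call must be one of {_CALLS}, got {call!r}")
    return call


@dataclass(frozen=True)
class MeasurementRecord:
    """One reviewer's call for one replicate gel lane of one pair."""

    primer_id: str
    template_id: str
    replicate: int
    reviewer: int
    band_call: str

    def __post_init__(self) -> None:
        if not 1 <= self.replicate <= 3:
            raise ValueError("replicate must be in 1..3")
        if not 1 <= self.reviewer <= 5:
            raise ValueError("reviewer must be in 1..5")
        _check_call(self.band_call)


@dataclass(frozen=True)
class LabeledPTP:
    """A primer-template pair with consensus label and predictors."""

    primer_id: str
    template_id: str
    label: str
    features: FeatureVector
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_call(self.label)


def reviewer_label(calls: Sequence[str]) -> str:
    """Per-reviewer call from triplicate lanes: Amplified iff >= 2 of 3."""
    if len(calls) != 3:
        raise ValueError(f"expected exactly 3 replicate calls, got {len(calls)}")
    n_amp = sum(1 for c in calls if _check_call(c) == AMPLIFIED)
    return AMPLIFIED if n_amp >= 2 else UNAMPLIFIED


def consensus_label(reviewer_labels: Sequence[str]) -> str:
    """Pair label: Amplified iff a strict majority of reviewers say so."""
    if not reviewer_labels:
        raise ValueError("at least one reviewer label is required")
    n_amp = sum(1 for c in reviewer_labels if _check_call(c) == AMPLIFIED)
    return AMPLIFIED if n_amp > len(reviewer_labels) - n_amp else UNAMPLIFIED


def label_from_measurements(records: Iterable[MeasurementRecord]) -> str:
    """Consensus label of one pair from its raw per-lane reviewer calls."""
    by_reviewer: dict[int, dict[int, str]] = {}
    for rec in records:
        by_reviewer.setdefault(rec.reviewer, {})[rec.replicate] = rec.band_call
    per_reviewer = [
        reviewer_label([calls[r] for r in sorted(calls)])
        for calls in by_reviewer.values()
    ]
    return consensus_label(per_reviewer)


def read_measurements(path) -> dict[tuple[str, str], str]:
    """Consensus labels from a raw measurement CSV.

    Columns: primer_id, template_id, replicate, reviewer, band_call.
    Returns ``{(primer_id, template_id): label}``.
    """
    df = pd.read_csv(path)
    required = ["primer_id", "template_id", "replicate", "reviewer", "band_call"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"measurement table missing columns: {missing}")
    records = [
        MeasurementRecord(
            primer_id=str(r.primer_id), template_id=str(r.template_id),
            replicate=int(r.replicate), reviewer=int(r.reviewer),
            band_call=str(r.band_call),
        )
        for r in df.itertuples()
    ]
    if len({(r.primer_id, r.template_id, r.replicate, r.reviewer) for r in records}) != len(records):
        raise ValueError("duplicate (pair, replicate, reviewer) measurements")
    labels: dict[tuple[str, str], str] = {}
    by_pair: dict[tuple[str, str], list[MeasurementRecord]] = {}
    for rec in records:
        by_pair.setdefault((rec.primer_id, rec.template_id), []).append(rec)
    for key, recs in by_pair.items():
        labels[key] = label_from_measurements(recs)
    return labels


def filter_by_mismatches(
    pairs: Sequence[LabeledPTP], max_mismatches: int = 12
) -> tuple[list[LabeledPTP], dict[str, int]]:
    """Drop pairs whose best binding mode has too many mismatches.

    Returns the retained pairs and a ``{"retained": .., "removed": ..}``
    report.
    """
    kept = [p for p in pairs if p.features.n_mismatches_total <= max_mismatches]
    return kept, {"retained": len(kept), "removed": len(pairs) - len(kept)}


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint validation/training/testing index sets covering all pairs."""

    validation: tuple[int, ...]
    training: tuple[int, ...]
    testing: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        all_idx = set(self.validation) | set(self.training) | set(self.testing)
        n = len(self.validation) + len(self.training) + len(self.testing)
        if len(all_idx) != n:
            raise ValueError("split index sets must be disjoint")


def split_dataset(
    pairs: Sequence,
    fractions: tuple[float, float, float] = (0.25, 0.50, 0.25),
    seed: int = 0,
) -> DatasetSplit:
    """Random (validation, training, testing) split.

    Validation and testing sizes are floored at their fractions; the
    remainder goes to training (at N = 908 and the default fractions this
    yields 227/454/227).
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(pairs)
    if n < 4:
        raise ValueError("need at least 4 pairs to split")
    n_val = int(fractions[0] * n)
    n_test = int(fractions[2] * n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return DatasetSplit(
        validation=tuple(sorted(int(i) for i in perm[:n_val])),
        testing=tuple(sorted(int(i) for i in perm[n_val:n_val + n_test])),
        training=tuple(sorted(int(i) for i in perm[n_val + n_test:])),
        seed=seed,
    )


def write_split_manifest(split: DatasetSplit, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "seed": split.seed,
                "validation": list(split.validation),
                "training": list(split.training),
                "testing": list(split.testing),
            },
            fh,
            indent=1,
        )


def read_split_manifest(path) -> DatasetSplit:
    with open(path) as fh:
        d = json.load(fh)
    return DatasetSplit(
        validation=tuple(d["validation"]),
        training=tuple(d["training"]),
        testing=tuple(d["testing"]),
        seed=d["seed"],
    )


_REQUIRED_COLUMNS = [
    "primer_id", "template_id", "delta_g",
    "z1", "z2", "z3", "z4", "z5", "z6", "n_mismatches_total",
]


class SchemaError(ValueError):
    """The feature matrix is missing required columns."""


def read_feature_matrix(
    path, column_map: Mapping[str, str] | None = None
) -> list[LabeledPTP]:
    """Read a feature CSV (canonical schema, or any dialect via column_map).

    ``column_map`` maps source column names to canonical names, bridging
    externally deposited matrices whose headers differ.  ``x_n``/``i_x``
    are recomputed from ``z``; unknown columns are preserved in ``extras``.
    The label column is optional (prediction inputs are unlabeled): rows
    without a label default to Unamplified and carry
    ``extras["label_missing"] = True``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature matrix missing required columns: {missing}")
    known = set(_REQUIRED_COLUMNS) | {"primer_set", "x_n", "i_x", "label",
                                      "gc_ratio", "gc_clamp"}
    passthrough = [c for c in df.columns if c not in known]
    pairs: list[LabeledPTP] = []
    for _, row in df.iterrows():
        z = tuple(bool(int(row[f"z{j}"])) for j in range(1, 7))
        fv = FeatureVector(
            primer_id=str(row["primer_id"]),
            template_id=str(row["template_id"]),
            delta_g=float(row["delta_g"]),
            z=z,
            x_n=sum(z),
            i_x=max((j for j, zj in enumerate(z, 1) if zj), default=0),
            n_mismatches_total=int(row["n_mismatches_total"]),
            primer_set=str(row["primer_set"]) if "primer_set" in df.columns and pd.notna(row.get("primer_set")) else "",
        )
        extras = {c: row[c] for c in passthrough}
        raw_label = row.get("label") if "label" in df.columns else None
        if raw_label is None or pd.isna(raw_label) or str(raw_label) == "":
            label = UNAMPLIFIED
            extras["label_missing"] = True
        else:
            label = _check_call(str(raw_label))
        pairs.append(
            LabeledPTP(
                primer_id=fv.primer_id,
                template_id=fv.template_id,
                label=label,
                features=fv,
                extras=extras,
            )
        )
    return pairs


#: Default distribution of i_X (index 0..6).  Zero-mismatch pairs are the
#: single most common state; among mismatched pairs the mass increases
#: toward the 3' terminus, as observed in real primer-coverage data.
DEFAULT_IX_DISTRIBUTION = (0.30, 0.06, 0.08, 0.10, 0.12, 0.16, 0.18)

#: Published coefficients of the thermodynamic mismatch model
#: (intercept, dG, i_X, dG*i_X), on the log-odds scale.
PUBLISHED_TMM_COEFFICIENTS = (-5.6177, -1.5448, 0.3279, 0.1837)


def synthesize_dataset(
    n_pairs: int,
    coefficients: Sequence[float] = PUBLISHED_TMM_COEFFICIENTS,
    delta_g_range: tuple[float, float] = (-20.0, -1.0),
    i_x_distribution: Sequence[float] = DEFAULT_IX_DISTRIBUTION,
    seed: int = 0,
    extra_hexamer_rate: float = 0.3,
    outside_hexamer_mean: float = 2.0,
) -> list[LabeledPTP]:
    """Simulate labeled pairs under the logistic amplification law.

    Per pair: dG ~ Uniform(delta_g_range); i_X ~ Categorical over 0..6; a
    mismatch is planted at hexamer position i_X with independent extra
    mismatches at positions j < i_X (rate ``extra_hexamer_rate``);
    out-of-hexamer mismatches ~ Poisson(``outside_hexamer_mean``); the label
    is Bernoulli with logit p = b0 + b1*dG + b2*i_X + b3*dG*i_X.
    Fully reproducible under ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    lo, hi = delta_g_range
    if lo > hi or lo < -25.0 or hi > 0.0:
        raise ValueError(
            f"delta_g_range must be non-inverted and within [-25, 0], got {delta_g_range}"
        )
    b0, b1, b2, b3 = coefficients
    p_ix = np.asarray(i_x_distribution, dtype=float)
    if p_ix.shape != (7,) or (p_ix < 0).any() or not math.isclose(p_ix.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("i_x_distribution must be 7 non-negative weights summing to 1")
    rng = np.random.default_rng(seed)
    delta_g = rng.uniform(lo, hi, size=n_pairs) if lo < hi else np.full(n_pairs, lo)
    i_x = rng.choice(7, size=n_pairs, p=p_ix)
    logit = b0 + b1 * delta_g + b2 * i_x + b3 * delta_g * i_x
    prob = 1.0 / (1.0 + np.exp(-logit))
    labels = rng.random(n_pairs) < prob
    extra = rng.random((n_pairs, 6)) < extra_hexamer_rate
    outside = rng.poisson(outside_hexamer_mean, size=n_pairs)
    pairs: list[LabeledPTP] = []
    for k in range(n_pairs):
        ix = int(i_x[k])
        z = [False] * 6
        if ix > 0:
            z[ix - 1] = True
            for j in range(ix - 1):  # extras strictly below i_X keep i_X the max
                if extra[k, j]:
                    z[j] = True
        x_n = sum(z)
        fv = FeatureVector(
            primer_id=f"sim_primer_{k}",
            template_id=f"sim_template_{k}",
            delta_g=float(delta_g[k]),
            z=tuple(z),
            x_n=x_n,
            i_x=ix,
            n_mismatches_total=x_n + int(outside[k]),
            primer_set="synthetic",
        )
        pairs.append(
            LabeledPTP(
                primer_id=fv.primer_id,
                template_id=fv.template_id,
                label=AMPLIFIED if labels[k] else UNAMPLIFIED,
                features=fv,
                extras={"true_probability": float(prob[k])},
            )
        )
    return pairs
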