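"""Logistic amplification models.

The central model class is a plain maximum-likelihood logistic regression
over the pair-level predictors (dG, the hexamer mismatch encodings, and
product interaction terms).  Perfectly collinear columns — e.g. X_N when
all of z1..z6 are present, since X_N = sum_j z_j — are flagged *aliased*
and excluded from estimation rather than fitted, mirroring how singular
design columns are reported by standard GLM software.

Model selection is greedy backward stepwise on the AIC (2k - 2 ln L, with k
the number of estimated coefficients), respecting marginality: a main
effect is not dropped while an interaction containing it remains.

The published thermodynamic mismatch model (TMM) ships as package data:
logit p = b0 + b1*dG + b2*i_X + b3*dG*i_X with b = (-5.6177, -1.5448,
0.3279, 0.1837), together with its probability-scale classification
cutoffs (high specificity 0.839; Youden 0.461).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .dataset import AMPLIFIED, UNAMPLIFIED, LabeledPTP

__all__ = [
    "LogisticModel",
    "FitDiagnosticError",
    "design_matrix",
    "fit_logistic",
    "aic",
    "backward_stepwise",
    "predict_probability",
    "fe_score",
    "fe_classify",
    "published_tmm",
    "published_cutoffs",
    "LR1_TERMS",
    "LR2_TERMS",
    "TMM_TERMS",
]

#: Term sets of the two exploratory models and the selected model.
LR1_TERMS = ["intercept", "z1", "z2", "z3", "z4", "z5", "z6", "x_n", "delta_g"]
LR2_TERMS = LR1_TERMS + ["i_x", "delta_g:i_x"]
TMM_TERMS = ["intercept", "delta_g", "i_x", "delta_g:i_x"]

_ALIAS_TOL = 1e-10


class FitDiagnosticError(RuntimeError):
    """Single-class data, perfect separation, or a non-converged fit."""


@dataclass(frozen=True)
class LogisticModel:
    """A fitted (or published) logistic regression on the log-odds scale.

    ``coefficients`` align with ``terms``; aliased terms carry NaN
    coefficients and ``aliased[i]`` is True.  ``aic`` is 2k - 2 ln L with k
    counting estimated (non-aliased) coefficients only.
    """

    name: str
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]
    standard_errors: tuple[float, ...] | None = None
    wald_p_values: tuple[float, ...] | None = None
    log_likelihood: float | None = None
    aic: float | None = None
    n_obs: int | None = None
    aliased: tuple[bool, ...] = ()
    selection_trace: tuple[tuple[str, float], ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.terms):
            raise ValueError("coefficients must align with terms")
        if not self.aliased:
            object.__setattr__(
                self, "aliased", tuple(math.isnan(c) for c in self.coefficients)
            )

    @property
    def k(self) -> int:
        """Number of estimated coefficients (aliased terms do not count)."""
        return sum(1 for a in self.aliased if not a)

    def linear_predictor(self, values: Mapping[str, float]) -> float:
        lp = 0.0
        for term, coef, alias in zip(self.terms, self.coefficients, self.aliased):
            if alias:
                continue
            lp += coef * _term_value(term, values)
        return lp

    def predict(self, values: Mapping[str, float]) -> float:
        return _expit(self.linear_predictor(values))

    def to_json(self, path) -> None:
        def _clean(x):
            if x is None:
                return None
            return [None if (isinstance(v, float) and math.isnan(v)) else v for v in x]

        with open(path, "w") as fh:
            json.dump(
                {
                    "name": self.name,
                    "terms": list(self.terms),
                    "coefficients": _clean(self.coefficients),
                    "standard_errors": _clean(self.standard_errors),
                    "wald_p_values": _clean(self.wald_p_values),
                    "log_likelihood": self.log_likelihood,
                    "aic": self.aic,
                    "n_obs": self.n_obs,
                    "selection_trace": [list(t) for t in self.selection_trace],
                    "provenance": self.provenance,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticModel":
        def _tup(x):
            if x is None:
                return None
            return tuple(math.nan if v is None else float(v) for v in x)

        return cls(
            name=d.get("name", "model"),
            terms=tuple(d["terms"]),
            coefficients=_tup(d["coefficients"]),
            standard_errors=_tup(d.get("standard_errors")),
            wald_p_values=_tup(d.get("wald_p_values")),
            log_likelihood=d.get("log_likelihood"),
            aic=d.get("aic"),
            n_obs=d.get("n_obs"),
            selection_trace=tuple(
                (t[0], float(t[1])) for t in d.get("selection_trace", [])
            ),
            provenance=d.get("provenance", ""),
        )

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _base_value(name: str, values: Mapping[str, float]) -> float:
    if name == "intercept":
        return 1.0
    if name not in values:
        raise KeyError(f"no value supplied for model term {name!r}")
    return float(values[name])


def _term_value(term: str, values: Mapping[str, float]) -> float:
    out = 1.0
    for factor in term.split(":"):
        out *= _base_value(factor, values)
    return out


def _pair_values(pair: LabeledPTP) -> dict[str, float]:
    fv = pair.features
    vals = {
        "delta_g": fv.delta_g,
        "i_x": float(fv.i_x),
        "x_n": float(fv.x_n),
        "n_mismatches_total": float(fv.n_mismatches_total),
    }
    for j in range(6):
        vals[f"z{j+1}"] = float(fv.z[j])
    return vals


def design_matrix(data: Sequence[LabeledPTP], terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) with one column per term (interactions as products), y = 1 for Amplified."""
    X = np.empty((len(data), len(terms)))
    y = np.empty(len(data))
    for i, pair in enumerate(data):
        vals = _pair_values(pair)
        for j, term in enumerate(terms):
            X[i, j] = _term_value(term, vals)
        y[i] = 1.0 if pair.label == AMPLIFIED else 0.0
    return X, y


def _aliased_columns(X: np.ndarray) -> list[int]:
    """Indices of columns linearly dependent on earlier ones.

    Columns are admitted left to right; a column that does not increase the
    rank of the admitted set (rank-revealing QR, tolerance 1e-10) is flagged
    aliased — the later column of a dependency loses, matching how singular
    terms are reported as NA by standard GLM software.
    """
    keep: list[int] = []
    aliased: list[int] = []
    for j in range(X.shape[1]):
        sub = X[:, keep + [j]]
        r = scipy.linalg.qr(sub, mode="r")[0]
        diag = np.abs(np.diag(r))
        scale = max(diag.max(), 1.0)
        if np.all(diag > _ALIAS_TOL * scale):
            keep.append(j)
        else:
            aliased.append(j)
    return aliased


def fit_logistic(
    data: Sequence[LabeledPTP],
    terms: Sequence[str],
    name: str = "logistic",
) -> LogisticModel:
    """Maximum-likelihood logistic regression via IRLS.

    Convergence tolerance 1e-8, at most 100 iterations.  Perfectly
    collinear columns are flagged aliased (NaN coefficient) and excluded
    from estimation; single-class data and perfect separation raise
    :class:`FitDiagnosticError` rather than silently diverging.
    """
    terms = list(terms)
    X, y = design_matrix(data, terms)
    if len(np.unique(y)) < 2:
        raise FitDiagnosticError("all observations carry the same label; nothing to fit")
    aliased_idx = set(_aliased_columns(X))
    kept = [j for j in range(len(terms)) if j not in aliased_idx]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            res = sm.GLM(y, X[:, kept], family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8
            )
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise FitDiagnosticError(f"perfect separation: {exc}") from exc
    if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 1e8:
        raise FitDiagnosticError("fit diverged (unbounded coefficients); data may be separable")
    coefs = np.full(len(terms), np.nan)
    ses = np.full(len(terms), np.nan)
    pvals = np.full(len(terms), np.nan)
    coefs[kept] = res.params
    ses[kept] = res.bse
    pvals[kept] = res.pvalues
    k = len(kept)
    llf = float(res.llf)
    return LogisticModel(
        name=name,
        terms=tuple(terms),
        coefficients=tuple(coefs),
        standard_errors=tuple(ses),
        wald_p_values=tuple(pvals),
        log_likelihood=llf,
        aic=2 * k - 2 * llf,
        n_obs=len(data),
        aliased=tuple(j in aliased_idx for j in range(len(terms))),
    )


def aic(model: LogisticModel) -> float:
    """AIC = 2k - 2 ln L, with k the number of estimated coefficients."""
    if model.log_likelihood is None:
        raise ValueError("model carries no log-likelihood")
    return 2 * model.k - 2 * model.log_likelihood


def _removable(terms: Sequence[str]) -> list[str]:
    """Terms droppable this step: not the intercept, and no main effect whose
    interaction is still present (marginality)."""
    out = []
    for t in terms:
        if t == "intercept":
            continue
        if ":" not in t and any(
            ":" in other and t in other.split(":") for other in terms
        ):
            continue
        out.append(t)
    return out


def backward_stepwise(
    data: Sequence[LabeledPTP],
    initial_terms: Sequence[str],
    name: str = "stepwise",
) -> LogisticModel:
    """Greedy backward elimination minimizing the AIC.

    Each step refits every single-term-removal candidate and removes the
    term giving the largest AIC decrease; the loop stops when every removal
    would raise the AIC.  A removal that leaves the AIC exactly unchanged
    is accepted (parsimony at a tie): this matters when the term set spans
    a redundant design — e.g. all of z1..z6 next to x_n = sum z_j — where
    dropping one redundant column cannot change the fit.  The removal trace
    (term, AIC after removal) is attached to the returned model.
    """
    current = fit_logistic(data, initial_terms, name=name)
    trace: list[tuple[str, float]] = []
    while True:
        best: LogisticModel | None = None
        best_term = ""
        for term in _removable(current.terms):
            cand_terms = [t for t in current.terms if t != term]
            try:
                cand = fit_logistic(data, cand_terms, name=name)
            except FitDiagnosticError:
                continue
            if best is None or cand.aic < best.aic:
                best, best_term = cand, term
        if best is None or best.aic > current.aic + 1e-8:
            return replace(current, selection_trace=tuple(trace))
        trace.append((best_term, best.aic))
        current = best


def predict_probability(
    model: LogisticModel, delta_g: float, i_x: int, **other: float
) -> float:
    """Probability of amplification for one pair under ``model``."""
    if not (isinstance(i_x, (int, np.integer)) and 0 <= i_x <= 6):
        raise ValueError(f"i_x must be an integer in 0..6, got {i_x!r}")
    values = {"delta_g": float(delta_g), "i_x": float(i_x), **other}
    return model.predict(values)


def fe_score(delta_g: float) -> float:
    """Baseline free-energy score: the annealing dG itself (lower = more
    likely amplified; ROC direction is 'less')."""
    return float(delta_g)


def fe_classify(delta_g: float, cutoff: float) -> str:
    """Free-energy classification rule: Amplified iff dG < cutoff (strict)."""
    return AMPLIFIED if delta_g < cutoff else UNAMPLIFIED


def _published_dict() -> dict:
    with resources.files("primeramp.data").joinpath("tmm_published.json").open() as fh:
        return json.load(fh)


def published_tmm() -> LogisticModel:
    """The published TMM coefficients as a read-only model instance."""
    return LogisticModel.from_dict(_published_dict())


def published_cutoffs() -> dict[str, float]:
    """Bundled probability-scale cutoffs: high-specificity and Youden."""
    return dict(_published_dict()["cutoffs"])
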