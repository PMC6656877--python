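"""Predictor encodings for primer-template pairs.

The per-pair predictors are the annealing free energy dG and three
encodings of mismatches within the 3' hexamer (the six primer positions
nearest the 3' terminus, indexed j = 1..6 with j = 6 the terminal base):

* ``z`` in {0,1}^6 — z_j = 1 iff position j of the hexamer is mismatched;
* ``X_N = sum_j z_j`` — the number of hexamer mismatches;
* ``i_X = max{j : z_j = 1}`` (0 if none) — the hexamer mismatch closest to
  the 3' terminus.

Primer-intrinsic descriptors (GC ratio, GC-clamp extent, longest
homopolymer run) are computed alongside but are not model inputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

from .binding import (
    BindingConformation,
    InvalidSequenceError,
    NucleotideSequence,
    find_best_binding,
)
from . import thermo

__all__ = [
    "FeatureVector",
    "PrimerDescriptors",
    "encode_hexamer",
    "closest_3prime_mismatch",
    "gc_ratio",
    "gc_clamp_extent",
    "longest_run",
    "primer_descriptors",
    "featurize_pair",
    "FEATURE_COLUMNS",
    "write_feature_table",
]


@dataclass(frozen=True)
class FeatureVector:
    """Per-pair predictors; invariants of the encodings are enforced."""

    primer_id: str
    template_id: str
    delta_g: float
    z: tuple[bool, bool, bool, bool, bool, bool]
    x_n: int
    i_x: int
    n_mismatches_total: int
    primer_set: str = ""

    def __post_init__(self) -> None:
        if len(self.z) != 6:
            raise ValueError("z must have exactly 6 entries")
        if self.x_n != sum(self.z):
            raise ValueError("x_n must equal the number of set entries in z")
        expected_ix = max((j for j, zj in enumerate(self.z, start=1) if zj), default=0)
        if self.i_x != expected_ix:
            raise ValueError(f"i_x must be {expected_ix}, got {self.i_x}")
        if self.n_mismatches_total < self.x_n:
            raise ValueError("total mismatches cannot be fewer than hexamer mismatches")


@dataclass(frozen=True)
class PrimerDescriptors:
    length: int
    gc_ratio: float
    gc_clamp_extent: int
    longest_run: int

    def __post_init__(self) -> None:
        if not 0 <= self.gc_clamp_extent <= self.length:
            raise ValueError("GC clamp extent must lie within the primer length")


def encode_hexamer(conformation: BindingConformation) -> tuple[bool, ...]:
    """Binary hexamer mismatch vector z; z[j-1] is position j, j=6 the 3' end."""
    if len(conformation) < 6:
        raise InvalidSequenceError("hexamer encoding requires primer length >= 6")
    return tuple(j in conformation.hexamer_mismatch_positions for j in range(1, 7))


def closest_3prime_mismatch(z: Sequence[bool]) -> int:
    """i_X: largest hexamer position with a mismatch, 0 if the hexamer is clean."""
    return max((j for j, zj in enumerate(z, start=1) if zj), default=0)


def _bases_of(seq) -> str:
    return (seq.bases if isinstance(seq, NucleotideSequence) else str(seq)).upper()


def gc_ratio(seq) -> float:
    """Fraction of G/C bases (the S code counts; other degenerate codes do not)."""
    bases = _bases_of(seq)
    if not bases:
        raise InvalidSequenceError("empty sequence")
    return sum(1 for b in bases if b in "GCS") / len(bases)


def gc_clamp_extent(seq) -> int:
    """Length of the G/C run ending at the 3' terminus (0 if the 3' base is A/T)."""
    bases = _bases_of(seq)
    if not bases:
        raise InvalidSequenceError("empty sequence")
    n = 0
    for b in reversed(bases):
        if b in "GCS":
            n += 1
        else:
            break
    return n


def longest_run(seq) -> int:
    """Maximal homopolymer run anywhere in the sequence (descriptive only)."""
    bases = _bases_of(seq)
    best = cur = 1
    for prev, b in zip(bases, bases[1:]):
        cur = cur + 1 if b == prev else 1
        best = max(best, cur)
    return best


def primer_descriptors(primer: NucleotideSequence) -> PrimerDescriptors:
    return PrimerDescriptors(
        length=len(primer),
        gc_ratio=gc_ratio(primer),
        gc_clamp_extent=gc_clamp_extent(primer),
        longest_run=longest_run(primer),
    )


def featurize_pair(
    primer: NucleotideSequence,
    template: NucleotideSequence,
    temperature_celsius: float = 55.0,
    params: "thermo.NNParameterSet | None" = None,
    primer_set: str = "",
) -> FeatureVector:
    """Best binding conformation -> annealing dG -> hexamer encodings.

    The binding search breaks mismatch-count ties by annealing free energy
    at the requested temperature, so the featurization is deterministic.
    """
    scorer = lambda c: thermo.annealing_delta_g(
        c, primer, template, temperature_celsius, params
    ).delta_g
    conf = find_best_binding(primer, template, thermodynamics=scorer)
    result = thermo.annealing_delta_g(conf, primer, template, temperature_celsius, params)
    z = encode_hexamer(conf)
    return FeatureVector(
        primer_id=primer.identifier,
        template_id=template.identifier,
        delta_g=result.delta_g,
        z=z,
        x_n=sum(z),
        i_x=closest_3prime_mismatch(z),
        n_mismatches_total=conf.n_mismatches,
        primer_set=primer_set,
    )


#: Canonical feature-table schema (also accepted by the dataset reader).
FEATURE_COLUMNS = [
    "primer_id", "template_id", "primer_set", "delta_g",
    "z1", "z2", "z3", "z4", "z5", "z6",
    "x_n", "i_x", "n_mismatches_total", "gc_ratio", "gc_clamp", "label",
]


def write_feature_table(
    vectors: Iterable[FeatureVector],
    path,
    labels: Sequence[str] | None = None,
    descriptors: Sequence[PrimerDescriptors] | None = None,
) -> None:
    """One CSV row per pair in the canonical schema; label column optional."""
    vectors = list(vectors)
    if labels is not None and len(labels) != len(vectors):
        raise ValueError("labels must align with vectors")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FEATURE_COLUMNS)
        for i, v in enumerate(vectors):
            desc = descriptors[i] if descriptors is not None else None
            writer.writerow(
                [
                    v.primer_id, v.template_id, v.primer_set,
                    f"{v.delta_g:.6g}",
                    *[int(zj) for zj in v.z],
                    v.x_n, v.i_x, v.n_mismatches_total,
                    f"{desc.gc_ratio:.3f}" if desc else "",
                    desc.gc_clamp_extent if desc else "",
                    labels[i] if labels is not None else "",
                ]
            )
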