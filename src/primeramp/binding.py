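"""Primer-template binding-site search.

A primer is placed ungapped at every offset of the template (sense-strand
convention: a forward primer is compared base-by-base against the strand it
copies, so a perfect binding site is an exact substring up to IUPAC
degeneracy).  The most likely binding conformation is the one minimizing the
number of mismatches; ties are broken by annealing free energy when a
thermodynamic scorer is supplied, otherwise by smallest offset.

Positions within the 3' hexamer (the last six primer bases) are reported
1-based with j = 6 at the 3' terminus, the convention used throughout the
feature encodings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC_CODES",
    "NucleotideSequence",
    "BindingConformation",
    "bases_compatible",
    "enumerate_conformations",
    "find_best_binding",
    "reverse_complement",
    "read_fasta",
    "write_conformations_tsv",
]

#: IUPAC nucleotide codes mapped to the set of concrete bases they denote.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class InvalidSequenceError(ValueError):
    """Raised for sequences containing non-IUPAC characters or empty input."""


def _validate_bases(bases: str, identifier: str = "") -> str:
    if not bases:
        raise InvalidSequenceError(f"empty sequence {identifier!r}")
    up = bases.upper()
    bad = set(up) - set(IUPAC_CODES)
    if bad:
        raise InvalidSequenceError(
            f"sequence {identifier!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return up


@dataclass(frozen=True)
class NucleotideSequence:
    """A primer or template sequence, stored 5'->3' over the IUPAC alphabet."""

    identifier: str
    bases: str
    role: str = "primer"  # "primer" or "template"

    def __post_init__(self) -> None:
        if self.role not in ("primer", "template"):
            raise ValueError(f"role must be 'primer' or 'template', got {self.role!r}")
        object.__setattr__(self, "bases", _validate_bases(self.bases, self.identifier))

    def __len__(self) -> int:
        return len(self.bases)


def reverse_complement(bases: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(bases.upper()))


def bases_compatible(primer_base: str, template_base: str) -> bool:
    """True iff the IUPAC expansions of the two codes intersect.

    A compatible position is a match: a degenerate primer position is
    synthesized as a base mixture, so at least one primer molecule pairs
    perfectly with the template base.
    """
    try:
        pa = IUPAC_CODES[primer_base.upper()]
        ta = IUPAC_CODES[template_base.upper()]
    except KeyError as exc:
        raise InvalidSequenceError(f"invalid IUPAC code: {exc.args[0]!r}") from exc
    return bool(pa & ta)


@dataclass(frozen=True)
class BindingConformation:
    """One ungapped primer placement on a template.

    ``offset`` is the 0-based template index aligned with the primer 5' base.
    ``hexamer_mismatch_positions`` re-indexes mismatches among the last six
    primer positions so that j = 6 is the 3' terminus.
    """

    primer_id: str
    template_id: str
    offset: int
    per_position_match: tuple[bool, ...]
    n_mismatches: int = field(init=False)
    hexamer_mismatch_positions: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        n_mm = sum(1 for m in self.per_position_match if not m)
        object.__setattr__(self, "n_mismatches", n_mm)
        L = len(self.per_position_match)
        hex_len = min(6, L)
        positions = frozenset(
            6 - (L - 1 - i)
            for i in range(L - hex_len, L)
            if not self.per_position_match[i]
        )
        object.__setattr__(self, "hexamer_mismatch_positions", positions)

    def __len__(self) -> int:
        return len(self.per_position_match)


def _score_offset(primer: NucleotideSequence, template_bases: str, offset: int) -> tuple[bool, ...]:
    return tuple(
        bases_compatible(pb, template_bases[offset + i])
        for i, pb in enumerate(primer.bases)
    )


def enumerate_conformations(
    primer: NucleotideSequence, template: NucleotideSequence
) -> list[BindingConformation]:
    """All fully-contained ungapped placements of the primer on the template.

    Placements overhanging a template end are not generated: templates are
    assumed to contain the complete annealing region (they carry the full
    leader upstream of the target gene), so partial overlaps are rejected.
    """
    if len(primer) > len(template):
        raise InvalidSequenceError(
            f"primer {primer.identifier!r} (length {len(primer)}) longer than "
            f"template {template.identifier!r} (length {len(template)})"
        )
    return [
        BindingConformation(
            primer_id=primer.identifier,
            template_id=template.identifier,
            offset=off,
            per_position_match=_score_offset(primer, template.bases, off),
        )
        for off in range(len(template) - len(primer) + 1)
    ]


def find_best_binding(
    primer: NucleotideSequence,
    template: NucleotideSequence,
    thermodynamics: Callable[[BindingConformation], float] | None = None,
    search_reverse_complement: bool = False,
) -> BindingConformation:
    """Most likely binding conformation: minimal mismatch count.

    Among placements tied on mismatch count, the one with minimal annealing
    free energy wins when ``thermodynamics`` (a conformation -> dG scorer) is
    given; otherwise the smallest offset, which keeps results deterministic.

    ``search_reverse_complement`` additionally searches the template's
    reverse complement (off by default: forward primers are scored against
    sense-strand templates).
    """
    candidates = enumerate_conformations(primer, template)
    if search_reverse_complement:
        rc = NucleotideSequence(
            template.identifier, reverse_complement(template.bases), role="template"
        )
        candidates += enumerate_conformations(primer, rc)
    best_mm = min(c.n_mismatches for c in candidates)
    tied = [c for c in candidates if c.n_mismatches == best_mm]
    if thermodynamics is not None and len(tied) > 1:
        return min(tied, key=lambda c: (thermodynamics(c), c.offset))
    return min(tied, key=lambda c: c.offset)


def read_fasta(path, role: str) -> list[NucleotideSequence]:
    """Read a multi-record FASTA into validated sequences (case-insensitive)."""
    records = [
        NucleotideSequence(identifier=rec.id, bases=str(rec.seq), role=role)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InvalidSequenceError(f"no FASTA records found in {path}")
    return records


def write_conformations_tsv(conformations: Iterable[BindingConformation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["primer_id", "template_id", "offset", "n_mismatches", "hexamer_mismatch_positions"]
        )
        for c in conformations:
            writer.writerow(
                [
                    c.primer_id,
                    c.template_id,
                    c.offset,
                    c.n_mismatches,
                    ",".join(str(j) for j in sorted(c.hexamer_mismatch_positions)),
                ]
            )
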