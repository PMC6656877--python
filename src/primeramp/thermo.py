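"""Nearest-neighbor thermodynamics of primer-template annealing.

The free energy of duplex formation is the sum of dinucleotide-step
enthalpy/entropy terms plus duplex-initiation terms, evaluated at the
annealing temperature:

    dG = dH - T_K * dS / 1000      (dH kcal/mol, dS cal/(mol K))

Watson-Crick steps and internal single-mismatch steps come from a
:class:`NNParameterSet`.  The default set is assembled from the unified
Watson-Crick parameters and the internal-mismatch series shipped with
Biopython (``Bio.SeqUtils.MeltingTemp`` tables DNA_NN3 and DNA_IMM1, 1 M Na+
reference conditions; no salt correction is applied).

Steps that published single-mismatch tables do not cover — tandem (adjacent)
mismatches and mismatches at a duplex end — contribute a configurable
neutral penalty (default 0 kcal/mol) and are flagged in the result.  This is
a deliberate, conservative fallback; exact parity with any particular
hybridization program is not a goal of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.SeqUtils import MeltingTemp as _mt

from .binding import (
    IUPAC_CODES,
    BindingConformation,
    InvalidSequenceError,
    NucleotideSequence,
    reverse_complement,
)

__all__ = [
    "NNParameterSet",
    "AnnealingResult",
    "ParameterizationError",
    "annealing_delta_g",
    "self_dimer_delta_g",
    "unified_parameters",
    "default_parameters",
    "load_parameter_table",
    "write_parameter_table",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
_KELVIN = 273.15


class ParameterizationError(KeyError):
    """A required thermodynamic step is absent and no fallback applies."""


@dataclass(frozen=True)
class NNParameterSet:
    """Immutable nearest-neighbor parameter table.

    Keys are duplex steps written ``XY/WZ``: ``XY`` is 5'->3' on the primer
    strand, ``WZ`` the paired bases of the bound strand written 3'->5'
    beneath them (so ``W`` pairs with ``X``).  A step is looked up directly
    or in the flipped orientation (``key[::-1]``).
    """

    stack_params: dict[str, tuple[float, float]]
    initiation: dict[str, tuple[float, float]]
    source_label: str
    tandem_penalty: tuple[float, float] = (0.0, 0.0)

    def lookup(self, step: str) -> tuple[float, float] | None:
        hit = self.stack_params.get(step)
        if hit is None:
            hit = self.stack_params.get(step[::-1])
        return hit

    def validate_complete(self) -> None:
        """Every WC step and every internal single-mismatch step must resolve."""
        missing = []
        for a in "ACGT":
            for b in "ACGT":
                for x in "ACGT":
                    for y in "ACGT":
                        wc1, wc2 = x == _COMP[a], y == _COMP[b]
                        if wc1 and wc2 or wc1 != wc2:
                            if self.lookup(f"{a}{b}/{x}{y}") is None:
                                missing.append(f"{a}{b}/{x}{y}")
        if missing:
            raise ParameterizationError(
                f"parameter set {self.source_label!r} missing steps: {missing}"
            )


def unified_parameters() -> NNParameterSet:
    """Default parameter set: unified WC stacks + internal single mismatches."""
    stacks: dict[str, tuple[float, float]] = {}
    init: dict[str, tuple[float, float]] = {}
    for key, val in _mt.DNA_NN3.items():
        if key.startswith("init") or key == "sym":
            init[key] = tuple(val)
        else:
            stacks[key] = tuple(val)
    for key, val in _mt.DNA_IMM1.items():
        if "I" in key:  # inosine steps are out of scope
            continue
        stacks[key] = tuple(val)
    params = NNParameterSet(
        stack_params=stacks,
        initiation=init,
        source_label="unified-WC+internal-mismatch (Biopython DNA_NN3/DNA_IMM1)",
    )
    params.validate_complete()
    return params


_DEFAULT_PARAMS: NNParameterSet | None = None


def default_parameters() -> NNParameterSet:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = unified_parameters()
    return _DEFAULT_PARAMS


def load_parameter_table(path) -> NNParameterSet:
    """Load a plain-text parameter table.

    Format: a ``# source: <label>`` header line, then whitespace-separated
    rows ``step dH dS``.  Rows named ``init*`` populate initiation terms.
    Completeness is validated on load.
    """
    stacks: dict[str, tuple[float, float]] = {}
    init: dict[str, tuple[float, float]] = {}
    source = Path(path).name
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "source:" in line:
                    source = line.split("source:", 1)[1].strip()
                continue
            step, dh, ds = line.split()
            if step.startswith("init") or step == "sym":
                init[step] = (float(dh), float(ds))
            else:
                stacks[step] = (float(dh), float(ds))
    params = NNParameterSet(stack_params=stacks, initiation=init, source_label=source)
    params.validate_complete()
    return params


def write_parameter_table(params: NNParameterSet, path) -> None:
    """Serialize a parameter set to the plain-text table format."""
    with open(path, "w") as fh:
        fh.write(f"# source: {params.source_label}\n")
        fh.write("# step dH[kcal/mol] dS[cal/(mol K)]\n")
        for step, (dh, ds) in sorted(params.initiation.items()):
            fh.write(f"{step} {dh} {ds}\n")
        for step, (dh, ds) in sorted(params.stack_params.items()):
            fh.write(f"{step} {dh} {ds}\n")


@dataclass(frozen=True)
class AnnealingResult:
    """Duplex formation energetics at a given temperature.

    Satisfies ``delta_g == delta_h - T_K * delta_s / 1000`` exactly by
    construction.  ``fallback_steps`` lists 0-based step indices that used
    the neutral tandem/terminal-mismatch fallback.
    """

    delta_g: float
    delta_h: float
    delta_s: float
    temperature_celsius: float
    source_label: str = ""
    fallback_steps: tuple[int, ...] = ()

    @classmethod
    def from_hs(cls, dh: float, ds: float, temperature_celsius: float, **kw) -> "AnnealingResult":
        dg = dh - (temperature_celsius + _KELVIN) * ds / 1000.0
        return cls(delta_g=dg, delta_h=dh, delta_s=ds,
                   temperature_celsius=temperature_celsius, **kw)


def _resolve_degenerate(code: str, partner: str) -> str:
    """Concrete base for a degenerate code: the partner-matching expansion
    if the intersection is non-empty, else the first expansion alphabetically."""
    exp = IUPAC_CODES[code]
    if len(exp) == 1:
        return next(iter(exp))
    partner_exp = IUPAC_CODES[partner]
    common = exp & partner_exp
    pool = common if common else exp
    return min(pool)


def _duplex_hs(
    primer_bases: str,
    template_window: str,
    params: NNParameterSet,
) -> tuple[float, float, list[int]]:
    """Sum dH/dS over an aligned duplex (sense-strand convention).

    The physically bound strand is the complement of the sense window, so a
    step key pairs primer bases with complemented window bases.
    """
    p = [
        _resolve_degenerate(pb, tb)
        for pb, tb in zip(primer_bases.upper(), template_window.upper())
    ]
    w = [
        _resolve_degenerate(tb, pb)
        for pb, tb in zip(primer_bases.upper(), template_window.upper())
    ]
    n = len(p)
    if n < 2:
        raise InvalidSequenceError("duplex must span at least 2 base pairs")
    matched = [p[i] == w[i] for i in range(n)]
    dh = ds = 0.0
    fallbacks: list[int] = []
    # initiation: per-end terms apply only to a Watson-Crick terminal pair
    for end in (0, n - 1):
        if matched[end]:
            term = "init_G/C" if p[end] in "GC" else "init_A/T"
            h, s = params.initiation.get(term, (0.0, 0.0))
            dh += h
            ds += s
    h, s = params.initiation.get("init", (0.0, 0.0))
    dh += h
    ds += s
    for i in range(n - 1):
        pair1, pair2 = matched[i], matched[i + 1]
        terminal_mm = (i == 0 and not pair1) or (i == n - 2 and not pair2)
        if (not pair1 and not pair2) or terminal_mm:
            h, s = params.tandem_penalty
            fallbacks.append(i)
        else:
            step = f"{p[i]}{p[i+1]}/{_COMP[w[i]]}{_COMP[w[i+1]]}"
            hit = params.lookup(step)
            if hit is None:
                raise ParameterizationError(
                    f"no parameters for step {step!r} in set {params.source_label!r}"
                )
            h, s = hit
        dh += h
        ds += s
    return dh, ds, fallbacks


def annealing_delta_g(
    conformation: BindingConformation,
    primer: NucleotideSequence,
    template: NucleotideSequence,
    temperature_celsius: float,
    params: NNParameterSet | None = None,
) -> AnnealingResult:
    """Free energy of annealing for a binding conformation.

    The template window at ``conformation.offset`` is paired against the
    primer; steps with one internal mismatch use the mismatch series, steps
    the tables do not cover use the neutral fallback (flagged).
    """
    if params is None:
        params = default_parameters()
    off = conformation.offset
    window = template.bases[off: off + len(primer)]
    if len(window) != len(primer):
        raise InvalidSequenceError("conformation does not fit on the template")
    dh, ds, fallbacks = _duplex_hs(primer.bases, window, params)
    return AnnealingResult.from_hs(
        dh, ds, temperature_celsius,
        source_label=params.source_label, fallback_steps=tuple(fallbacks),
    )


def self_dimer_delta_g(
    primer: NucleotideSequence,
    temperature_celsius: float,
    params: NNParameterSet | None = None,
) -> float:
    """Most stable ungapped self-dimer free energy, clamped at 0.

    Two antiparallel copies of the primer are slid against each other; in
    sense-strand coordinates this is the primer aligned against its own
    reverse complement at every overlap of length >= 2.  Non-negative
    minima are reported as 0 (no appreciable self-complementarity).
    """
    if len(primer) < 4:
        raise InvalidSequenceError("self-dimer scan requires primer length >= 4")
    if params is None:
        params = default_parameters()
    rc = reverse_complement(primer.bases)
    n = len(primer)
    best = 0.0
    for shift in range(-(n - 2), n - 1):
        a0, b0 = max(0, shift), max(0, -shift)
        ln = n - abs(shift)
        dh, ds, _ = _duplex_hs(primer.bases[a0: a0 + ln], rc[b0: b0 + ln], params)
        dg = dh - (temperature_celsius + _KELVIN) * ds / 1000.0
        best = min(best, dg)
    return best
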