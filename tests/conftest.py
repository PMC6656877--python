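import numpy as np
import pytest

from primeramp.binding import NucleotideSequence

BASES = "ACGT"


def random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def mutate(rng: np.random.Generator, bases: str, positions) -> str:
    """Substitute each given position with a different concrete base."""
    out = list(bases)
    for pos in positions:
        out[pos] = rng.choice([b for b in BASES if b != bases[pos]])
    return "".join(out)


def plant_primer(rng, template_bases: str, offset: int, length: int, mismatch_positions=()):
    """A primer equal to the template window at ``offset`` except at the
    given primer positions (0-based from the primer 5' end)."""
    window = template_bases[offset: offset + length]
    return NucleotideSequence("planted", mutate(rng, window, mismatch_positions))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
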