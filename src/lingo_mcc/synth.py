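"""Deterministic synthetic SMILES libraries for testing and benchmarking.

Generated strings are random text over a SMILES-like alphabet, **not**
chemically valid molecules.  That is deliberate: every stage of the method —
fragmentation, packing, merging, thresholding — treats a SMILES purely as a
character string, so the textual statistics that matter (length distribution,
alphabet, repeat structure) are controlled here while chemistry is not
modelled at all.  Do not feed these libraries to tools that parse SMILES
chemically.

:func:`mutate_pair` produces a copy of a compound with an exact number of
character substitutions, giving controllable similarity to the original: one
substitution can destroy at most q overlapping Lingos, so similarity decays
smoothly (on average) with the substitution count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .smiles_io import Compound

__all__ = ["DEFAULT_ALPHABET", "SynthSpec", "gen_library", "mutate_pair"]

# Common SMILES organic-subset characters: atoms, aromatics, bonds, branches,
# brackets, ring-closure digits, stereo/charge marks.
DEFAULT_ALPHABET = "CNOPSFIclnos=#()[]1234567890@+-/\\Br"


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic library.

    ``length_dist`` selects how character counts are drawn: ``"uniform"``
    takes ``(low, high)`` inclusive bounds; ``"truncnorm"`` takes
    ``(mean, sd)`` and redraws until the rounded length is >= 1.
    """

    n: int
    length_dist: str = "uniform"
    params: tuple[float, float] = (20, 80)
    alphabet: str = DEFAULT_ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n must be >= 0, got {self.n}")
        if self.length_dist not in ("uniform", "truncnorm"):
            raise ConfigurationError(f"unknown length_dist {self.length_dist!r}")
        if not self.alphabet:
            raise ConfigurationError("alphabet must be non-empty")
        if self.length_dist == "uniform":
            low, high = self.params
            if not (1 <= low <= high):
                raise ConfigurationError(f"need 1 <= low <= high, got {self.params}")
        elif self.params[1] < 0:
            raise ConfigurationError(f"sd must be >= 0, got {self.params[1]}")


def _draw_lengths(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.length_dist == "uniform":
        low, high = int(spec.params[0]), int(spec.params[1])
        return rng.integers(low, high + 1, size=spec.n)
    mean, sd = spec.params
    lengths = np.empty(spec.n, dtype=np.int64)
    for i in range(spec.n):
        while True:
            l = int(round(rng.normal(mean, sd)))
            if l >= 1:
                lengths[i] = l
                break
    return lengths


def gen_library(spec: SynthSpec) -> list[Compound]:
    """Generate ``spec.n`` compounds with ids S000001, S000002, …

    Characters are drawn i.i.d. from the alphabet; identical spec + seed
    yields a byte-identical library.
    """
    rng = np.random.default_rng(spec.seed)
    chars = np.array(list(spec.alphabet))
    lengths = _draw_lengths(spec, rng)
    out = []
    for i in range(spec.n):
        drawn = rng.choice(chars, size=int(lengths[i]))
        # a leading '#' would read back as a comment line; redraw it
        while drawn[0] == "#":
            drawn[0] = rng.choice(chars)
        out.append(Compound(id=f"S{i + 1:06d}", smiles="".join(drawn), source_line=i + 1))
    return out


def mutate_pair(base: Compound, substitutions: int, seed: int, alphabet: str = DEFAULT_ALPHABET) -> Compound:
    """Copy of ``base`` with exactly ``substitutions`` characters replaced.

    Positions are drawn without replacement; each replacement character is
    drawn from ``alphabet`` excluding the character it replaces, so every
    chosen position genuinely changes.
    """
    L = len(base.smiles)
    if not 0 <= substitutions <= L:
        raise ConfigurationError(f"substitutions must be in [0, {L}], got {substitutions}")
    rng = np.random.default_rng(seed)
    chars = list(base.smiles)
    positions = rng.choice(L, size=substitutions, replace=False) if substitutions else []
    for pos in positions:
        # never place '#' first (it would read back as a comment line)
        choices = [c for c in alphabet if c != chars[pos] and not (pos == 0 and c == "#")]
        chars[int(pos)] = choices[int(rng.integers(len(choices)))]
    return Compound(id=f"{base.id}_mut", smiles="".join(chars), source_line=base.source_line)
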