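"""LINGO profile construction.

A compound's *LINGO profile* holds four quantities derived from its SMILES
string of length ``l``:

* **scores** — the distinct q-character substrings (Lingos), each packed into
  an integer by big-endian per-character ASCII codes, sorted ascending;
* **numbers** — the multiplicity of each distinct Lingo, aligned with scores;
* **length** — ``l``, the character count;
* **magnitude** — the count of distinct Lingos (``len(scores)``).

A sliding window with offset 1 yields ``l − q + 1`` Lingos, so
``sum(numbers) == l − q + 1`` whenever ``l ≥ q``; shorter strings produce an
empty profile.  Big-endian packing makes integer order coincide with
lexicographic substring order, so the sorted score list is exactly the sorted
substring list.  For q ≤ 4 scores fit in 32 bits; q ≤ 8 uses 64 bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidLingoError
from .smiles_io import Compound

__all__ = ["LingoProfile", "normalize_smiles", "fragment", "pack_score", "build_profile"]

DEFAULT_Q = 4


def normalize_smiles(smiles: str, ring_digit_zeroing: bool = False) -> str:
    """Optionally collapse ring-closure digits to '0'.

    In SMILES, a decimal digit outside a bracket atom is a ring-closure label
    whose value is arbitrary, so "C1CCCCC1" and "C2CCCCC2" denote the same
    molecule.  With ``ring_digit_zeroing`` every such digit (including the
    digits of a ``%nn`` two-digit closure) becomes '0', making the q-gram
    profile invariant to ring numbering; digits inside ``[...]`` (isotopes,
    charges, hydrogen counts) are untouched.  Default off: packing then sees
    the string exactly as written.
    """
    if not ring_digit_zeroing:
        return smiles
    out = []
    depth = 0
    for ch in smiles:
        if ch == "[":
            depth += 1
        elif ch == "]" and depth > 0:
            depth -= 1
        if depth == 0 and ch.isdigit():
            out.append("0")
        else:
            out.append(ch)
    return "".join(out)


def fragment(smiles: str, q: int = DEFAULT_Q) -> list[str]:
    """All contiguous q-character windows of ``smiles``, left to right.

    A string of length ``l ≥ q`` yields exactly ``l − q + 1`` windows; shorter
    strings yield an empty list.
    """
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    return [smiles[i : i + q] for i in range(len(smiles) - q + 1)]


def pack_score(qgram: str, q: int = DEFAULT_Q) -> int:
    """Pack a q-character ASCII string into an integer score.

    Big-endian: the first character occupies the most significant byte, i.e.
    ``score = c0·256^(q−1) + … + c(q−1)`` with ``ci`` the ASCII code point.
    Injective over q-character ASCII strings, and score order equals
    lexicographic order.  Fits 32 bits for q ≤ 4 (64 bits for q ≤ 8).
    """
    if len(qgram) != q:
        raise InvalidLingoError(f"expected a {q}-character Lingo, got {qgram!r}")
    score = 0
    for ch in qgram:
        cp = ord(ch)
        if cp >= 128:
            raise InvalidLingoError(f"non-ASCII character {ch!r} in Lingo {qgram!r}")
        score = (score << 8) | cp
    return score


def _score_dtype(q: int) -> np.dtype:
    if q <= 4:
        return np.dtype(np.uint32)
    if q <= 8:
        return np.dtype(np.uint64)
    raise InvalidLingoError(f"q={q} exceeds the 64-bit packing limit (q <= 8)")


@dataclass(frozen=True)
class LingoProfile:
    """Sorted unique Lingo scores with multiplicities, plus length and q."""

    scores: np.ndarray  # strictly ascending unsigned ints, one per unique Lingo
    numbers: np.ndarray  # positive int64 multiplicities, aligned with scores
    length: int  # character count of the (normalized) SMILES
    q: int = DEFAULT_Q

    @property
    def magnitude(self) -> int:
        """Number of distinct Lingos."""
        return int(self.scores.size)

    @property
    def total(self) -> int:
        """Total Lingo count, ``max(0, length − q + 1)``."""
        return int(self.numbers.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LingoProfile):
            return NotImplemented
        return (
            self.length == other.length
            and self.q == other.q
            and np.array_equal(self.scores, other.scores)
            and np.array_equal(self.numbers, other.numbers)
        )

    __hash__ = None  # type: ignore[assignment]


_EMPTY_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def build_profile(
    compound: Compound | str,
    q: int = DEFAULT_Q,
    ring_digit_zeroing: bool = False,
) -> LingoProfile:
    """Fragment, pack, count and sort: the full profile of one compound.

    Accepts a :class:`Compound` or a bare SMILES string.  Strings shorter
    than q produce an empty profile (magnitude 0) rather than an error —
    real libraries contain 1–3-character SMILES.
    """
    smiles = compound.smiles if isinstance(compound, Compound) else compound
    smiles = normalize_smiles(smiles, ring_digit_zeroing)
    dtype = _score_dtype(q)
    n = len(smiles)
    if n < q:
        if q not in _EMPTY_CACHE:
            _EMPTY_CACHE[q] = (np.empty(0, dtype=dtype), np.empty(0, dtype=np.int64))
        scores, numbers = _EMPTY_CACHE[q]
        return LingoProfile(scores=scores, numbers=numbers, length=n, q=q)
    try:
        codes = np.frombuffer(smiles.encode("ascii"), dtype=np.uint8)
    except UnicodeEncodeError as exc:
        raise InvalidLingoError(f"non-ASCII character in SMILES {smiles!r}") from exc
    windows = np.lib.stride_tricks.sliding_window_view(codes, q).astype(np.uint64)
    weights = (np.uint64(256) ** np.arange(q - 1, -1, -1, dtype=np.uint64))
    packed = windows @ weights
    scores, numbers = np.unique(packed, return_counts=True)
    scores.setflags(write=False)
    numbers = numbers.astype(np.int64)
    numbers.setflags(write=False)
    return LingoProfile(scores=scores.astype(dtype), numbers=numbers, length=n, q=q)
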