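"""Tanimoto coefficients between LINGO profiles.

Two interpretations of intersection-over-union are supported:

* ``multiset`` (default) — Lingos are counted with multiplicity:
  ``I = Σ_shared min(n_a, n_b)``, ``U = Σ n_a + Σ n_b − I``; this is the
  multiset Jaccard coefficient over the q-gram bags.
* ``set`` — only distinct Lingos count:
  ``I = #shared scores``, ``U = magnitude_a + magnitude_b − I``.

Both are computed by a single linear merge of the two ascending score lists.
When both profiles are empty (both strings shorter than q) the coefficient is
defined as 0: a molecule too short to produce any Lingo matches nothing, not
everything.  Coefficients are accumulated in exact integer arithmetic and
divided once in double precision.
"""

from __future__ import annotations

from collections import Counter

from .errors import IncompatibleProfileError
from .lingo_core import DEFAULT_Q, LingoProfile, fragment, normalize_smiles

__all__ = ["MODES", "tanimoto", "tanimoto_oracle", "merge_intersection"]

MODES = ("multiset", "set")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def merge_intersection(a: LingoProfile, b: LingoProfile) -> tuple[int, int, int]:
    """Linear merge of two sorted score lists.

    Returns ``(shared, overlap, steps)``: the count of shared distinct scores,
    the multiset overlap ``Σ min(n_a, n_b)`` over shared scores, and the
    number of merge steps taken (at most ``magnitude_a + magnitude_b``, useful
    for instrumenting the linear-cost claim).
    """
    sa, sb = a.scores, b.scores
    na, nb = a.numbers, b.numbers
    i = j = shared = overlap = steps = 0
    la, lb = sa.size, sb.size
    while i < la and j < lb:
        steps += 1
        x, y = sa[i], sb[j]
        if x == y:
            shared += 1
            overlap += min(int(na[i]), int(nb[j]))
            i += 1
            j += 1
        elif x < y:
            i += 1
        else:
            j += 1
    return shared, overlap, steps


def tanimoto(a: LingoProfile, b: LingoProfile, mode: str = "multiset") -> float:
    """Tanimoto coefficient of two profiles, in [0, 1].

    Raises :class:`IncompatibleProfileError` if the profiles were built with
    different q.  Symmetric; 1.0 in multiset mode iff the two q-gram bags are
    identical; 0.0 when the profiles share no score (or both are empty).
    """
    _check_mode(mode)
    if a.q != b.q:
        raise IncompatibleProfileError(f"profile q mismatch: {a.q} vs {b.q}")
    shared, overlap, _ = merge_intersection(a, b)
    if mode == "multiset":
        inter = overlap
        union = a.total + b.total - overlap
    else:
        inter = shared
        union = a.magnitude + b.magnitude - shared
    if union == 0:
        return 0.0
    return inter / union


def tanimoto_oracle(
    smiles_a: str,
    smiles_b: str,
    q: int = DEFAULT_Q,
    mode: str = "multiset",
    ring_digit_zeroing: bool = False,
) -> float:
    """Reference computation from raw strings: no packing, no sorting.

    Materializes both q-gram multisets in hash maps and applies the
    intersection/union definition directly.  Used as the independent check
    for the sorted-merge path.
    """
    _check_mode(mode)
    ca = Counter(fragment(normalize_smiles(smiles_a, ring_digit_zeroing), q))
    cb = Counter(fragment(normalize_smiles(smiles_b, ring_digit_zeroing), q))
    if mode == "multiset":
        inter = sum(min(n, cb[g]) for g, n in ca.items())
        union = sum(ca.values()) + sum(cb.values()) - inter
    else:
        inter = len(ca.keys() & cb.keys())
        union = len(ca) + len(cb) - inter
    if union == 0:
        return 0.0
    return inter / union
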