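"""Batched pairwise Tanimoto kernel over CSR-packed profile arrays.

Profiles are concatenated into flat score/number arrays with offsets (one
slice per compound), and the kernel walks each (query row, database column)
pair with the same linear merge as :func:`lingo_mcc.similarity.tanimoto`.
JIT-compiled with numba when available (the kernel releases the GIL so
worker threads genuinely overlap); otherwise a pure-Python fallback with
identical semantics is used.
"""

from __future__ import annotations

import numpy as np

MODE_MULTISET = 0
MODE_SET = 1


def _pairwise_rows(rows, qs, qn, qoff, qtot, ds, dn, doff, dtot, mode, out):
    # rows: query indices this worker owns; out: full (k, r) matrix,
    # each worker writes only its own rows.
    n_db = doff.size - 1
    for t in range(rows.size):
        i = rows[t]
        a0 = qoff[i]
        a1 = qoff[i + 1]
        for j in range(n_db):
            b0 = doff[j]
            b1 = doff[j + 1]
            ia = a0
            jb = b0
            shared = 0
            overlap = 0
            while ia < a1 and jb < b1:
                x = qs[ia]
                y = ds[jb]
                if x == y:
                    na = qn[ia]
                    nb = dn[jb]
                    overlap += na if na < nb else nb
                    shared += 1
                    ia += 1
                    jb += 1
                elif x < y:
                    ia += 1
                else:
                    jb += 1
            if mode == MODE_MULTISET:
                inter = overlap
                union = qtot[i] + dtot[j] - overlap
            else:
                inter = shared
                union = (a1 - a0) + (b1 - b0) - shared
            out[i, j] = inter / union if union > 0 else 0.0


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    pairwise_rows = numba.njit(nogil=True, cache=False)(_pairwise_rows)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    pairwise_rows = _pairwise_rows
    HAVE_NUMBA = False


def pack_csr(profiles) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate profiles into (scores, numbers, offsets, totals) arrays."""
    n = len(profiles)
    offsets = np.zeros(n + 1, dtype=np.int64)
    for i, p in enumerate(profiles):
        offsets[i + 1] = offsets[i] + p.magnitude
    scores = np.empty(int(offsets[-1]), dtype=np.uint64)
    numbers = np.empty(int(offsets[-1]), dtype=np.int64)
    totals = np.empty(n, dtype=np.int64)
    for i, p in enumerate(profiles):
        scores[offsets[i] : offsets[i + 1]] = p.scores.astype(np.uint64)
        numbers[offsets[i] : offsets[i + 1]] = p.numbers
        totals[i] = p.total
    return scores, numbers, offsets, totals
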