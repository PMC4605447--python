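"""Reading `.smi` compound libraries and writing tabular hit reports.

The `.smi` dialect accepted here is the de-facto standard: one record per
line, ``SMILES[<whitespace>ID]``, ``#`` comment lines and blank lines skipped.
SMILES tokens are restricted to printable ASCII (code points 33–126) because
score packing assumes one byte per character; strings are never chemically
validated — the whole method treats SMILES as plain text.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import SmilesFormatError

__all__ = ["Compound", "read_smi", "write_smi", "write_hits"]

HIT_HEADER = ("query_id", "db_id", "tanimoto")


@dataclass(frozen=True)
class Compound:
    """One library record: an identifier and a raw SMILES string.

    ``source_line`` is the 1-based line number of the record in the file it
    was read from (or its 1-based position for generated libraries).
    """

    id: str
    smiles: str
    source_line: int = 0

    def __len__(self) -> int:  # character count == LINGO length
        return len(self.smiles)


def _token_ok(token: str) -> bool:
    return all(33 <= ord(c) <= 126 for c in token)


def read_smi(path: str | Path, on_error: str = "abort") -> list[Compound]:
    """Read a `.smi` library, one compound per non-blank non-comment line.

    The first whitespace-delimited token of a line is the SMILES; the second,
    if present, is the identifier, otherwise the id defaults to ``L<line>``.
    A SMILES token containing whitespace-adjacent non-printable or non-ASCII
    characters raises :class:`SmilesFormatError` naming the line, or — with
    ``on_error="skip"`` — drops the line with a warning.  Duplicate ids are
    always an error; duplicate SMILES strings are allowed.
    """
    if on_error not in ("abort", "skip"):
        raise ValueError(f"on_error must be 'abort' or 'skip', got {on_error!r}")
    path = Path(path)
    compounds: list[Compound] = []
    seen_ids: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            smiles = tokens[0]
            if not _token_ok(smiles):
                msg = f"{path}:{lineno}: SMILES token contains non-printable or non-ASCII characters"
                if on_error == "abort":
                    raise SmilesFormatError(msg)
                warnings.warn(msg + " (line skipped)", stacklevel=2)
                continue
            cid = tokens[1] if len(tokens) > 1 else f"L{lineno}"
            if cid in seen_ids:
                raise SmilesFormatError(f"{path}:{lineno}: duplicate compound id {cid!r}")
            seen_ids.add(cid)
            compounds.append(Compound(id=cid, smiles=smiles, source_line=lineno))
    return compounds


def write_smi(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write compounds as ``SMILES<TAB>ID`` lines (inverse of :func:`read_smi`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c in compounds:
            fh.write(f"{c.smiles}\t{c.id}\n")


def write_hits(
    hits: Sequence[tuple[str, str, float]], path: str | Path
) -> None:
    """Write a hit report as a 3-column TSV.

    Rows are grouped by query (in first-appearance order of the query id),
    sorted within a query by descending coefficient with ties broken by
    database id ascending.  Coefficients are printed with 6 decimal places.
    """
    for _, _, coef in hits:
        if not 0.0 <= coef <= 1.0:
            raise ValueError(f"coefficient {coef} outside [0, 1]")
    order: dict[str, int] = {}
    for qid, _, _ in hits:
        order.setdefault(qid, len(order))
    ranked = sorted(hits, key=lambda h: (order[h[0]], -h[2], h[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(HIT_HEADER) + "\n")
        for qid, dbid, coef in ranked:
            fh.write(f"{qid}\t{dbid}\t{coef:.6f}\n")
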