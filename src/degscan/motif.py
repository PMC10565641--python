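"""Position-frequency matrices and degenerate consensus motifs.

A consensus motif is an ordered list of columns; each column is either a
residue *class* (an explicit subset of the 20 standard amino acids) or a
wildcard (no constraint).  The interchange notation is the bracket pattern
familiar from short-linear-motif work, e.g. ``[LP][LP][TS]P..[TSDE]`` for
the Cdc4 phosphodegron (CPD) recognised by FBXW7: phospho-acceptor S/T at
the '0' position, an invariant proline at '+1', and a phospho-mimetic or
acidic residue at '+4'.

Motif equality downstream is per-column SET equality, never string
equality: ``[TS]`` and ``[ST]`` denote the same class.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity / non-standard codes tolerated in protein sequences.  They
#: never satisfy an explicit residue class but do satisfy a wildcard.
AMBIGUITY_CODES = "XBZUO"

#: Sentinel column value meaning "no constraint".
WILDCARD = None

Column = Optional[frozenset]  # frozenset of residues, or WILDCARD


class PatternError(ValueError):
    """Malformed bracket-notation pattern."""


@dataclass(frozen=True)
class ConsensusMotif:
    """Degenerate sequence motif over the 20-letter amino-acid alphabet.

    Parameters
    ----------
    columns
        One entry per motif position: a ``frozenset`` of allowed residues,
        or ``None`` for a wildcard.
    zero_column
        1-based index of the phospho-acceptor ('0') column, if annotated.
    plus4_column
        1-based index of the '+4' column; must equal ``zero_column + 4``.
    """

    columns: tuple
    zero_column: Optional[int] = None
    plus4_column: Optional[int] = None

    def __post_init__(self):
        for i, col in enumerate(self.columns, start=1):
            if col is WILDCARD:
                continue
            if not col:
                raise ValueError(f"column {i}: empty residue class")
            bad = set(col) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(f"column {i}: non-standard residues {sorted(bad)}")
        if self.zero_column is not None:
            if not 1 <= self.zero_column <= len(self.columns):
                raise ValueError("zero_column outside motif")
            if self.plus4_column is not None:
                if self.plus4_column != self.zero_column + 4:
                    raise ValueError("plus4_column must equal zero_column + 4")
                if self.plus4_column > len(self.columns):
                    raise ValueError("plus4_column outside motif")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def length(self) -> int:
        return len(self.columns)

    def class_sizes(self) -> list:
        """Size of each column class (wildcard counts as the full 20)."""
        return [20 if c is WILDCARD else len(c) for c in self.columns]

    def matches_window(self, window: str) -> bool:
        """True iff ``window`` (length L) satisfies every column class.

        Ambiguity codes (X, B, Z, U, O) satisfy only wildcard columns.
        """
        if len(window) != len(self.columns):
            return False
        for res, col in zip(window, self.columns):
            if col is WILDCARD:
                continue
            if res not in col:
                return False
        return True

    def regex(self) -> str:
        """Regular-expression equivalent (one char class per column)."""
        parts = []
        for col in self.columns:
            if col is WILDCARD:
                parts.append(".")
            elif len(col) == 1:
                parts.append(next(iter(col)))
            else:
                parts.append("[" + "".join(sorted(col)) + "]")
        return "".join(parts)

    def set_equal(self, other: "ConsensusMotif") -> bool:
        """Column-wise set equality (ignores '0'/'+4' annotation)."""
        return self.columns == other.columns

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def to_document(self, provenance: str = "") -> dict:
        return {
            "pattern": serialize_pattern(self),
            "zero_column": self.zero_column,
            "plus4_column": self.plus4_column,
            "provenance": provenance,
        }

    def save(self, path, provenance: str = "") -> None:
        Path(path).write_text(json.dumps(self.to_document(provenance), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "ConsensusMotif":
        doc = json.loads(Path(path).read_text())
        return parse_pattern(doc["pattern"], zero_column=doc.get("zero_column"))


@dataclass
class PositionFrequencyMatrix:
    """Column-wise residue counts over an aligned set of fixed-length windows.

    ``counts`` has shape (L, 20), residues indexed alphabetically; every
    column sums to ``n_sequences``.
    """

    counts: np.ndarray
    n_sequences: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 20:
            raise ValueError("counts must have shape (L, 20)")
        if (self.counts < 0).any():
            raise ValueError("negative count")
        sums = self.counts.sum(axis=1)
        if not (sums == self.n_sequences).all():
            raise ValueError("every column must sum to n_sequences")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_sequences

    def column_counts(self, col: int) -> dict:
        """Residue → count for 1-based column ``col`` (zero counts omitted)."""
        row = self.counts[col - 1]
        return {AMINO_ACIDS[i]: int(c) for i, c in enumerate(row) if c}


def build_pfm(catalog) -> PositionFrequencyMatrix:
    """Tally column-wise residue counts over all catalog windows."""
    if len(catalog.instances) == 0:
        raise ValueError("cannot build a frequency matrix from an empty catalog")
    L = catalog.window_length
    counts = np.zeros((L, 20), dtype=np.int64)
    for inst in catalog.instances:
        for j, res in enumerate(inst.window_seq):
            counts[j, AA_INDEX[res]] += 1
    return PositionFrequencyMatrix(counts, len(catalog.instances))


def column_information(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> np.ndarray:
    """Per-column Shannon information content in bits.

    IC = log2(20) − H(column).  With the small-sample correction enabled
    the Miller–Madow style penalty (|A|−1)/(2·ln2·n) with |A| = 20 is
    subtracted and the result floored at zero.
    """
    freqs = pfm.frequencies()
    ic = np.empty(pfm.length)
    for j in range(pfm.length):
        p = freqs[j][freqs[j] > 0]
        h = -(p * np.log2(p)).sum()
        ic[j] = math.log2(20) - h
    if small_sample_correction:
        ic -= (20 - 1) / (2 * math.log(2) * pfm.n_sequences)
        ic = np.maximum(ic, 0.0)
    return ic


def derive_consensus(
    pfm: PositionFrequencyMatrix,
    include_threshold: float = 0.2,
    max_class: int = 4,
    zero_column: Optional[int] = None,
) -> ConsensusMotif:
    """Reduce a frequency matrix to a degenerate consensus.

    Per column the class is the set of residues with empirical frequency
    ≥ ``include_threshold``; an empty class, or one larger than
    ``max_class``, becomes a wildcard.  Deterministic and independent of
    instance order by construction.
    """
    if not 0 < include_threshold <= 1:
        raise ValueError("include_threshold must lie in (0, 1]")
    freqs = pfm.frequencies()
    cols = []
    for j in range(pfm.length):
        members = frozenset(
            AMINO_ACIDS[i] for i in range(20) if freqs[j, i] >= include_threshold
        )
        if not members or len(members) > max_class:
            cols.append(WILDCARD)
        else:
            cols.append(members)
    plus4 = None
    if zero_column is not None:
        zc = cols[zero_column - 1]
        if zc is not WILDCARD and not zc <= {"S", "T"}:
            logger.warning(
                "zero-column class %s is not a subset of {S, T}; "
                "catalog may not be phosphodegron-like",
                sorted(zc),
            )
        if zero_column + 4 <= pfm.length:
            plus4 = zero_column + 4
    return ConsensusMotif(tuple(cols), zero_column=zero_column, plus4_column=plus4)


_TOKEN = re.compile(r"\.|[A-Z]|\[([A-Z]+)\]")


def parse_pattern(text: str, zero_column: Optional[int] = None) -> ConsensusMotif:
    """Parse bracket notation ('.' wildcard, '[...]' class, bare letter).

    When ``zero_column`` is not given it defaults to the first column whose
    class is a subset of {S, T} and is immediately followed by an
    invariant-P column — the phospho-acceptor/+1-proline arrangement that
    defines a CPD.  If no such column exists the motif is left
    unannotated.
    """
    cols = []
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == ".":
            cols.append(WILDCARD)
            pos += 1
        elif ch == "[":
            end = text.find("]", pos)
            if end == -1:
                raise PatternError(f"unclosed '[' at offset {pos}")
            body = text[pos + 1 : end]
            if not body:
                raise PatternError(f"empty class at offset {pos}")
            bad = set(body) - set(AMINO_ACIDS)
            if bad:
                raise PatternError(
                    f"illegal residue {sorted(bad)} in class at offset {pos}"
                )
            cols.append(frozenset(body))
            pos = end + 1
        elif ch in AMINO_ACIDS:
            cols.append(frozenset(ch))
            pos += 1
        elif ch == "]":
            raise PatternError(f"unmatched ']' at offset {pos}")
        else:
            raise PatternError(f"illegal character {ch!r} at offset {pos}")
    if not cols:
        raise PatternError("empty pattern")

    if zero_column is None:
        for i in range(len(cols) - 1):
            c, nxt = cols[i], cols[i + 1]
            if c is not WILDCARD and c <= {"S", "T"} and nxt == frozenset("P"):
                zero_column = i + 1
                break
    plus4 = None
    if zero_column is not None and zero_column + 4 <= len(cols):
        plus4 = zero_column + 4
    return ConsensusMotif(tuple(cols), zero_column=zero_column, plus4_column=plus4)


def serialize_pattern(
    motif: ConsensusMotif,
    ordering: str = "alphabetical",
    pfm: Optional[PositionFrequencyMatrix] = None,
) -> str:
    """Canonical bracket notation.

    ``ordering="alphabetical"`` (default) sorts class members; with
    ``"frequency"`` members are ordered by descending count in the
    supplied frequency matrix (ties alphabetical).
    """
    if ordering not in ("alphabetical", "frequency"):
        raise ValueError(f"unknown ordering {ordering!r}")
    if ordering == "frequency" and pfm is None:
        raise ValueError("frequency ordering requires a frequency matrix")
    parts = []
    for j, col in enumerate(motif.columns):
        if col is WILDCARD:
            parts.append(".")
        elif len(col) == 1:
            parts.append(next(iter(col)))
        else:
            if ordering == "alphabetical":
                members = sorted(col)
            else:
                members = sorted(col, key=lambda aa: (-pfm.counts[j, AA_INDEX[aa]], aa))
            parts.append("[" + "".join(members) + "]")
    return "".join(parts)


#: The validated CPD consensus used for the proteome search.
CPD_PATTERN = "[LP][LP][TS]P..[TSDE]"


def cpd_motif() -> ConsensusMotif:
    """The reference CPD consensus motif (zero column 3, '+4' column 7)."""
    return parse_pattern(CPD_PATTERN)
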