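"""Cross-species conservation of a matched degron window.

Works on a user-supplied multiple sequence alignment (aligned FASTA, '-'
gaps) of orthologs for one gene.  Two transparent scores are computed for
a reference window:

* **motif retention** — the fraction of non-reference members whose
  aligned window still satisfies the motif's residue classes.  A gap
  never satisfies any column, wildcard included: an absent residue is no
  evidence of conservation.
* **per-column identity** — the fraction of non-reference members whose
  aligned residue equals the reference residue, gaps counting as
  mismatches.

Alignment construction (ortholog retrieval, MSA) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO

from .motif import ConsensusMotif, WILDCARD


@dataclass
class OrthologFamily:
    """Aligned ortholog sequences for one gene.

    ``members`` maps sequence id (species tag or accession) to its aligned
    sequence; insertion order is preserved.  ``reference_id`` names the
    scanned (e.g. human) protein's row.
    """

    gene_symbol: str
    reference_id: str
    members: Dict[str, str]

    def __post_init__(self):
        if self.reference_id not in self.members:
            raise ValueError(f"reference {self.reference_id!r} not among members")
        lengths = {len(s) for s in self.members.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences differ in length")

    @property
    def reference(self) -> str:
        return self.members[self.reference_id]

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ConservationResult:
    gene_symbol: str
    ref_window_start: int
    motif_retention: float
    column_identity: Tuple[float, ...]
    n_members: int


def read_alignment_fasta(path, reference_id: str, gene_symbol: str = "") -> OrthologFamily:
    """Read one aligned-FASTA family (first token of each header is the id)."""
    members: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in members:
            raise ValueError(f"{path}: duplicate member id {rec.id!r}")
        members[rec.id] = str(rec.seq).upper()
    if not members:
        raise ValueError(f"{path}: empty alignment")
    return OrthologFamily(
        gene_symbol=gene_symbol or reference_id,
        reference_id=reference_id,
        members=members,
    )


def map_window_to_alignment(family: OrthologFamily, ref_start: int, L: int) -> List[int]:
    """Alignment columns (1-based) holding the reference window's residues.

    ``ref_start`` is a 1-based *ungapped* position in the reference row;
    reference gap columns are skipped.
    """
    if ref_start < 1 or L < 1:
        raise ValueError("ref_start and L must be ≥ 1")
    cols = []
    ungapped = 0
    for aln_col, ch in enumerate(family.reference, start=1):
        if ch == "-":
            continue
        ungapped += 1
        if ungapped >= ref_start:
            cols.append(aln_col)
            if len(cols) == L:
                return cols
    raise ValueError(
        f"window [{ref_start}, {ref_start + L - 1}] exceeds reference "
        f"ungapped length {ungapped}"
    )


def score_conservation(
    motif: ConsensusMotif, family: OrthologFamily, ref_start: int
) -> ConservationResult:
    """Score motif retention and per-column identity of a reference window."""
    if family.n_members < 2:
        raise ValueError("family needs at least two members to compare")
    L = motif.length
    cols = map_window_to_alignment(family, ref_start, L)
    ref_window = [family.reference[c - 1] for c in cols]

    others = [
        seq for mid, seq in family.members.items() if mid != family.reference_id
    ]
    n_other = len(others)
    retained = 0
    identity = np.zeros(L)
    for seq in others:
        window = [seq[c - 1] for c in cols]
        ok = True
        for res, col in zip(window, motif.columns):
            if res == "-":
                ok = False  # gaps never satisfy any column, wildcard included
                break
            if col is not WILDCARD and res not in col:
                ok = False
                break
        if ok:
            retained += 1
        for j in range(L):
            if window[j] != "-" and window[j] == ref_window[j]:
                identity[j] += 1
    return ConservationResult(
        gene_symbol=family.gene_symbol,
        ref_window_start=ref_start,
        motif_retention=retained / n_other,
        column_identity=tuple(identity / n_other),
        n_members=family.n_members,
    )


#: Default repo convention for calling a window "highly conserved".
HIGH_CONSERVATION_THRESHOLD = 0.8


def write_conservation_tsv(results, path) -> None:
    lines = ["\t".join(("gene_symbol", "ref_window_start", "motif_retention",
                        "n_members", "column_identity"))]
    for r in results:
        lines.append(
            "\t".join(
                (
                    r.gene_symbol,
                    str(r.ref_window_start),
                    f"{r.motif_retention:.6g}",
                    str(r.n_members),
                    ",".join(f"{x:.6g}" for x in r.column_identity),
                )
            )
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
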