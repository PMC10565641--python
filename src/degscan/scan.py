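"""Proteome FASTA input and exhaustive motif scanning.

The scan is a hard-class match: every window of length L whose residues
satisfy all column classes is reported, overlapping hits included — no
scoring, no suppression.  Coordinates are 1-based inclusive throughout,
matching protein-database convention.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional

from Bio import SeqIO

from .motif import AMBIGUITY_CODES, AMINO_ACIDS, ConsensusMotif

logger = logging.getLogger(__name__)

_VALID_CHARS = set(AMINO_ACIDS) | set(AMBIGUITY_CODES)
_GN_RE = re.compile(r"\bGN=(\S+)")


class FastaError(ValueError):
    """Invalid FASTA record."""


@dataclass(frozen=True)
class ProteinRecord:
    """One canonical protein sequence."""

    protein_id: str
    gene_symbol: str
    sequence: str


@dataclass(frozen=True)
class CpdMatch:
    """One motif hit.

    ``zero_pos``/``plus4_pos`` are the protein coordinates of the motif's
    '0' (phospho-acceptor) and '+4' columns; ``None`` when the motif
    carries no such annotation.
    """

    protein_id: str
    gene_symbol: str
    start_pos: int
    match_seq: str
    zero_pos: Optional[int]
    plus4_pos: Optional[int]


@dataclass
class CandidateTable:
    """All matches of one scan plus the per-gene aggregation."""

    matches: List[CpdMatch]
    per_gene: Dict[str, int]
    candidate_genes: List[str]

    @classmethod
    def from_matches(cls, matches: List[CpdMatch]) -> "CandidateTable":
        per_gene = Counter(m.gene_symbol for m in matches)
        return cls(
            matches=list(matches),
            per_gene=dict(per_gene),
            candidate_genes=sorted(per_gene),
        )


def _sanitize(seq: str, record_id: str) -> str:
    seq = str(seq).upper().rstrip("*")
    if not seq:
        raise FastaError(f"record {record_id!r}: empty sequence")
    if "*" in seq:
        raise FastaError(f"record {record_id!r}: internal stop codon")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise FastaError(f"record {record_id!r}: illegal character(s) {sorted(bad)}")
    return seq


def _parse_header(record, dialect: str):
    if dialect == "uniprot":
        parts = record.id.split("|")
        protein_id = parts[1] if len(parts) >= 3 else record.id
        m = _GN_RE.search(record.description)
        gene = m.group(1) if m else ""
    elif dialect == "plain":
        protein_id = record.id
        gene = record.id
    else:
        raise ValueError(f"unknown header dialect {dialect!r}")
    return protein_id, gene


def read_fasta(path, header_dialect: str = "plain") -> List[ProteinRecord]:
    """Read a protein FASTA.

    ``uniprot`` dialect parses ``db|ACC|NAME`` ids and a ``GN=`` gene
    token; ``plain`` uses the first whitespace-delimited header token as
    both protein id and gene symbol.  Trailing '*' is stripped; a record
    with an internal '*', an empty sequence or a duplicated id is an
    error.  A missing gene symbol falls back to the protein id.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        protein_id, gene = _parse_header(rec, header_dialect)
        if protein_id in seen:
            raise FastaError(f"duplicate protein_id {protein_id!r}")
        seen.add(protein_id)
        if not gene:
            logger.warning(
                "record %s has no gene symbol; using protein_id as aggregation key",
                protein_id,
            )
            gene = protein_id
        records.append(ProteinRecord(protein_id, gene, _sanitize(rec.seq, protein_id)))
    return records


def scan_protein(motif: ConsensusMotif, record: ProteinRecord) -> List[CpdMatch]:
    """Report every (possibly overlapping) motif match in one protein.

    Implemented as a compiled regular expression inside a lookahead so
    overlapping windows are all found; sorted by start position.
    """
    pattern = re.compile("(?=(" + motif.regex() + "))")
    out = []
    for m in pattern.finditer(record.sequence):
        start = m.start() + 1  # 1-based
        zero = plus4 = None
        if motif.zero_column is not None:
            zero = start + motif.zero_column - 1
            if motif.plus4_column is not None:
                plus4 = zero + 4
        out.append(
            CpdMatch(
                protein_id=record.protein_id,
                gene_symbol=record.gene_symbol,
                start_pos=start,
                match_seq=m.group(1),
                zero_pos=zero,
                plus4_pos=plus4,
            )
        )
    return out


def scan_proteome(
    motif: ConsensusMotif, records: Iterable[ProteinRecord]
) -> CandidateTable:
    """Scan every protein; aggregate match counts per gene symbol.

    Output order is protein input order, then start position.
    """
    records = list(records)
    if not records:
        raise ValueError("no protein records to scan")
    matches: List[CpdMatch] = []
    for rec in records:
        matches.extend(scan_protein(motif, rec))
    return CandidateTable.from_matches(matches)


_TSV_HEADER = (
    "gene_symbol",
    "protein_id",
    "n_matches_in_gene",
    "start_pos",
    "zero_pos",
    "plus4_pos",
    "match_seq",
)


def write_candidates_tsv(table: CandidateTable, path) -> None:
    """One row per match; ``n_matches_in_gene`` repeats the per-gene total."""
    lines = ["\t".join(_TSV_HEADER)]
    for m in table.matches:
        lines.append(
            "\t".join(
                (
                    m.gene_symbol,
                    m.protein_id,
                    str(table.per_gene[m.gene_symbol]),
                    str(m.start_pos),
                    "" if m.zero_pos is None else str(m.zero_pos),
                    "" if m.plus4_pos is None else str(m.plus4_pos),
                    m.match_seq,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_candidates_tsv(path) -> CandidateTable:
    """Inverse of :func:`write_candidates_tsv`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    if tuple(header) != _TSV_HEADER:
        raise ValueError(f"{path}: unexpected header {header}")
    matches = []
    for line in lines[1:]:
        if not line.strip():
            continue
        gene, pid, _n, start, zero, plus4, seq = line.split("\t")
        matches.append(
            CpdMatch(
                protein_id=pid,
                gene_symbol=gene,
                start_pos=int(start),
                match_seq=seq,
                zero_pos=int(zero) if zero else None,
                plus4_pos=int(plus4) if plus4 else None,
            )
        )
    return CandidateTable.from_matches(matches)
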