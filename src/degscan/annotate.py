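"""Phosphosite annotation of motif matches and gene-set overlaps.

Matches are cross-referenced with a table of known phosphorylation sites
at their '0' (phospho-acceptor) and '+4' positions.  A site only counts
when its recorded residue agrees with the actual sequence residue at that
position — position alone is not accepted, guarding against
coordinate-version drift between the site table and the scanned proteome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .motif import AMINO_ACIDS
from .scan import CandidateTable, CpdMatch, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhosphoSite:
    protein_id: str
    position: int  # 1-based
    residue: str


class PhosphoSiteTable:
    """Set of known phosphosites keyed by (protein_id, position)."""

    def __init__(self, sites: Iterable[PhosphoSite]):
        self.sites: List[PhosphoSite] = []
        self._index: Dict[Tuple[str, int], str] = {}
        for s in sites:
            if s.position < 1:
                raise ValueError(f"site {s}: position must be ≥ 1")
            if s.residue not in AMINO_ACIDS:
                raise ValueError(f"site {s}: residue {s.residue!r} not a standard amino acid")
            self.sites.append(s)
            self._index[(s.protein_id, s.position)] = s.residue

    def residue_at(self, protein_id: str, position: int) -> Optional[str]:
        return self._index.get((protein_id, position))

    def __len__(self) -> int:
        return len(self.sites)


def read_phosphosites(path) -> PhosphoSiteTable:
    """Read a TSV with header columns protein_id, position, residue."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = None
    sites = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = fields
            for req in ("protein_id", "position", "residue"):
                if req not in header:
                    raise ValueError(f"{path}: header lacks column {req!r}")
            continue
        row = dict(zip(header, fields))
        sites.append(
            PhosphoSite(row["protein_id"], int(row["position"]), row["residue"].upper())
        )
    return PhosphoSiteTable(sites)


@dataclass(frozen=True)
class AnnotatedMatch:
    match: CpdMatch
    phospho_zero: bool
    phospho_plus4: bool


def annotate_phospho(
    table: CandidateTable,
    sites: PhosphoSiteTable,
    records: Iterable[ProteinRecord],
) -> List[AnnotatedMatch]:
    """Flag each match whose '0'/'+4' position is a known phosphosite.

    A site is accepted only when its recorded residue matches the actual
    sequence residue; disagreements are logged and treated as absent.
    Site protein ids that do not resolve against the records are logged
    once and ignored.  Match coordinates and counts are never altered.
    """
    seq_by_id = {r.protein_id: r.sequence for r in records}
    unresolved = {s.protein_id for s in sites.sites} - set(seq_by_id)
    if unresolved:
        logger.warning(
            "%d phosphosite protein id(s) not in the scanned records (ignored): %s",
            len(unresolved), ", ".join(sorted(unresolved)[:5]),
        )

    def _flag(protein_id: str, pos: Optional[int]) -> bool:
        if pos is None:
            return False
        site_res = sites.residue_at(protein_id, pos)
        if site_res is None:
            return False
        seq = seq_by_id.get(protein_id)
        if seq is None or pos > len(seq):
            return False
        if seq[pos - 1] != site_res:
            logger.warning(
                "site (%s, %d, %s) disagrees with sequence residue %s; ignored",
                protein_id, pos, site_res, seq[pos - 1],
            )
            return False
        return True

    return [
        AnnotatedMatch(
            match=m,
            phospho_zero=_flag(m.protein_id, m.zero_pos),
            phospho_plus4=_flag(m.protein_id, m.plus4_pos),
        )
        for m in table.matches
    ]


def write_annotated_tsv(annotated: List[AnnotatedMatch], path) -> None:
    header = ("gene_symbol", "protein_id", "start_pos", "zero_pos", "plus4_pos",
              "match_seq", "phospho_zero", "phospho_plus4")
    lines = ["\t".join(header)]
    for a in annotated:
        m = a.match
        lines.append("\t".join((
            m.gene_symbol, m.protein_id, str(m.start_pos),
            "" if m.zero_pos is None else str(m.zero_pos),
            "" if m.plus4_pos is None else str(m.plus4_pos),
            m.match_seq, str(a.phospho_zero), str(a.phospho_plus4),
        )))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def read_gmt(path) -> Dict[str, List[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: Dict[str, List[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: GMT line needs name, description, members")
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name {name!r}")
        sets[name] = [g.strip() for g in fields[2:] if g.strip()]
    return sets


def write_gmt(sets: Dict[str, List[str]], path, description: str = "synthetic") -> None:
    lines = ["\t".join([name, description] + list(members)) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def venn_overlap(candidate_genes: Iterable[str], gene_set: Iterable[str]) -> Dict[str, int]:
    """Exact set-intersection counts between candidates and one gene set.

    Both sides are uppercased and deduplicated before comparison.
    Returns ``{"both", "candidates_only", "set_only"}``.
    """
    cand = {g.upper() for g in candidate_genes}
    gset = {g.upper() for g in gene_set}
    both = cand & gset
    return {
        "both": len(both),
        "candidates_only": len(cand - gset),
        "set_only": len(gset - cand),
    }
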