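"""Catalog of experimentally validated degron windows.

Each instance is a fixed-length peptide window aligned on the
phospho-acceptor ('0') residue, taken from a substrate with published
evidence of E3-ligase recognition.  The catalog is the training input for
the position-frequency matrix and consensus derivation; curation itself
(literature search) is upstream of this package.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

from .motif import AMINO_ACIDS

logger = logging.getLogger(__name__)

_COLUMNS = ("substrate_name", "window_seq", "zero_protein_pos", "source_ref")


class CatalogError(ValueError):
    """Malformed or invalid degron table."""


@dataclass(frozen=True)
class DegronInstance:
    """One validated degron window.

    ``zero_protein_pos`` is the 1-based position of the phospho-acceptor
    in the source protein, when known.
    """

    substrate_name: str
    window_seq: str
    zero_protein_pos: Optional[int] = None
    source_ref: str = ""


@dataclass
class DegronCatalog:
    """Ordered set of degron instances sharing one window geometry."""

    instances: List[DegronInstance]
    window_length: int
    zero_column: int

    def __post_init__(self):
        if not 1 <= self.zero_column <= self.window_length:
            raise CatalogError("zero_column outside window")
        for inst in self.instances:
            self._validate(inst)
        dup = [w for w, c in Counter(i.window_seq for i in self.instances).items() if c > 1]
        if dup:
            logger.warning(
                "duplicate degron windows (legitimately up-weight the "
                "frequency matrix): %s", ", ".join(sorted(dup))
            )

    def _validate(self, inst: DegronInstance) -> None:
        if len(inst.window_seq) != self.window_length:
            raise CatalogError(
                f"instance {inst.substrate_name!r}: window {inst.window_seq!r} "
                f"has length {len(inst.window_seq)}, expected {self.window_length}"
            )
        bad = set(inst.window_seq) - set(AMINO_ACIDS)
        if bad:
            raise CatalogError(
                f"instance {inst.substrate_name!r}: illegal residue(s) {sorted(bad)}"
            )
        zero_res = inst.window_seq[self.zero_column - 1]
        if zero_res not in "ST":
            raise CatalogError(
                f"instance {inst.substrate_name!r}: column-{self.zero_column} "
                f"residue {zero_res!r} not in {{S, T}}"
            )

    def __len__(self) -> int:
        return len(self.instances)


def read_degron_table(path, window_length: int, zero_column: int) -> DegronCatalog:
    """Read a tab-delimited degron table.

    Required header column ``window_seq``; recognised optional columns
    ``substrate_name``, ``zero_protein_pos``, ``source_ref``.  Lines
    starting with '#' and blank lines are ignored.  Row order is
    preserved.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = None
    instances = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            if "window_seq" not in header:
                raise CatalogError(f"{path}: header lacks required column 'window_seq'")
            unknown = set(header) - set(_COLUMNS)
            if unknown:
                raise CatalogError(f"{path}: unknown column(s) {sorted(unknown)}")
            continue
        if len(fields) > len(header):
            raise CatalogError(f"{path}: line {lineno}: more fields than header columns")
        row = dict(zip(header, (f.strip() for f in fields)))
        if not row.get("window_seq"):
            raise CatalogError(f"{path}: line {lineno}: missing window_seq")
        zpos = row.get("zero_protein_pos") or None
        if zpos is not None:
            try:
                zpos = int(zpos)
            except ValueError:
                raise CatalogError(
                    f"{path}: line {lineno}: zero_protein_pos {zpos!r} is not an integer"
                ) from None
            if zpos < 1:
                raise CatalogError(f"{path}: line {lineno}: zero_protein_pos must be ≥ 1")
        instances.append(
            DegronInstance(
                substrate_name=row.get("substrate_name", ""),
                window_seq=row["window_seq"].upper(),
                zero_protein_pos=zpos,
                source_ref=row.get("source_ref", ""),
            )
        )
    if header is None:
        raise CatalogError(f"{path}: empty table")
    return DegronCatalog(instances, window_length=window_length, zero_column=zero_column)


def load_synthetic_catalog() -> DegronCatalog:
    """The packaged SYNTHETIC degron catalog.

    Twelve constructed windows whose column frequencies reduce (at the
    default derivation settings) to the CPD consensus
    ``[LP][LP][TS]P..[TSDE]``.  A stand-in for a curated table of
    validated degrons, not biological ground truth.
    """
    from importlib.resources import files

    path = files("degscan") / "data" / "degrons_synthetic.tsv"
    return read_degron_table(path, window_length=7, zero_column=3)


def write_degron_table(catalog: DegronCatalog, path) -> None:
    """Write the catalog back to TSV (round-trips with read_degron_table)."""
    out = ["\t".join(_COLUMNS)]
    for inst in catalog.instances:
        out.append(
            "\t".join(
                (
                    inst.substrate_name,
                    inst.window_seq,
                    "" if inst.zero_protein_pos is None else str(inst.zero_protein_pos),
                    inst.source_ref,
                )
            )
        )
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
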