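"""Synthetic inputs for the whole pipeline.

Every generator is a pure function of its arguments and a single integer
seed: background proteomes with motif-matching windows implanted at
recorded positions, gapless ortholog families with a per-site
substitution probability, phosphosite tables, and gene-set collections
with one deliberately enriched ("spiked") set.  These emulate the shapes
of a curated proteome, an ortholog alignment resource, a phosphosite
database extract and a GO-BP style collection — not their biological
content; see the methods note for what that does and does not buy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .motif import AMINO_ACIDS, ConsensusMotif, WILDCARD
from .scan import ProteinRecord

logger = logging.getLogger(__name__)

_AA_ARR = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: Bounded redraws per protein before deterministic masking kicks in.
CLEAN_RETRY_LIMIT = 100


@dataclass(frozen=True)
class ImplantRecord:
    protein_id: str
    start_pos: int  # 1-based
    implant_seq: str


def _as_background(background) -> np.ndarray:
    if background is None:
        return np.full(20, 1 / 20)
    if isinstance(background, dict):
        vec = np.zeros(20)
        for aa, p in background.items():
            vec[AMINO_ACIDS.index(aa)] = p
    else:
        vec = np.asarray(background, dtype=float)
    if vec.shape != (20,) or (vec < 0).any() or not np.isclose(vec.sum(), 1.0):
        raise ValueError("background must be a distribution over the 20 residues")
    return vec / vec.sum()


def expected_match_rate(motif: ConsensusMotif, background=None) -> float:
    """Analytic per-window match probability under an i.i.d. background.

    Product over columns of the background mass of each class; wildcard
    columns contribute 1.
    """
    vec = _as_background(background)
    rate = 1.0
    for col in motif.columns:
        if col is WILDCARD:
            continue
        rate *= sum(vec[AMINO_ACIDS.index(aa)] for aa in col)
    return rate


def _draw_motif_window(motif: ConsensusMotif, rng: np.random.Generator) -> str:
    """Uniform draw from the motif's satisfying sequences: independent
    uniform choice per column from its class (wildcard = full alphabet)."""
    out = []
    for col in motif.columns:
        choices = AMINO_ACIDS if col is WILDCARD else sorted(col)
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _draw_sequence(length: int, bg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_AA_ARR, size=length, p=bg)


def _mask_options(motif: ConsensusMotif) -> List[Tuple[int, str]]:
    """Candidate (column offset, replacement residue) pairs that destroy a
    match, most-constrained columns first."""
    opts = []
    for j, col in enumerate(motif.columns):
        if col is WILDCARD:
            continue
        outside = [aa for aa in AMINO_ACIDS if aa not in col]
        opts.append((len(col), j, outside[0]))
    if not opts:
        raise ValueError("cannot mask matches of an all-wildcard motif")
    opts.sort()
    return [(j, res) for _, j, res in opts]


def gen_proteome(
    n_proteins: int,
    length: Union[int, Tuple[int, int]],
    seed: int,
    background=None,
    motif: Optional[ConsensusMotif] = None,
    n_implants: int = 0,
    clean_background: bool = False,
) -> Tuple[List[ProteinRecord], List[ImplantRecord]]:
    """Draw a synthetic proteome, optionally implanting motif windows.

    Residues are i.i.d. from ``background`` (default uniform).  With
    ``clean_background`` any accidental motif match outside implant
    positions triggers a redraw of the protein (implants re-written at
    the same positions); after ``CLEAN_RETRY_LIMIT`` redraws the
    remaining accidental matches are destroyed deterministically by
    substituting the most-constrained column's residue with one outside
    its class.  Implant positions are non-overlapping within a protein.
    Fully reproducible from the seed.
    """
    if n_implants and motif is None:
        raise ValueError("implants require a motif")
    if clean_background and motif is None:
        raise ValueError("clean_background requires a motif")
    bg = _as_background(background)
    rng = np.random.default_rng(seed)
    if isinstance(length, int):
        lengths = [length] * n_proteins
    else:
        lo, hi = length
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_proteins)]

    L = motif.length if motif is not None else 0
    # allocate implants to proteins with room
    implant_plan: Dict[int, List[int]] = {i: [] for i in range(n_proteins)}
    for _ in range(n_implants):
        placed = False
        for _attempt in range(1000):
            i = int(rng.integers(n_proteins))
            if lengths[i] < L:
                continue
            start = int(rng.integers(1, lengths[i] - L + 2))  # 1-based
            if all(abs(start - s) >= L for s in implant_plan[i]):
                implant_plan[i].append(start)
                placed = True
                break
        if not placed:
            raise ValueError("could not place implants: proteins too short or too full")

    pattern = re.compile("(?=(" + motif.regex() + "))") if motif is not None else None
    records: List[ProteinRecord] = []
    truth: List[ImplantRecord] = []
    for i in range(n_proteins):
        pid = f"SYN{i:04d}"
        starts = sorted(implant_plan[i])

        def _compose() -> Tuple[str, List[str]]:
            arr = _draw_sequence(lengths[i], bg, rng)
            seqs = []
            for s in starts:
                w = _draw_motif_window(motif, rng)
                arr[s - 1 : s - 1 + L] = np.frombuffer(w.encode(), dtype=np.uint8)
                seqs.append(w)
            return arr.tobytes().decode(), seqs

        seq, implant_seqs = _compose()
        if clean_background:
            def _accidental(s: str) -> List[int]:
                return [m.start() + 1 for m in pattern.finditer(s)
                        if m.start() + 1 not in starts]

            retries = 0
            while _accidental(seq) and retries < CLEAN_RETRY_LIMIT:
                seq, implant_seqs = _compose()
                retries += 1
            stray = _accidental(seq)
            if stray:
                logger.info(
                    "protein %s: masking %d accidental match(es) after %d redraws",
                    pid, len(stray), retries,
                )
                implant_sites = {
                    p for s in starts for p in range(s, s + L)
                }
                options = _mask_options(motif)
                chars = list(seq)
                while stray:
                    for s in stray:
                        for off, res in options:
                            if s + off not in implant_sites:
                                chars[s - 1 + off] = res
                                break
                        else:  # fully inside implants: cannot happen for
                            raise RuntimeError(  # motifs with >1 constrained column
                                f"unmaskable accidental match at {pid}:{s}"
                            )
                    seq = "".join(chars)
                    stray = _accidental(seq)
        records.append(ProteinRecord(pid, f"G{pid}", seq))
        for s, w in zip(starts, implant_seqs):
            truth.append(ImplantRecord(pid, s, w))
    return records, truth


def verify_implants(records: Sequence[ProteinRecord], truth: Sequence[ImplantRecord]) -> bool:
    """True iff every truth row's implant_seq sits at its recorded position."""
    seq_by_id = {r.protein_id: r.sequence for r in records}
    return all(
        seq_by_id[t.protein_id][t.start_pos - 1 : t.start_pos - 1 + len(t.implant_seq)]
        == t.implant_seq
        for t in truth
    )


def write_proteome_fasta(records: Sequence[ProteinRecord], path) -> None:
    lines = []
    for r in records:
        lines.append(f">{r.protein_id} GN={r.gene_symbol}")
        for i in range(0, len(r.sequence), 60):
            lines.append(r.sequence[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_implant_truth_tsv(truth: Sequence[ImplantRecord], path) -> None:
    lines = ["protein_id\tstart_pos\timplant_seq"]
    lines += [f"{t.protein_id}\t{t.start_pos}\t{t.implant_seq}" for t in truth]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ----------------------------------------------------------------------
# ortholog families
# ----------------------------------------------------------------------

def gen_ortholog_family(
    reference: ProteinRecord,
    n_orthologs: int,
    sub_prob: float,
    seed: int,
    preserve_window: Optional[Tuple[int, int]] = None,
):
    """Gapless identity-aligned family: each ortholog mutates each site
    independently with probability ``sub_prob`` to a uniformly chosen
    *different* residue; ``preserve_window=(start, L)`` (1-based) skips
    mutation inside that window."""
    from .conserve import OrthologFamily

    if not 0 <= sub_prob <= 1:
        raise ValueError("sub_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ref = reference.sequence
    n_sites = len(ref)
    protected = np.zeros(n_sites, dtype=bool)
    if preserve_window is not None:
        start, L = preserve_window
        protected[start - 1 : start - 1 + L] = True
    members = {reference.protein_id: ref}
    for k in range(n_orthologs):
        mutate = (rng.random(n_sites) < sub_prob) & ~protected
        chars = list(ref)
        for idx in np.nonzero(mutate)[0]:
            alternatives = [aa for aa in AMINO_ACIDS if aa != ref[idx]]
            chars[idx] = alternatives[rng.integers(19)]
        members[f"ortho{k:03d}"] = "".join(chars)
    return OrthologFamily(
        gene_symbol=reference.gene_symbol,
        reference_id=reference.protein_id,
        members=members,
    )


# ----------------------------------------------------------------------
# phosphosites
# ----------------------------------------------------------------------

def gen_phosphosites(
    records: Sequence[ProteinRecord],
    positions: Iterable[Tuple[str, int]],
):
    """Phosphosite table for the given (protein_id, position) pairs,
    residues read off the actual sequences (so they always agree)."""
    from .annotate import PhosphoSite, PhosphoSiteTable

    seq_by_id = {r.protein_id: r.sequence for r in records}
    sites = []
    for pid, pos in positions:
        seq = seq_by_id[pid]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} outside {pid}")
        sites.append(PhosphoSite(pid, pos, seq[pos - 1]))
    return PhosphoSiteTable(sites)


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def gen_genesets(
    universe: Sequence[str],
    n_sets: int,
    set_size: Union[int, Tuple[int, int]],
    seed: int,
    spiked: Optional[Tuple[int, int, Sequence[str]]] = None,
) -> Tuple[Dict[str, List[str]], Optional[str]]:
    """Null gene sets plus an optional spiked (truly enriched) set.

    Null sets are uniform draws without replacement from the universe.
    ``spiked=(size, overlap, candidates)`` builds one extra set of
    ``size`` genes of which exactly ``overlap`` come from ``candidates``
    and the rest from non-candidates.  Returns (sets, spiked_set_name).
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: Dict[str, List[str]] = {}
    for i in range(n_sets):
        size = set_size if isinstance(set_size, int) else int(
            rng.integers(set_size[0], set_size[1] + 1)
        )
        if size > len(universe):
            raise ValueError("set size exceeds universe")
        idx = rng.choice(len(universe), size=size, replace=False)
        sets[f"NULL{i:03d}"] = [universe[j] for j in sorted(idx)]
    spiked_name = None
    if spiked is not None:
        size, overlap, candidates = spiked
        cand = [g for g in universe if g in set(candidates)]
        non_cand = [g for g in universe if g not in set(candidates)]
        if overlap > len(cand) or size - overlap > len(non_cand) or overlap > size:
            raise ValueError("impossible spiked-set geometry")
        members = [cand[j] for j in rng.choice(len(cand), size=overlap, replace=False)]
        members += [
            non_cand[j]
            for j in rng.choice(len(non_cand), size=size - overlap, replace=False)
        ]
        spiked_name = "SPIKED"
        sets[spiked_name] = sorted(members)
    return sets, spiked_name
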