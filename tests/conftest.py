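import numpy as np
import pytest

from degscan.motif import AMINO_ACIDS, WILDCARD, ConsensusMotif, cpd_motif


@pytest.fixture
def cpd():
    """The reference CPD consensus [LP][LP][TS]P..[TSDE]."""
    return cpd_motif()


def naive_scan(motif, sequence):
    """Independent brute-force scan oracle.

    Enumerates every window and tests naive set membership per column;
    wildcard accepts anything.  Returns (1-based start, window) pairs.
    """
    L = len(motif.columns)
    hits = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        ok = True
        for res, col in zip(window, motif.columns):
            if col is None:  # wildcard
                continue
            if res not in col:
                ok = False
                break
        if ok:
            hits.append((i + 1, window))
    return hits


def random_motif(rng, max_len=8):
    """Random motif: per column wildcard (p=.3), singleton, or small class."""
    L = int(rng.integers(1, max_len + 1))
    cols = []
    for _ in range(L):
        u = rng.random()
        if u < 0.3:
            cols.append(WILDCARD)
        else:
            size = int(rng.integers(1, 5))
            idx = rng.choice(20, size=size, replace=False)
            cols.append(frozenset(AMINO_ACIDS[i] for i in idx))
    return ConsensusMotif(tuple(cols))


def random_sequence(rng, length):
    idx = rng.integers(0, 20, size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)
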