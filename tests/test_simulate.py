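import math

import numpy as np
import pytest

from degscan.conserve import score_conservation
from degscan.motif import ConsensusMotif, parse_pattern
from degscan.scan import ProteinRecord, scan_proteome
from degscan.simulate import (expected_match_rate, gen_genesets,
                              gen_ortholog_family, gen_phosphosites,
                              gen_proteome, verify_implants,
                              write_proteome_fasta)
from degscan.stats import ora


# ----------------------------------------------------------------------
# analytic match rate
# ----------------------------------------------------------------------

def test_expected_match_rate_cpd_uniform(cpd):
    # (2/20)^3 * (1/20) * 1 * 1 * (4/20) = 1e-5
    assert expected_match_rate(cpd) == pytest.approx(1.0e-5)


def test_expected_match_rate_wildcards_and_zero_mass(cpd):
    all_wild = ConsensusMotif((None, None, None))
    assert expected_match_rate(all_wild) == 1.0
    bg = {"A": 1.0}  # all mass on alanine: CPD classes have zero mass
    assert expected_match_rate(cpd, bg) == 0.0


def test_expected_match_rate_invalid_background(cpd):
    with pytest.raises(ValueError):
        expected_match_rate(cpd, {"A": 0.5})


# ----------------------------------------------------------------------
# proteome generation
# ----------------------------------------------------------------------

def test_gen_proteome_deterministic(cpd, tmp_path):
    a, ta = gen_proteome(10, 200, seed=3, motif=cpd, n_implants=5, clean_background=True)
    b, tb = gen_proteome(10, 200, seed=3, motif=cpd, n_implants=5, clean_background=True)
    assert a == b and ta == tb
    fa, fb = tmp_path / "a.fa", tmp_path / "b.fa"
    write_proteome_fasta(a, fa)
    write_proteome_fasta(b, fb)
    assert fa.read_bytes() == fb.read_bytes()


def test_gen_proteome_different_seeds_differ(cpd):
    a, _ = gen_proteome(5, 200, seed=1)
    b, _ = gen_proteome(5, 200, seed=2)
    assert a != b


def test_clean_background_scan_recovers_exactly_the_implants(cpd):
    records, truth = gen_proteome(
        50, 500, seed=11, motif=cpd, n_implants=20, clean_background=True
    )
    assert len(truth) == 20
    assert verify_implants(records, truth)
    table = scan_proteome(cpd, records)
    assert sorted((m.protein_id, m.start_pos) for m in table.matches) == sorted(
        (t.protein_id, t.start_pos) for t in truth
    )
    for t in truth:
        assert cpd.matches_window(t.implant_seq)


def test_implant_positions_non_overlapping(cpd):
    _, truth = gen_proteome(3, 100, seed=5, motif=cpd, n_implants=12,
                            clean_background=True)
    by_protein = {}
    for t in truth:
        by_protein.setdefault(t.protein_id, []).append(t.start_pos)
    for starts in by_protein.values():
        starts.sort()
        assert all(b - a >= cpd.length for a, b in zip(starts, starts[1:]))


def test_impossible_implant_geometry_rejected(cpd):
    with pytest.raises(ValueError):
        gen_proteome(1, 10, seed=0, motif=cpd, n_implants=5, clean_background=True)


def test_variable_length_law(cpd):
    records, _ = gen_proteome(20, (50, 150), seed=9)
    lengths = {len(r.sequence) for r in records}
    assert all(50 <= x <= 150 for x in lengths) and len(lengths) > 1


def test_background_match_rate_converges_to_analytic(cpd):
    # ~2e6 windows: expect ~20 matches, Poisson-distributed
    records, _ = gen_proteome(200, 10_006, seed=101)
    n_windows = sum(len(r.sequence) - cpd.length + 1 for r in records)
    table = scan_proteome(cpd, records)
    expected = n_windows * expected_match_rate(cpd)
    assert abs(len(table.matches) - expected) <= 3 * math.sqrt(expected)


# ----------------------------------------------------------------------
# ortholog families
# ----------------------------------------------------------------------

@pytest.fixture
def reference():
    return ProteinRecord("REF", "TOY", "MMMLLTPQQDAAAAAAAAAA")


def test_zero_substitution_fully_retains(cpd, reference):
    fam = gen_ortholog_family(reference, 5, sub_prob=0.0, seed=1)
    res = score_conservation(cpd, fam, ref_start=4)
    assert res.motif_retention == 1.0


def test_preserve_window_under_total_substitution(cpd, reference):
    fam = gen_ortholog_family(
        reference, 5, sub_prob=1.0, seed=1, preserve_window=(4, 7)
    )
    res = score_conservation(cpd, fam, ref_start=4)
    assert res.motif_retention == 1.0
    # every site outside the window was substituted
    for mid, seq in fam.members.items():
        if mid == "REF":
            continue
        assert seq[3:10] == reference.sequence[3:10]
        assert all(seq[i] != reference.sequence[i] for i in range(3))


def test_per_site_identity_tracks_substitution_probability(reference):
    long_ref = ProteinRecord("REF", "TOY", "A" * 500)
    fam = gen_ortholog_family(long_ref, 100, sub_prob=0.1, seed=2)
    identities = [
        np.mean([a == b for a, b in zip(seq, long_ref.sequence)])
        for mid, seq in fam.members.items()
        if mid != "REF"
    ]
    se = math.sqrt(0.1 * 0.9 / 500)
    assert abs(np.mean(identities) - 0.9) <= 3 * se


def test_retention_monotone_in_substitution_probability(cpd, reference):
    means = []
    for sub in (0.0, 0.2, 0.6):
        rets = []
        for seed in range(10):
            fam = gen_ortholog_family(reference, 10, sub_prob=sub, seed=seed)
            rets.append(score_conservation(cpd, fam, ref_start=4).motif_retention)
        means.append(np.mean(rets))
    assert means[0] >= means[1] >= means[2]


def test_invalid_sub_prob_rejected(reference):
    with pytest.raises(ValueError):
        gen_ortholog_family(reference, 3, sub_prob=1.5, seed=0)


# ----------------------------------------------------------------------
# phosphosites
# ----------------------------------------------------------------------

def test_gen_phosphosites_residues_agree(reference):
    table = gen_phosphosites([reference], [("REF", 6), ("REF", 10)])
    assert table.residue_at("REF", 6) == "T"
    assert table.residue_at("REF", 10) == "D"
    with pytest.raises(ValueError):
        gen_phosphosites([reference], [("REF", 99)])


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def test_gen_genesets_deterministic():
    universe = [f"G{i}" for i in range(200)]
    a = gen_genesets(universe, 10, 20, seed=4)
    b = gen_genesets(universe, 10, 20, seed=4)
    assert a == b


def test_spiked_set_has_exact_overlap():
    universe = [f"G{i}" for i in range(200)]
    candidates = universe[:40]
    sets, spiked = gen_genesets(
        universe, 10, 20, seed=4, spiked=(20, 8, candidates)
    )
    assert spiked == "SPIKED"
    members = sets[spiked]
    assert len(members) == 20
    assert len(set(members) & set(candidates)) == 8


def test_spiked_set_detected_by_ora():
    universe = [f"G{i}" for i in range(500)]
    candidates = universe[:50]
    sets, spiked = gen_genesets(universe, 20, 25, seed=6, spiked=(25, 15, candidates))
    rows = ora(candidates, sets, universe)
    assert rows[0].set_name == spiked
    assert rows[0].q_value < 0.05


def test_impossible_spike_geometry_rejected():
    universe = [f"G{i}" for i in range(50)]
    with pytest.raises(ValueError):
        gen_genesets(universe, 2, 10, seed=0, spiked=(10, 11, universe[:5]))
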