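"""Structure I/O, domain selection, and correspondence building."""

from __future__ import annotations

import itertools

import gemmi
import numpy as np
import pytest

from fusemotion import simulate
from fusemotion.errors import CorrespondenceError, FormatError, SelectionError
from fusemotion.structures import (
    DomainDefinition,
    build_correspondence,
    default_domain_definitions,
    load_domain_definitions,
    read_structure,
    select_domain,
    write_pdb,
)

from conftest import make_structure

TWO_ATOM_PDB = """\
ATOM      1  CA  ALA A  10      11.000  22.000  33.000  1.00 10.00           C
ATOM      2  CA  GLY A  11      14.500  22.250  30.125  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A  10      1.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A  10      9.000   0.000   0.000  0.40 10.00           C
END
"""


def test_read_minimal_pdb_returns_printed_coordinates(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_ATOM_PDB)
    s = read_structure(p)
    assert len(s) == 2
    np.testing.assert_allclose(s.atoms[0].position, [11.0, 22.0, 33.0])
    np.testing.assert_allclose(s.atoms[1].position, [14.5, 22.25, 30.125])
    assert s.atoms[0].residue_number == 10
    assert s.atoms[1].residue_name == "GLY"


def test_pdb_and_mmcif_roundtrip_identical(tmp_path):
    p = tmp_path / "two.pdb"
    p.write_text(TWO_ATOM_PDB)
    st = gemmi.read_pdb(str(p))
    st.setup_entities()
    cif = tmp_path / "two.cif"
    st.make_mmcif_document().write_file(str(cif))
    a = read_structure(p, format="pdb")
    b = read_structure(cif, format="mmcif")
    assert len(a) == len(b)
    for x, y in zip(a.atoms, b.atoms):
        assert x.residue_key == y.residue_key
        np.testing.assert_allclose(x.position, y.position, atol=1e-3)


def test_altloc_keeps_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    s = read_structure(p)
    assert len(s) == 1
    np.testing.assert_allclose(s.atoms[0].position, [1.0, 0.0, 0.0])
    assert s.atoms[0].occupancy == pytest.approx(0.6)


def test_unreadable_file_raises_format_error(tmp_path):
    missing = tmp_path / "nope.pdb"
    with pytest.raises(FormatError):
        read_structure(missing)


def test_write_read_roundtrip_preserves_coordinates(tmp_path, rod):
    out = tmp_path / "rod.pdb"
    write_pdb(rod, out)
    back = read_structure(out)
    assert len(back) == len(rod)
    np.testing.assert_allclose(back.coords(), rod.coords(), atol=1e-3)


def test_domain_selection_excludes_out_of_range_residues():
    # a 28–564 chain restricted to the 28–457 construct drops 458–564
    s, _ = simulate.gen_rod_structure(
        n_domains=4, residues_per_domain=135, start_residue=28, seed=0
    )  # residues 28..567
    d1d2 = DomainDefinition("D1D2", (("A", 28, 457),))
    sel = select_domain(s, d1d2)
    numbers = {a.residue_number for a in sel.atoms}
    assert max(numbers) == 457 and min(numbers) == 28
    assert len(numbers) == 430


def test_whole_structure_interval_is_identity(rod):
    d = DomainDefinition("all", (("A", 1, 10_000),))
    sel = select_domain(rod, d)
    assert len(sel) == len(rod)
    np.testing.assert_array_equal(sel.coords(), rod.coords())


def test_fusion_loop_interval_selects_expected_residue_count():
    s, _ = simulate.gen_rod_structure(
        n_domains=4, residues_per_domain=60, start_residue=28, seed=0
    )
    fl1 = DomainDefinition("FL1", (("A", 190, 198),))
    sel = select_domain(s, fl1, "CA-only")
    assert len(sel) == 9


def test_empty_selection_raises(rod):
    d = DomainDefinition("ghost", (("Z", 1, 5),))
    with pytest.raises(SelectionError):
        select_domain(rod, d)


def test_select_domain_idempotent_and_commutes_with_filter(rod, rod_domains):
    d = rod_domains["D2"]
    once = select_domain(rod, d, "CA-only")
    twice = select_domain(once, d, "CA-only")
    np.testing.assert_array_equal(once.coords(), twice.coords())
    other_order = select_domain(select_domain(rod, d, "all-atoms"), d, "CA-only")
    np.testing.assert_array_equal(once.coords(), other_order.coords())


def test_identity_correspondence_with_self_is_bijection(rod):
    corr = build_correspondence(rod, rod, "identity")
    assert len(corr) == len(rod.residue_keys())
    assert all(a == b for a, b in corr.pairs)


def test_disjoint_numbering_identity_mode_errors():
    a = make_structure(np.random.default_rng(0).normal(size=(5, 3)), start=1)
    b = make_structure(np.random.default_rng(1).normal(size=(5, 3)), start=100)
    with pytest.raises(CorrespondenceError):
        build_correspondence(a, b, "identity")


def _brute_force_global_alignment(seq_a, seq_b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Enumerate all global alignments; return the optimal score and the set
    of residue-pairings realized by at least one optimal alignment."""
    best = {"score": -np.inf, "pairings": []}

    def recurse(i, j, score, pairs):
        if i == len(seq_a) and j == len(seq_b):
            if score > best["score"] + 1e-12:
                best["score"], best["pairings"] = score, [tuple(pairs)]
            elif abs(score - best["score"]) <= 1e-12:
                best["pairings"].append(tuple(pairs))
            return
        if i < len(seq_a) and j < len(seq_b):
            s = match if seq_a[i] == seq_b[j] else mismatch
            recurse(i + 1, j + 1, score + s, pairs + [(i, j)])
        if i < len(seq_a):
            recurse(i + 1, j, score + gap, pairs)
        if j < len(seq_b):
            recurse(i, j + 1, score + gap, pairs)

    recurse(0, 0, 0.0, [])
    return best["score"], best["pairings"]


def test_sequence_alignment_matches_brute_force_enumeration():
    # ACDEF vs ACEF: every optimal alignment pairs 4 residues, D unpaired
    seq_a, seq_b = "ACDEF", "ACEF"
    names = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE"}
    score, pairings = _brute_force_global_alignment(seq_a, seq_b)
    assert all(len(p) == 4 for p in pairings)

    rng = np.random.default_rng(0)
    a = make_structure(rng.normal(size=(5, 3)), start=1)
    b = make_structure(rng.normal(size=(4, 3)), start=50)
    for s, seq in ((a, seq_a), (b, seq_b)):
        for atom, letter in zip(s.atoms, seq):
            object.__setattr__(atom, "residue_name", names[letter])
    corr = build_correspondence(a, b, "sequence-alignment")
    got = tuple((ka[1] - 1, kb[1] - 50) for ka, kb in corr.pairs)
    assert got in pairings
    unpaired_a = set(range(5)) - {i for i, _ in got}
    assert unpaired_a == {2}  # the D residue


def test_user_table_mode_passthrough(rod):
    keys = rod.residue_keys()[:5]
    corr = build_correspondence(rod, rod, "user-table", pairs=[(k, k) for k in keys])
    assert len(corr) == 5


def test_domain_yaml_roundtrip(tmp_path):
    cfg = tmp_path / "domains.yaml"
    cfg.write_text(
        "domains:\n"
        "  - {name: D1, chain: A, start: 28, end: 130}\n"
        "  - {name: D1, chain: A, start: 446, end: 457}\n"
        "  - {name: D3, chain: A, start: 458, end: 564}\n"
    )
    doms = load_domain_definitions(cfg)
    assert doms["D1"].intervals == (("A", 28, 130), ("A", 446, 457))
    assert doms["D3"].contains("A", 500)


def test_default_domain_definitions_are_consistent():
    doms = default_domain_definitions()
    assert doms["D1D2"].intervals == (("A", 28, 457),)
    assert doms["D3"].intervals == (("A", 458, 564),)
    # canonical fusion-loop intervals in author numbering
    assert doms["FL1"].intervals[0][1:] == (190, 198)
    assert doms["J0"].intervals[0][1:] == (447, 456)


def test_overlapping_intervals_rejected():
    with pytest.raises(ValueError):
        DomainDefinition("bad", (("A", 1, 10), ("A", 5, 20)))
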