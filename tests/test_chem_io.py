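"""Structure parsing, pocket extraction, and protein graph construction."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from protacdeg import chem_io
from protacdeg.chem_io import Atom, PocketSpec
from protacdeg.egnn import random_transform
from protacdeg.synthetic import random_molecule, random_pocket, write_mol2

# ---------------------------------------------------------------------------
# mol2
# ---------------------------------------------------------------------------

TOY_MOL2 = """@<TRIPOS>MOLECULE
toy
3 2 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      1 C1     0.0000    0.0000    0.0000 C.3 1 LIG 0.0
      2 N2     1.5000    0.0000    0.0000 N.3 1 LIG 0.0
      3 O3     1.5000    1.4000    0.0000 O.3 1 LIG 0.0
@<TRIPOS>BOND
     1     1     2 1
     2     2     3 2
"""


def test_mol2_roundtrip_toy(tmp_path):
    p = tmp_path / "toy.mol2"
    p.write_text(TOY_MOL2)
    g = chem_io.parse_mol2(p)
    assert g.n_nodes == 3
    assert len(g.edges) == 2
    np.testing.assert_allclose(g.coords[1], [1.5, 0.0, 0.0])
    assert g.elements == ["C", "N", "O"]
    # bond order encoded: second bond is a double bond
    double_col = chem_io.EDGE_ATTR_NAMES.index("double")
    assert g.edge_attr[:, double_col].sum() == 1


def test_mol2_reversed_atom_order_keeps_coords_with_atoms(tmp_path):
    reversed_text = """@<TRIPOS>MOLECULE
toy
3 2 0 0 0
SMALL
NO_CHARGES

@<TRIPOS>ATOM
      3 O3     1.5000    1.4000    0.0000 O.3 1 LIG 0.0
      2 N2     1.5000    0.0000    0.0000 N.3 1 LIG 0.0
      1 C1     0.0000    0.0000    0.0000 C.3 1 LIG 0.0
@<TRIPOS>BOND
     1     1     2 1
     2     2     3 2
"""
    p = tmp_path / "rev.mol2"
    p.write_text(reversed_text)
    g = chem_io.parse_mol2(p)
    # coords follow the atom id, not the row position
    by_el = dict(zip(g.elements, g.coords))
    np.testing.assert_allclose(by_el["C"], [0.0, 0.0, 0.0])
    np.testing.assert_allclose(by_el["O"], [1.5, 1.4, 0.0])
    # same edges up to the element identity of the endpoints
    pairs = {frozenset((g.elements[i], g.elements[j])) for i, j in g.edges}
    assert pairs == {frozenset(("C", "N")), frozenset(("N", "O"))}


def _oracle_parse_mol2(text):
    """Independent minimal TRIPOS reader used as a cross-check."""
    section, atoms, bonds = None, [], []
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("@<TRIPOS>"):
            section = s[9:]
        elif s and section == "ATOM":
            f = s.split()
            atoms.append((int(f[0]), tuple(map(float, f[2:5]))))
        elif s and section == "BOND":
            f = s.split()
            bonds.append((int(f[1]), int(f[2])))
    idx = {orig: i for i, (orig, _) in enumerate(atoms)}
    adj = np.zeros((len(atoms), len(atoms)), dtype=int)
    for a, b in bonds:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = 1
    return adj, np.array([xyz for _, xyz in atoms])


def test_mol2_adjacency_matches_independent_parser(tmp_path):
    g, text = random_molecule(12, seed=3)
    oracle_adj, oracle_coords = _oracle_parse_mol2(text)
    np.testing.assert_array_equal(g.adjacency, oracle_adj)
    np.testing.assert_allclose(g.coords, oracle_coords, atol=1e-12)


def test_mol2_errors(tmp_path):
    p = tmp_path / "bad.mol2"
    p.write_text("@<TRIPOS>ATOM\n1 C1 nan_is_bad x y C.3\n")
    with pytest.raises(chem_io.ParseError):
        chem_io.parse_mol2(p)
    p2 = tmp_path / "empty.mol2"
    p2.write_text("@<TRIPOS>MOLECULE\nempty\n")
    with pytest.raises(chem_io.ParseError, match="no atoms"):
        chem_io.parse_mol2(p2)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _pdb_atom(serial, name, resname, resseq, xyz, element, altloc=" ", occ=1.0):
    return (f"ATOM  {serial:>5d} {name:<4s}{altloc}{resname:>3s} A{resseq:>4d}"
            f"    {xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}{occ:>6.2f}  0.00"
            f"          {element:>2s}")


def test_pdb_roundtrip_two_residues(tmp_path):
    lines = []
    s = 1
    for r in range(2):
        for a, (name, el) in enumerate([("N", "N"), ("CA", "C"), ("C", "C")]):
            lines.append(_pdb_atom(s, name, "ALA", r + 1, (float(s), 0.0, 0.0), el))
            s += 1
    p = tmp_path / "two.pdb"
    p.write_text("\n".join(lines) + "\n")
    atoms = chem_io.parse_pdb(p)
    assert len(atoms) == 6
    assert {a.residue_id for a in atoms} == {0, 1}
    assert all(a.residue_name == "ALA" for a in atoms)


def test_pdb_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        _pdb_atom(1, "CA", "ALA", 1, (0.0, 0.0, 0.0), "C", altloc="A", occ=0.4),
        _pdb_atom(2, "CA", "ALA", 1, (9.0, 0.0, 0.0), "C", altloc="B", occ=0.6),
        _pdb_atom(3, "CB", "ALA", 1, (1.0, 0.0, 0.0), "C"),
    ]
    p = tmp_path / "alt.pdb"
    p.write_text("\n".join(lines) + "\n")
    atoms = chem_io.parse_pdb(p)
    assert len(atoms) == 2
    ca = [a for a in atoms if np.isclose(a.coords[0], 9.0)]
    assert len(ca) == 1  # occupancy 0.6 copy won


def test_pdb_coords_match_biopython(tmp_path):
    """Coordinates agree with an independent reader (Biopython)."""
    Bio = pytest.importorskip("Bio.PDB")
    text, _ = random_pocket(8, seed=11, inside_fraction=0.5)
    p = tmp_path / "pocket.pdb"
    p.write_text(text)
    ours = chem_io.parse_pdb(p, strip_solvent=False)
    parser = Bio.PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(p))
    ref = np.array([a.get_coord() for a in structure.get_atoms()])
    np.testing.assert_allclose(np.array([a.coords for a in ours]), ref, atol=1e-3)


def test_pdb_unreadable_coords_raise(tmp_path):
    bad = _pdb_atom(1, "CA", "ALA", 1, (0.0, 0.0, 0.0), "C").replace("   0.000", "  xx.yyy", 1)
    p = tmp_path / "bad.pdb"
    p.write_text(bad + "\n")
    with pytest.raises(chem_io.ParseError):
        chem_io.parse_pdb(p)


# ---------------------------------------------------------------------------
# pocket extraction
# ---------------------------------------------------------------------------

def _res_atom(el, xyz, rid, rname="ALA", idx=0):
    return Atom(element=el, coords=xyz, residue_id=rid, residue_name=rname, atom_index=idx)


def test_pocket_distance_rule():
    lig = [Atom(element="C", coords=(0, 0, 0))]
    rec = [_res_atom("C", (3, 0, 0), 0), _res_atom("N", (6, 0, 0), 0),
           _res_atom("C", (10, 0, 0), 1)]
    pocket = chem_io.extract_pocket(PocketSpec(lig, rec, cutoff=5.0))
    # residue 0 kept atomically (even its far atom); residue 1 dropped
    assert {a.residue_id for a in pocket} == {0}
    assert len(pocket) == 2


def test_pocket_monotone_in_cutoff():
    rng = np.random.default_rng(5)
    lig = [Atom(element="C", coords=tuple(rng.normal(size=3)))]
    rec = [_res_atom("C", tuple(rng.normal(scale=6, size=3)), rid=i // 3)
           for i in range(60)]
    small = {(a.residue_id, a.coords) for a in
             chem_io.extract_pocket(PocketSpec(lig, rec, cutoff=5.0))}
    big = {(a.residue_id, a.coords) for a in
           chem_io.extract_pocket(PocketSpec(lig, rec, cutoff=6.0))}
    assert small <= big


def test_pocket_matches_bruteforce_scan():
    rng = np.random.default_rng(9)
    lig = [Atom(element="C", coords=tuple(rng.normal(size=3))) for _ in range(4)]
    rec = [_res_atom("C", tuple(rng.normal(scale=7, size=3)), rid=i // 4)
           for i in range(120)]
    pocket = chem_io.extract_pocket(PocketSpec(lig, rec, cutoff=5.0))
    # brute force: all-pairs loop
    keep = set()
    for a in rec:
        for b in lig:
            if np.linalg.norm(np.subtract(a.coords, b.coords)) <= 5.0:
                keep.add(a.residue_id)
    expected = [a for a in rec if a.residue_id in keep]
    assert [(a.residue_id, a.coords) for a in pocket] == \
        [(a.residue_id, a.coords) for a in expected]


def test_pocket_idempotent():
    rng = np.random.default_rng(3)
    lig = [Atom(element="C", coords=(0, 0, 0))]
    rec = [_res_atom("C", tuple(rng.normal(scale=5, size=3)), rid=i // 3)
           for i in range(30)]
    once = chem_io.extract_pocket(PocketSpec(lig, rec, cutoff=5.0))
    twice = chem_io.extract_pocket(PocketSpec(lig, once, cutoff=5.0))
    assert [(a.residue_id, a.coords) for a in once] == \
        [(a.residue_id, a.coords) for a in twice]


def test_empty_receptor_gives_empty_pocket():
    lig = [Atom(element="C", coords=(0, 0, 0))]
    assert chem_io.extract_pocket(PocketSpec(lig, [], cutoff=5.0)) == []


# ---------------------------------------------------------------------------
# protein graphs
# ---------------------------------------------------------------------------

def test_protein_graph_intra_only_when_residues_far():
    atoms = [_res_atom("C", (0, 0, 0), 0), _res_atom("N", (1.4, 0, 0), 0),
             _res_atom("C", (20, 0, 0), 1), _res_atom("N", (21.4, 0, 0), 1)]
    g = chem_io.build_protein_graph(atoms, kind="POI", inter_cutoff=4.5)
    assert set(g.edge_kind) == {"intra_residue"}
    assert len(g.edges) == 2


def test_protein_graph_threshold_behavior():
    cut = 4.5
    atoms = [_res_atom("C", (0, 0, 0), 0), _res_atom("N", (1.4, 0, 0), 0),
             _res_atom("C", (1.4 + cut - 1e-6, 0, 0), 1),
             _res_atom("N", (1.4 + cut + 1.4, 0, 0), 1)]
    g = chem_io.build_protein_graph(atoms, kind="E3", inter_cutoff=cut)
    inter = [k for k in g.edge_kind if k == "inter_residue"]
    assert len(inter) == 1


def test_protein_graph_matches_allpairs_oracle():
    rng = np.random.default_rng(17)
    atoms = []
    for r in range(5):
        center = rng.normal(scale=4, size=3)
        for a in range(3):
            atoms.append(_res_atom("C", tuple(center + rng.normal(scale=0.8, size=3)), r))
    g = chem_io.build_protein_graph(atoms, kind="POI")
    coords = np.array([a.coords for a in atoms])
    d = cdist(coords, coords)
    expected = set()
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            same = atoms[i].residue_id == atoms[j].residue_id
            if (same and d[i, j] <= 1.9) or (not same and d[i, j] <= 4.5):
                expected.add((i, j))
    assert set(map(tuple, g.edges)) == expected


def test_single_atom_pocket_graph():
    g = chem_io.build_protein_graph([_res_atom("C", (0, 0, 0), 0)], kind="POI")
    assert g.n_nodes == 1 and len(g.edges) == 0


def test_topology_invariant_under_rigid_motion():
    rng = np.random.default_rng(23)
    atoms = [_res_atom("C", tuple(rng.normal(scale=4, size=3)), rid=i // 3)
             for i in range(24)]
    t = random_transform(rng)
    moved = [_res_atom(a.element, tuple(t.apply(np.array([a.coords]))[0]),
                       a.residue_id) for a in atoms]
    g1 = chem_io.build_protein_graph(atoms, kind="POI")
    g2 = chem_io.build_protein_graph(moved, kind="POI")
    assert np.array_equal(g1.edges, g2.edges)
    assert g1.edge_kind == g2.edge_kind
    lig = [Atom(element="C", coords=(0.0, 0.0, 0.0))]
    lig_moved = [Atom(element="C", coords=tuple(t.apply(np.zeros((1, 3)))[0]))]
    p1 = chem_io.extract_pocket(PocketSpec(lig, atoms, 5.0))
    p2 = chem_io.extract_pocket(PocketSpec(lig_moved, moved, 5.0))
    assert [a.residue_id for a in p1] == [a.residue_id for a in p2]


def test_graph_serialization_roundtrip(tiny_dataset):
    for s in tiny_dataset["samples"][:3]:
        for g in s.graphs.values():
            g2 = chem_io.graph_from_json(chem_io.graph_to_json(g))
            np.testing.assert_allclose(g2.coords, g.coords)
            np.testing.assert_array_equal(g2.edges, g.edges)
            np.testing.assert_allclose(g2.features, g.features)
            g2.validate()


def test_smiles_graph_flagged_non_canonical():
    g = chem_io.smiles_to_graph("CCOCC", seed=1)
    assert g.kind == "PROTAC"
    assert g.n_nodes == 5
    assert "non-canonical" in g.provenance["coords"]


def test_every_parsed_graph_satisfies_invariants(tiny_dataset):
    for s in tiny_dataset["samples"]:
        for g in s.graphs.values():
            g.validate()
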