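"""Molecular structure I/O and 3D graph construction.

Reads TRIPOS mol2 files (PROTACs with docked 3D coordinates) and PDB
files (POI / E3-ligase structures with a bound ligand), extracts binding
pockets as the set of residues within a distance cutoff of the ligand,
and builds the three kinds of attributed 3D molecule graphs the encoder
consumes:

* PROTAC graphs: atoms as nodes, covalent bonds as edges;
* protein pocket graphs: atoms as nodes, with *intra-residue* edges
  (covalent-range contacts inside one residue) and *inter-residue*
  edges (heavy-atom contacts between residues within a cutoff).

Coordinates are Cartesian angstroms exactly as stored in the file; no
re-centering happens at parse time.  Hydrogens are dropped by default so
graphs stay small and heavy-atom distances drive the geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Atom",
    "MoleculeGraph",
    "PocketSpec",
    "ParseError",
    "parse_mol2",
    "parse_pdb",
    "extract_pocket",
    "build_protein_graph",
    "smiles_to_graph",
    "graph_to_json",
    "graph_from_json",
]

# edge attribute layout: bond-order one-hot + edge-class one-hot + distance
EDGE_ATTR_NAMES = ("single", "double", "triple", "aromatic", "intra_residue",
                   "inter_residue", "distance")
EDGE_ATTR_DIM = len(EDGE_ATTR_NAMES)

#: residue names treated as solvent/ions and stripped before pocket work
_SOLVENT = {"HOH", "WAT", "DOD", "H2O", "NA", "K", "CL", "MG", "ZN", "CA",
            "MN", "SO4", "PO4"}

_DEFAULT_INTER_CUTOFF = 4.5  # Å, heavy-atom inter-residue contact
_DEFAULT_INTRA_CUTOFF = 1.9  # Å, covalent-range heavy-atom distance


class ParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a small molecule or protein.

    ``residue_id``/``residue_name`` are ``None`` exactly when the atom
    belongs to a small molecule.
    """

    element: str
    coords: tuple
    residue_id: int | None = None
    residue_name: str | None = None
    atom_index: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_index}")
        if (self.residue_id is None) != (self.residue_name is None):
            raise ValueError("residue_id and residue_name must be set together")


@dataclass
class MoleculeGraph:
    """3D attributed molecule graph G = {A, X, H}.

    Edges are stored once per undirected pair as an ``(E, 2)`` index
    array with ``i < j``; ``edge_kind[e]`` is one of ``bond``,
    ``intra_residue``, ``inter_residue`` and ``edge_attr[e]`` follows
    :data:`EDGE_ATTR_NAMES`.
    """

    kind: str  # PROTAC | POI | E3
    coords: np.ndarray  # (N, 3) Å
    features: np.ndarray  # (N, d)
    edges: np.ndarray  # (E, 2) int, i < j
    edge_kind: list  # length E
    edge_attr: np.ndarray  # (E, EDGE_ATTR_DIM)
    elements: list  # length N
    residue_ids: list | None = None  # protein graphs only
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        if len(self.edges):
            a[self.edges[:, 0], self.edges[:, 1]] = 1
            a[self.edges[:, 1], self.edges[:, 0]] = 1
        return a

    def validate(self) -> None:
        n = self.n_nodes
        if n < 1:
            raise ValueError("graph has no nodes")
        if self.features.shape[0] != n:
            raise ValueError("coords/features row mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-loop present")
            pairs = set(map(tuple, self.edges))
            if len(pairs) != len(self.edges):
                raise ValueError("duplicate edge")
        if len(self.edge_kind) != len(self.edges) or self.edge_attr.shape[0] != len(self.edges):
            raise ValueError("edge annotation length mismatch")
        allowed = {"PROTAC": {"bond"}, "POI": {"intra_residue", "inter_residue"},
                   "E3": {"intra_residue", "inter_residue"}}[self.kind]
        if not set(self.edge_kind) <= allowed:
            raise ValueError(f"edge kinds {set(self.edge_kind)} not allowed for {self.kind}")


@dataclass
class PocketSpec:
    """Ligand + receptor atoms and the pocket distance cutoff (Å)."""

    ligand_atoms: list
    receptor_atoms: list
    cutoff: float = 5.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


# ---------------------------------------------------------------------------
# mol2
# ---------------------------------------------------------------------------

_BOND_ORDER = {"1": "single", "2": "double", "3": "triple", "ar": "aromatic",
               "am": "single", "du": "single", "un": "single", "nc": None}


def parse_mol2(path, drop_hydrogens: bool = True) -> MoleculeGraph:
    """Parse a TRIPOS mol2 file into a PROTAC graph.

    One node per heavy atom (hydrogens dropped unless requested
    otherwise); bonds become undirected edges whose attributes encode
    the bond order; coordinates are copied verbatim.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    section = None
    raw_atoms = []  # (orig_id, element, xyz, is_aromatic_type)
    raw_bonds = []  # (a, b, order_key)
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[len("@<TRIPOS>"):].upper()
            continue
        if not stripped or stripped.startswith("#"):
            continue
        if section == "ATOM":
            parts = stripped.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: malformed ATOM record: {line!r}")
            try:
                orig_id = int(parts[0])
                xyz = (float(parts[2]), float(parts[3]), float(parts[4]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unreadable ATOM fields: {line!r}") from exc
            sybyl = parts[5]
            element = sybyl.split(".")[0].capitalize()
            aromatic_type = sybyl.lower().endswith(".ar")
            raw_atoms.append((orig_id, element, xyz, aromatic_type))
        elif section == "BOND":
            parts = stripped.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: malformed BOND record: {line!r}")
            try:
                a, b = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unreadable BOND indices: {line!r}") from exc
            raw_bonds.append((a, b, parts[3].lower()))

    if not raw_atoms:
        raise ParseError(f"{path}: no atoms found")

    keep = {}
    atoms = []
    for orig_id, element, xyz, aro in raw_atoms:
        if drop_hydrogens and element in ("H", "D"):
            continue
        keep[orig_id] = len(atoms)
        atoms.append((element, xyz, aro))
    if not atoms:
        raise ParseError(f"{path}: structure contains only hydrogens")

    edge_set = {}
    aromatic_atoms = {i for i, (_, _, aro) in enumerate(atoms) if aro}
    for a, b, key in raw_bonds:
        if key not in _BOND_ORDER:
            raise ParseError(f"{path}: unknown bond type {key!r}")
        order = _BOND_ORDER[key]
        if order is None or a not in keep or b not in keep:
            continue
        i, j = keep[a], keep[b]
        if i == j:
            continue
        if key == "ar":
            aromatic_atoms.update((i, j))
        edge_set[(min(i, j), max(i, j))] = order

    coords = np.array([xyz for _, xyz, _ in atoms], dtype=float)
    elements = [el for el, _, _ in atoms]
    edges = np.array(sorted(edge_set), dtype=int).reshape(-1, 2)
    orders = [edge_set[tuple(e)] for e in edges]

    ring_atoms = _ring_members(len(atoms), edges)
    from . import featurize  # late import: featurize depends on chem_io types

    degree = np.zeros(len(atoms), dtype=int)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    feats = np.stack([
        featurize.atom_features(
            element=elements[i], degree=int(degree[i]),
            aromatic=i in aromatic_atoms, in_ring=i in ring_atoms,
            residue_name=None)
        for i in range(len(atoms))
    ])

    attr = np.zeros((len(edges), EDGE_ATTR_DIM))
    for e, (i, j) in enumerate(edges):
        attr[e, EDGE_ATTR_NAMES.index(orders[e])] = 1.0
        attr[e, -1] = np.linalg.norm(coords[i] - coords[j])

    g = MoleculeGraph(kind="PROTAC", coords=coords, features=feats, edges=edges,
                      edge_kind=["bond"] * len(edges), edge_attr=attr,
                      elements=elements, provenance={"source": str(path)})
    g.validate()
    return g


def _ring_members(n: int, edges: np.ndarray) -> set:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, edges))
    members: set = set()
    for cycle in nx.cycle_basis(g):
        members.update(cycle)
    return members


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def parse_pdb(path, drop_hydrogens: bool = True, strip_solvent: bool = True) -> list:
    """Parse ATOM/HETATM records of a PDB file into a list of :class:`Atom`.

    Fixed-column parsing; altLoc duplicates are resolved by keeping the
    highest-occupancy copy (ties: first listed), insertion codes fold
    into the residue ordering, waters/ions are stripped.
    """
    best = {}  # (chain, resseq, icode, resname, atname) -> (occ, order, record)
    order = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            resname = line[17:20].strip()
            if strip_solvent and resname in _SOLVENT:
                continue
            element = line[76:78].strip().capitalize()
            if not element:
                name = line[12:16].strip()
                element = "".join(c for c in name if c.isalpha())[:1].capitalize()
            if drop_hydrogens and element in ("H", "D"):
                continue
            try:
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: unreadable coordinate columns: {line.rstrip()!r}"
                ) from exc
            occ_field = line[54:60].strip()
            occ = float(occ_field) if occ_field else 1.0
            key = (line[21], line[22:26].strip(), line[26], resname, line[12:16].strip())
            if key not in best or occ > best[key][0]:
                prior_order = best[key][1] if key in best else order
                best[key] = (occ, prior_order, (element, xyz, resname))
            order += 1

    residue_index: dict = {}
    atoms = []
    entries = sorted(((v[1], k, v[2]) for k, v in best.items()))
    for orig_order, key, (element, xyz, resname) in entries:
        res_key = key[:3]
        if res_key not in residue_index:
            residue_index[res_key] = len(residue_index)
        atoms.append(Atom(element=element, coords=xyz,
                          residue_id=residue_index[res_key], residue_name=resname,
                          atom_index=len(atoms)))
    return atoms


# ---------------------------------------------------------------------------
# pocket extraction and protein graphs
# ---------------------------------------------------------------------------

def extract_pocket(spec: PocketSpec) -> list:
    """Residues with any heavy atom within ``cutoff`` of any ligand atom.

    Whole residues are kept or dropped atomically.  Atom indices are
    renumbered consecutively in the returned list; residue ids keep
    their original values.
    """
    if not spec.ligand_atoms:
        raise ValueError("ligand_atoms must be nonempty")
    if not spec.receptor_atoms:
        return []
    lig = np.array([a.coords for a in spec.ligand_atoms])
    rec = np.array([a.coords for a in spec.receptor_atoms])
    mind = cdist(rec, lig).min(axis=1)
    hit_residues = {a.residue_id for a, d in zip(spec.receptor_atoms, mind)
                    if d <= spec.cutoff}
    out = []
    for a in spec.receptor_atoms:
        if a.residue_id in hit_residues:
            out.append(Atom(element=a.element, coords=a.coords,
                            residue_id=a.residue_id, residue_name=a.residue_name,
                            atom_index=len(out)))
    return out


def build_protein_graph(pocket_atoms, kind: str = "POI",
                        inter_cutoff: float = _DEFAULT_INTER_CUTOFF,
                        intra_cutoff: float = _DEFAULT_INTRA_CUTOFF,
                        provenance: dict | None = None) -> MoleculeGraph:
    """Build a pocket graph with intra- and inter-residue edges.

    Intra-residue edges connect same-residue heavy atoms at covalent
    range (``intra_cutoff``); inter-residue edges connect atoms of
    different residues within ``inter_cutoff``.
    """
    if not pocket_atoms:
        raise ValueError("pocket_atoms must be nonempty")
    if kind not in ("POI", "E3"):
        raise ValueError("protein graph kind must be POI or E3")
    coords = np.array([a.coords for a in pocket_atoms], dtype=float)
    res = np.array([a.residue_id for a in pocket_atoms])
    n = len(pocket_atoms)
    d = cdist(coords, coords)
    edges, kinds, attrs = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            same = res[i] == res[j]
            if same and d[i, j] <= intra_cutoff:
                ek = "intra_residue"
            elif not same and d[i, j] <= inter_cutoff:
                ek = "inter_residue"
            else:
                continue
            edges.append((i, j))
            kinds.append(ek)
            a = np.zeros(EDGE_ATTR_DIM)
            a[EDGE_ATTR_NAMES.index(ek)] = 1.0
            a[-1] = d[i, j]
            attrs.append(a)

    from . import featurize

    degree = np.zeros(n, dtype=int)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    feats = np.stack([
        featurize.atom_features(element=a.element, degree=int(degree[i]),
                                aromatic=False, in_ring=False,
                                residue_name=a.residue_name)
        for i, a in enumerate(pocket_atoms)
    ])
    g = MoleculeGraph(
        kind=kind, coords=coords, features=feats,
        edges=np.array(edges, dtype=int).reshape(-1, 2), edge_kind=kinds,
        edge_attr=np.array(attrs).reshape(-1, EDGE_ATTR_DIM),
        elements=[a.element for a in pocket_atoms],
        residue_ids=list(res), provenance=provenance or {})
    g.validate()
    return g


# ---------------------------------------------------------------------------
# SMILES fallback and serialization
# ---------------------------------------------------------------------------

def smiles_to_graph(smiles: str, seed: int = 0) -> MoleculeGraph:
    """Build a PROTAC graph from SMILES with generated 3D coordinates.

    Coordinates come from a deterministic distance-geometry embedding
    (ETKDG) and are a convenience for entries lacking a docked mol2
    file; they are flagged non-canonical in the provenance.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        params.useRandomCoords = True
        AllChem.EmbedMolecule(mol, params)
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    elements = [a.GetSymbol() for a in mol.GetAtoms()]

    from . import featurize

    feats = np.stack([
        featurize.atom_features(element=a.GetSymbol(), degree=a.GetDegree(),
                                aromatic=a.GetIsAromatic(), in_ring=a.IsInRing(),
                                residue_name=None)
        for a in mol.GetAtoms()
    ])
    order_map = {Chem.BondType.SINGLE: "single", Chem.BondType.DOUBLE: "double",
                 Chem.BondType.TRIPLE: "triple", Chem.BondType.AROMATIC: "aromatic"}
    edges, kinds, attrs = [], [], []
    for b in mol.GetBonds():
        i, j = sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        edges.append((i, j))
        kinds.append("bond")
        a = np.zeros(EDGE_ATTR_DIM)
        a[EDGE_ATTR_NAMES.index(order_map.get(b.GetBondType(), "single"))] = 1.0
        a[-1] = np.linalg.norm(coords[i] - coords[j])
        attrs.append(a)
    g = MoleculeGraph(kind="PROTAC", coords=coords, features=feats,
                      edges=np.array(edges, dtype=int).reshape(-1, 2),
                      edge_kind=kinds, edge_attr=np.array(attrs).reshape(-1, EDGE_ATTR_DIM),
                      elements=elements,
                      provenance={"source": "smiles", "smiles": smiles,
                                  "coords": "etkdg-embedded (non-canonical)"})
    g.validate()
    return g


def graph_to_json(g: MoleculeGraph) -> str:
    return json.dumps({
        "kind": g.kind,
        "coords": g.coords.tolist(),
        "features": g.features.tolist(),
        "edges": g.edges.tolist(),
        "edge_kind": list(g.edge_kind),
        "edge_attr": g.edge_attr.tolist(),
        "elements": list(g.elements),
        "residue_ids": None if g.residue_ids is None else [int(r) for r in g.residue_ids],
        "provenance": g.provenance,
    })


def graph_from_json(text: str) -> MoleculeGraph:
    d = json.loads(text)
    g = MoleculeGraph(
        kind=d["kind"], coords=np.array(d["coords"], dtype=float),
        features=np.array(d["features"], dtype=float),
        edges=np.array(d["edges"], dtype=int).reshape(-1, 2),
        edge_kind=list(d["edge_kind"]),
        edge_attr=np.array(d["edge_attr"], dtype=float).reshape(-1, EDGE_ATTR_DIM),
        elements=list(d["elements"]), residue_ids=d["residue_ids"],
        provenance=d.get("provenance", {}))
    g.validate()
    return g
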