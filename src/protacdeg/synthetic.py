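"""Self-contained synthetic fixtures.

Everything the pipeline consumes — mol2 PROTACs with 3D coordinates,
PDB pockets with a bound ligand, a manifest with DC50/Dmax annotations —
can be generated here from a seed, so the full pipeline builds and
trains without any external download.

The planted-signal dataset draws a latent activity score from a known
function of information the model can see — the mean pairwise atom
distance of the PROTAC 3D graph and the molecule's topological polar
surface area — plus Gaussian noise, then emits DC50/Dmax values that
reproduce the activity threshold rule exactly.  Generated molecules are
geometrically plausible chains (bonded atoms ~1.5 Å apart) but make no
claim of chemical realism beyond parser acceptance; labels planted this
way test whether training recovers a 3D-geometry + descriptor signal,
not performance on real PROTACs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "random_molecule", "random_pocket",
           "planted_signal_dataset", "write_mol2"]

_AA3 = ("ALA", "ARG", "ASN", "ASP", "GLN", "GLU", "GLY", "LEU", "LYS", "SER")


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-signal dataset."""

    n_samples: int = 600
    atoms_range: tuple = (9, 12)        # PROTAC heavy atoms
    n_pocket_residues: int = 5
    pocket_inside_fraction: float = 0.6
    label_balance: float = 0.5          # fraction of high-activity entries
    signal_strength: float = 4.0        # latent effect size
    noise_sd: float = 0.5
    unlabeled_fraction: float = 0.0     # entries with DC50/Dmax withheld
    n_duplicates: int = 0               # planted (POI, SMILES) duplicates
    n_poi: int = 6
    n_e3: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.label_balance < 1):
            raise ValueError("label_balance must be in (0, 1)")
        if self.atoms_range[0] < 2:
            raise ValueError("atoms_range minimum must be >= 2")


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

def write_mol2(elements, coords, bonds, name: str = "synthetic") -> str:
    """Serialize a heavy-atom molecule as TRIPOS mol2 text (4-decimal
    coordinates)."""
    lines = ["@<TRIPOS>MOLECULE", name,
             f"{len(elements)} {len(bonds)} 0 0 0", "SMALL", "NO_CHARGES", ""]
    lines.append("@<TRIPOS>ATOM")
    for i, (el, xyz) in enumerate(zip(elements, coords), start=1):
        lines.append(f"{i:>7d} {el}{i:<3d} {xyz[0]:>10.4f} {xyz[1]:>10.4f} "
                     f"{xyz[2]:>10.4f} {el}.3 1 LIG 0.0000")
    lines.append("@<TRIPOS>BOND")
    for b, (i, j, order) in enumerate(bonds, start=1):
        lines.append(f"{b:>6d} {i + 1:>5d} {j + 1:>5d} {order:>4}")
    return "\n".join(lines) + "\n"


def random_molecule(n_atoms: int, seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    bond_length: float = 1.5):
    """Random connected 3D molecule: a chain backbone (a spanning tree)
    plus a few short ring-closure bonds, bonded atoms ~``bond_length`` Å
    apart on a semi-extended worm-like path.  Varying ``bond_length``
    per molecule emulates conformer compactness: extended conformers
    have longer local steps and a proportionally larger global extent.

    Returns ``(graph, mol2_text)``; the text round-trips through
    :func:`protacdeg.chem_io.parse_mol2`.
    """
    from . import chem_io

    if rng is None:
        rng = np.random.default_rng(seed)
    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    elements = list(rng.choice(["C", "N", "O"], size=n_atoms, p=[0.7, 0.15, 0.15]))
    coords = np.zeros((n_atoms, 3))
    bonds = []
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, n_atoms):
        # path backbone; near-persistent step direction gives a
        # semi-extended (worm-like) conformation whose global extent
        # tracks the local bond length
        parent = i - 1
        direction = direction + 0.08 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[i] = (coords[parent] + bond_length * direction
                     + rng.normal(scale=0.03, size=3))
        bonds.append((parent, i, "1"))
    existing = {(min(i, j), max(i, j)) for i, j, _ in bonds}
    for _ in range(n_atoms // 10):
        # short ring closures between near-in-chain atoms
        i = int(rng.integers(0, n_atoms - 2))
        key = (i, i + 2)
        if key not in existing:
            existing.add(key)
            bonds.append((key[0], key[1], "1"))
    text = write_mol2(elements, coords, bonds)
    import tempfile

    # build the graph by round-tripping the text through the parser so
    # generated fixtures always satisfy the parser's invariants
    with tempfile.NamedTemporaryFile("w", suffix=".mol2", delete=False) as fh:
        fh.write(text)
        path = fh.name
    graph = chem_io.parse_mol2(path)
    Path(path).unlink()
    graph.provenance = {"source": "synthetic"}
    return graph, text


def random_chain_smiles(rng: np.random.Generator, min_len: int = 8,
                        max_len: int = 16) -> str:
    """A random unbranched heavy-atom chain over C/N/O — always valid."""
    n = int(rng.integers(min_len, max_len + 1))
    atoms = rng.choice(["C", "N", "O"], size=n, p=[0.6, 0.2, 0.2])
    atoms[0] = "C"
    return "".join(atoms)


# ---------------------------------------------------------------------------
# pockets
# ---------------------------------------------------------------------------

def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, xyz, element: str) -> str:
    return (f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{resname:>3s} {chain}"
            f"{resseq:>4d}{'':1s}   {xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}"
            f"{1.00:>6.2f}{0.00:>6.2f}          {element:>2s}")


def random_pocket(n_residues: int, seed: int | None = None,
                  inside_fraction: float = 1.0,
                  rng: np.random.Generator | None = None):
    """Toy receptor + ligand PDB text.

    A 3-atom ligand (HETATM, resname LIG) sits at the origin; residues
    of 4 heavy atoms each are placed on a near shell (within 5 Å of the
    ligand) or a far shell (well outside), with ``inside_fraction`` of
    them near.  Returns ``(pdb_text, n_inside)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_residues < 1:
        raise ValueError("need at least one residue")
    n_inside = int(round(inside_fraction * n_residues))
    lines = []
    serial = 1
    for k in range(3):
        xyz = rng.normal(scale=0.5, size=3)
        lines.append(_pdb_line("HETATM", serial, f"C{k + 1}", "LIG", "A", 900 + k, xyz, "C"))
        serial += 1
    for r in range(n_residues):
        inside = r < n_inside
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = rng.uniform(2.5, 3.5) if inside else rng.uniform(11.0, 14.0)
        center = radius * direction
        resname = _AA3[int(rng.integers(len(_AA3)))]
        names = ("N", "CA", "C", "O")
        elems = ("N", "C", "C", "O")
        pos = center.copy()
        for a in range(4):
            if a:
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                pos = pos + 1.4 * step
            lines.append(_pdb_line("ATOM", serial, names[a], resname, "A", r + 1,
                                   pos, elems[a]))
            serial += 1
    return "\n".join(lines) + "\nEND\n", n_inside


# ---------------------------------------------------------------------------
# the planted-signal dataset
# ---------------------------------------------------------------------------

def planted_signal_dataset(config: SyntheticConfig, out_dir) -> tuple:
    """Generate a complete fixture dataset directory.

    Writes PROTAC mol2 files, pocket PDB files, ``manifest.csv`` and
    ``ground_truth.csv``; returns ``(manifest_df, truth_df)``.  The
    latent activity score is

        score = signal_strength * (z_geom + z_tpsa) / sqrt(2) + noise

    where z_geom standardizes the PROTAC's mean pairwise atom distance
    and z_tpsa its TPSA; labels threshold the score at the
    ``1 - label_balance`` quantile, and DC50/Dmax annotations are drawn
    on the matching side of the activity rule (DC50 < 100 nM and
    Dmax >= 80 for high; DC50 >= 100 nM and Dmax < 80 for low), so label
    assignment recovers the planted label exactly.
    """
    from . import featurize

    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    poi_paths, e3_paths = {}, {}
    for i in range(config.n_poi):
        text, _ = random_pocket(config.n_pocket_residues, rng=rng,
                                inside_fraction=config.pocket_inside_fraction)
        p = out / "structures" / f"poi_{i}.pdb"
        p.write_text(text)
        poi_paths[f"POI{i}"] = str(p)
    for i in range(config.n_e3):
        text, _ = random_pocket(config.n_pocket_residues, rng=rng,
                                inside_fraction=config.pocket_inside_fraction)
        p = out / "structures" / f"e3_{i}.pdb"
        p.write_text(text)
        e3_paths[f"E3{i}"] = str(p)

    rows, geom, tpsa = [], [], []
    for i in range(config.n_samples):
        n_atoms = int(rng.integers(config.atoms_range[0], config.atoms_range[1] + 1))
        # per-molecule conformer compactness: bond step 1.3-1.9 Å
        graph, text = random_molecule(n_atoms, rng=rng,
                                      bond_length=rng.uniform(1.3, 1.9))
        mol2_path = out / "structures" / f"protac_{i}.mol2"
        mol2_path.write_text(text)
        smiles = random_chain_smiles(rng)
        d = graph.coords[:, None, :] - graph.coords[None, :, :]
        geom.append(float(np.sqrt((d ** 2).sum(-1)).mean()))
        tpsa.append(featurize.compute_descriptors(smiles)[3])
        rows.append({
            "entry_id": f"S{i:04d}", "smiles": smiles,
            "poi_id": f"POI{int(rng.integers(config.n_poi))}",
            "e3_id": f"E3{int(rng.integers(config.n_e3))}",
            "protac_mol2_path": str(mol2_path),
        })

    geom = np.asarray(geom)
    tpsa = np.asarray(tpsa)
    z_geom = (geom - geom.mean()) / max(geom.std(), 1e-12)
    z_tpsa = (tpsa - tpsa.mean()) / max(tpsa.std(), 1e-12)
    eta = (z_geom + z_tpsa) / np.sqrt(2.0)
    score = config.signal_strength * eta + config.noise_sd * rng.normal(size=len(eta))
    threshold = np.quantile(score, 1.0 - config.label_balance)
    labels = (score > threshold).astype(int)

    unlabeled = rng.random(config.n_samples) < config.unlabeled_fraction
    for i, row in enumerate(rows):
        row["poi_structure_path"] = poi_paths[row["poi_id"]]
        row["e3_structure_path"] = e3_paths[row["e3_id"]]
        if unlabeled[i]:
            row["dc50_nM"] = np.nan
            row["dmax_pct"] = np.nan
        elif labels[i] == 1:
            row["dc50_nM"] = 10 ** rng.uniform(0.0, 1.99)
            row["dmax_pct"] = rng.uniform(80.0, 100.0)
        else:
            row["dc50_nM"] = 10 ** rng.uniform(2.0, 4.0)
            row["dmax_pct"] = rng.uniform(0.0, 79.9)

    # planted leakage duplicates: same POI and SMILES, fresh entry id
    base = len(rows)
    for j in range(config.n_duplicates):
        src = rows[int(rng.integers(base))]
        dup = dict(src)
        dup["entry_id"] = f"D{j:04d}"
        rows.append(dup)
        labels = np.append(labels, labels[int(src["entry_id"][1:])])
        eta = np.append(eta, eta[int(src["entry_id"][1:])])

    manifest = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "entry_id": manifest["entry_id"],
        "true_label": labels,
        "eta": eta,
    })
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return manifest, truth
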