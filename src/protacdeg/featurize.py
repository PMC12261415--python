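"""Per-atom features, chemical descriptors, and the PROTAC attribute vector.

The PROTAC attribute vector f_P fuses two views of the molecule: a small
set of physicochemical descriptors (selected from 11 candidates by a
two-step variance/chi-square + gradient-boosting procedure) and a Morgan
fingerprint.  Each view passes through its own one-layer perceptron and
the outputs are concatenated; the total size equals the encoder hidden
size d' so the pooled node sum and the attribute vector can be added.
"""

from __future__ import annotations

import warnings

import numpy as np

from .autodiff import Tensor, concat
from .nn import Linear

__all__ = [
    "ATOM_FEATURE_DIM",
    "DESCRIPTOR_NAMES",
    "atom_features",
    "compute_descriptors",
    "select_features",
    "morgan_fingerprint",
    "canonical_smiles",
    "Standardizer",
    "AttributeEncoder",
]

# --- per-atom feature layout -------------------------------------------

_ELEMENT_CLASSES = ("C", "N", "O", "S", "P", "halogen", "other")
_HALOGENS = {"F", "Cl", "Br", "I"}
_AA3 = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL")

#: documented feature layout, in order
FEATURE_LAYOUT = (
    [f"element_{e}" for e in _ELEMENT_CLASSES]
    + ["degree", "aromatic", "in_ring"]
    + [f"residue_{r}" for r in _AA3] + ["residue_other"]
)
ATOM_FEATURE_DIM = len(FEATURE_LAYOUT)


def atom_features(element: str, degree: int, aromatic: bool, in_ring: bool,
                  residue_name: str | None) -> np.ndarray:
    """Encode one atom: element one-hot, degree, aromatic/ring flags,
    and (protein atoms only) a residue-type one-hot.

    Unknown elements map to the ``other`` class with a logged warning.
    """
    v = np.zeros(ATOM_FEATURE_DIM)
    el = element.capitalize()
    if el in _ELEMENT_CLASSES:
        cls = el
    elif el in _HALOGENS:
        cls = "halogen"
    else:
        cls = "other"
        if not el.isalpha() or len(el) > 2:
            warnings.warn(f"unrecognized element {element!r} mapped to 'other'")
    v[_ELEMENT_CLASSES.index(cls)] = 1.0
    base = len(_ELEMENT_CLASSES)
    v[base] = float(degree)
    v[base + 1] = float(bool(aromatic))
    v[base + 2] = float(bool(in_ring))
    if residue_name is not None:
        rn = residue_name.upper()
        idx = _AA3.index(rn) if rn in _AA3 else len(_AA3)
        v[base + 3 + idx] = 1.0
    return v


# --- descriptors -------------------------------------------------------

DESCRIPTOR_NAMES = (
    "hbd_count",          # hydrogen bond donor count (donor-atom convention)
    "hba_count",          # hydrogen bond acceptor count
    "rotatable_bonds",    # rotatable bond count
    "tpsa",               # topological polar surface area, Å²
    "mol_weight",         # molecular weight, Da
    "clogp",              # Crippen logP
    "ring_count",
    "aromatic_rings",
    "heavy_atoms",
    "formal_charge",
    "fraction_csp3",
)


def compute_descriptors(smiles: str) -> np.ndarray:
    """The 11 candidate physicochemical descriptors for one SMILES."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return np.array([
        Descriptors.NumHDonors(mol),
        Descriptors.NumHAcceptors(mol),
        Descriptors.NumRotatableBonds(mol),
        Descriptors.TPSA(mol),
        Descriptors.MolWt(mol),
        Descriptors.MolLogP(mol),
        Descriptors.RingCount(mol),
        Descriptors.NumAromaticRings(mol),
        mol.GetNumHeavyAtoms(),
        Chem.GetFormalCharge(mol),
        Descriptors.FractionCSP3(mol),
    ], dtype=float)


def select_features(values: np.ndarray, labels, k: int = 6, seed: int = 0,
                    return_report: bool = False):
    """Two-step descriptor selection; returns a boolean mask of length 11.

    Step 1 (filter): drop near-zero-variance columns, score survivors by
    chi-square against the binary label (columns min-max scaled to [0,1]
    and binned into deciles so chi-square sees nonnegative counts-like
    values).  Step 2 (embedded): fit a gradient-boosted tree ensemble on
    the survivors and keep the top-``k`` by impurity importance, chi-square
    score breaking ties.  Deterministic given ``seed``.
    """
    from sklearn.ensemble import GradientBoostingClassifier
    from sklearn.feature_selection import chi2

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(values)):
        raise ValueError("descriptor values must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("selection needs both classes present")

    n, p = values.shape
    lo, hi = values.min(axis=0), values.max(axis=0)
    span = hi - lo
    variance_ok = span > 1e-12
    scaled = np.zeros_like(values)
    scaled[:, variance_ok] = (values[:, variance_ok] - lo[variance_ok]) / span[variance_ok]
    variance_ok &= scaled.var(axis=0) > 1e-8

    chi2_scores = np.zeros(p)
    survivors = np.flatnonzero(variance_ok)
    if survivors.size:
        binned = np.clip(np.floor(scaled[:, survivors] * 10), 0, 9)
        sc, _ = chi2(binned, labels)
        chi2_scores[survivors] = np.nan_to_num(sc)

    mask = np.zeros(p, dtype=bool)
    if survivors.size == 0:
        raise ValueError("all descriptors are (near-)constant")
    if k >= survivors.size:
        if k > survivors.size:
            warnings.warn(f"k={k} exceeds {survivors.size} surviving descriptors; keeping all")
        mask[survivors] = True
        importances = np.zeros(p)
    else:
        gbdt = GradientBoostingClassifier(n_estimators=100, max_depth=3,
                                          learning_rate=0.1, random_state=seed)
        gbdt.fit(values[:, survivors], labels)
        importances = np.zeros(p)
        importances[survivors] = gbdt.feature_importances_
        # rank by importance, chi-square then column index as tie-breaks
        order = sorted(survivors, key=lambda j: (-importances[j], -chi2_scores[j], j))
        mask[order[:k]] = True

    if return_report:
        import pandas as pd
        report = pd.DataFrame({
            "descriptor": DESCRIPTOR_NAMES[:p] if p == len(DESCRIPTOR_NAMES)
            else [f"d{i}" for i in range(p)],
            "variance": values.var(axis=0),
            "chi2": chi2_scores,
            "gbdt_importance": importances,
            "selected": mask,
        })
        return mask, report
    return mask


def morgan_fingerprint(smiles: str, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """Deterministic Morgan (circular) fingerprint as a 0/1 vector."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(nbits)
    for bit in fp.GetOnBits():
        arr[bit] = 1.0
    return arr


def canonical_smiles(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


# --- standardization and the attribute encoder -------------------------

class Standardizer:
    """Z-scoring with statistics frozen on the training split only."""

    def __init__(self):
        self.mean = None
        self.std = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, train_values: np.ndarray) -> "Standardizer":
        train_values = np.asarray(train_values, dtype=float)
        self.mean = train_values.mean(axis=0)
        self.std = train_values.std(axis=0)
        self.std = np.where(self.std < 1e-12, 1.0, self.std)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("Standardizer used before fit: train statistics missing")
        return (np.asarray(values, dtype=float) - self.mean) / self.std


class AttributeEncoder:
    """Two independent one-layer perceptrons fusing descriptors and
    fingerprint into the attribute vector f_P of size d'.

    Each branch outputs d'/2; the concatenation therefore matches the
    encoder hidden size, which the attention-pooling addition requires.
    """

    def __init__(self, n_desc: int, n_bits: int, d_hidden: int, rng):
        if d_hidden % 2:
            raise ValueError("d_hidden must be even")
        half = d_hidden // 2
        self.desc_mlp = Linear(n_desc, half, rng)
        self.fp_mlp = Linear(n_bits, half, rng)
        self.d_out = d_hidden

    def __call__(self, desc_z: Tensor, fingerprint: Tensor) -> Tensor:
        return concat([self.desc_mlp(desc_z), self.fp_mlp(fingerprint)], axis=-1)

    def parameters(self):
        return self.desc_mlp.parameters() + self.fp_mlp.parameters()
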