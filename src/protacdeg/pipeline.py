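"""Dataset assembly, activity labeling, leakage-aware splitting, training,
evaluation, and ablations.

Degradation activity is binarized from the two standard potency
annotations: a PROTAC is *low* activity iff DC50 >= 100 nM and
Dmax < 80%, otherwise *high*.  When only one annotation is present the
conjunction degenerates to the available clause.  Train/test splits are
random 80/20 over labeled entries, after which any test entry sharing
its (POI, canonical SMILES) pair with a training entry is excluded to
prevent leakage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import chem_io, featurize
from .config import TrainConfig
from .egnn import GraphBatch
from .model import DegradationModel
from .nn import Adam

__all__ = [
    "DegradationRecord",
    "SplitManifest",
    "TernaryComplexSample",
    "assign_activity_label",
    "make_split",
    "evaluate",
    "build_samples",
    "FeatureContext",
    "train_supervised",
    "predict_proba",
    "ablation_run",
    "read_manifest",
]

LABEL_TO_INT = {"low": 0, "high": 1}

MANIFEST_COLUMNS = ("entry_id", "smiles", "poi_id", "e3_id",
                    "protac_mol2_path", "poi_structure_path", "e3_structure_path",
                    "dc50_nM", "dmax_pct")


# ---------------------------------------------------------------------------
# records, labels, splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationRecord:
    entry_id: str
    smiles: str
    poi_id: str
    e3_id: str
    dc50: float | None = None   # nM
    dmax: float | None = None   # percent

    @property
    def label(self) -> str:
        return assign_activity_label(self.dc50, self.dmax)


def assign_activity_label(dc50: float | None, dmax: float | None) -> str:
    """Binarize degradation activity from DC50 (nM) and Dmax (%).

    *low* iff DC50 >= 100 nM AND Dmax < 80%; otherwise *high*.  With a
    single annotation present the missing clause is dropped; with both
    missing the entry is *unlabeled*.
    """
    if dc50 is not None:
        if not np.isfinite(dc50) or dc50 < 0:
            raise ValueError(f"invalid DC50: {dc50!r} (must be a nonnegative nM value)")
    if dmax is not None:
        if not np.isfinite(dmax) or not (0 <= dmax <= 100):
            raise ValueError(f"invalid Dmax: {dmax!r} (must be a percentage in [0, 100])")
    if dc50 is None and dmax is None:
        return "unlabeled"
    low = (dc50 is None or dc50 >= 100) and (dmax is None or dmax < 80)
    return "low" if low else "high"


@dataclass
class SplitManifest:
    train_ids: list
    test_ids: list
    excluded_ids: list
    seed: int

    def validate(self, records) -> None:
        sets = [set(self.train_ids), set(self.test_ids), set(self.excluded_ids)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split sets overlap")
        by_id = {r.entry_id: r for r in records}
        train_keys = {(by_id[i].poi_id, featurize.canonical_smiles(by_id[i].smiles))
                      for i in self.train_ids}
        for i in self.test_ids:
            key = (by_id[i].poi_id, featurize.canonical_smiles(by_id[i].smiles))
            if key in train_keys:
                raise ValueError(f"leakage: test entry {i} shares {key} with training set")


def make_split(records, test_fraction: float = 0.2, seed: int = 0) -> SplitManifest:
    """Random split of labeled records, then move leaking test entries
    (same POI and canonical PROTAC SMILES as any train entry) to
    ``excluded_ids``.  Deterministic given ``seed``."""
    labeled = [r for r in records if r.label != "unlabeled"]
    if len(labeled) < 2:
        raise ValueError("need at least two labeled records to split")
    ids = sorted(r.entry_id for r in labeled)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test_ids = [ids[i] for i in perm[:n_test]]
    train_ids = [ids[i] for i in perm[n_test:]]

    by_id = {r.entry_id: r for r in labeled}
    train_keys = {(by_id[i].poi_id, featurize.canonical_smiles(by_id[i].smiles))
                  for i in train_ids}
    kept, excluded = [], []
    for i in test_ids:
        key = (by_id[i].poi_id, featurize.canonical_smiles(by_id[i].smiles))
        (excluded if key in train_keys else kept).append(i)
    if not kept:
        raise ValueError("every test record was excluded as a duplicate; "
                         "try a different split seed")
    manifest = SplitManifest(train_ids=sorted(train_ids), test_ids=sorted(kept),
                             excluded_ids=sorted(excluded), seed=seed)
    manifest.validate(labeled)
    return manifest


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(probabilities, labels, threshold: float = 0.5) -> dict:
    """Accuracy (at 0.5), AUROC (rank statistic, ties get half credit),
    and F1 on the high class."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError("probabilities/labels length mismatch")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: labels contain a single class")
    pred = (p >= threshold).astype(int)
    accuracy = float((pred == y).mean())
    ranks = rankdata(p)
    auroc = float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {"accuracy": accuracy, "auroc": auroc, "f1": float(f1)}


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class TernaryComplexSample:
    """One dataset entry: the three molecule graphs plus PROTAC
    chemistry and (optionally) an activity label."""

    entry_id: str
    graphs: dict                 # entity -> MoleculeGraph
    descriptors: np.ndarray      # the 11 candidate descriptors
    fingerprint: np.ndarray
    label: int | None            # 1=high, 0=low, None=unlabeled
    record: DegradationRecord
    provenance: dict = field(default_factory=dict)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"entry_id": str, "poi_id": str, "e3_id": str})
    missing = set(MANIFEST_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def _float_or_none(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def record_from_row(row) -> DegradationRecord:
    return DegradationRecord(
        entry_id=str(row["entry_id"]), smiles=row["smiles"],
        poi_id=str(row["poi_id"]), e3_id=str(row["e3_id"]),
        dc50=_float_or_none(row.get("dc50_nM")),
        dmax=_float_or_none(row.get("dmax_pct")))


def _pocket_graph(pdb_path, kind: str, config: TrainConfig,
                  ligand_resname: str = "LIG"):
    atoms = chem_io.parse_pdb(pdb_path)
    ligand = [a for a in atoms if a.residue_name == ligand_resname]
    receptor = [a for a in atoms if a.residue_name != ligand_resname]
    if not ligand:
        raise ValueError(f"{pdb_path}: no ligand ({ligand_resname}) found to define pocket")
    pocket = chem_io.extract_pocket(chem_io.PocketSpec(
        ligand_atoms=ligand, receptor_atoms=receptor, cutoff=config.pocket_cutoff))
    if not pocket:
        raise ValueError(f"{pdb_path}: empty pocket at {config.pocket_cutoff} Å")
    return chem_io.build_protein_graph(
        pocket, kind=kind, inter_cutoff=config.inter_residue_cutoff,
        intra_cutoff=config.intra_residue_cutoff,
        provenance={"source": str(pdb_path)})


def build_samples(manifest: pd.DataFrame, config: TrainConfig) -> list:
    """Build :class:`TernaryComplexSample` objects from a manifest.

    PROTAC graphs come from the mol2 path when present, otherwise from
    an embedded SMILES conformer.  Protein graphs are pocket graphs
    around the bound ligand (HETATM residue ``LIG``), cached per
    structure file.
    """
    pocket_cache: dict = {}
    samples = []
    for _, row in manifest.iterrows():
        rec = record_from_row(row)
        mol2 = row.get("protac_mol2_path")
        if isinstance(mol2, str) and mol2:
            protac = chem_io.parse_mol2(mol2)
        else:
            protac = chem_io.smiles_to_graph(rec.smiles)
        graphs = {"PROTAC": protac}
        for ent, col in (("POI", "poi_structure_path"), ("E3", "e3_structure_path")):
            path = row[col]
            if path not in pocket_cache:
                pocket_cache[path] = _pocket_graph(path, ent, config)
            graphs[ent] = pocket_cache[path]
        label = rec.label
        samples.append(TernaryComplexSample(
            entry_id=rec.entry_id, graphs=graphs,
            descriptors=featurize.compute_descriptors(rec.smiles),
            fingerprint=featurize.morgan_fingerprint(
                rec.smiles, radius=config.model.fp_radius, nbits=config.model.fp_bits),
            label=None if label == "unlabeled" else LABEL_TO_INT[label],
            record=rec))
    return samples


class FeatureContext:
    """Descriptor selection + standardization frozen on training data."""

    def __init__(self, selected_mask: np.ndarray, standardizer: featurize.Standardizer,
                 report=None):
        self.selected_mask = selected_mask
        self.standardizer = standardizer
        self.report = report  # per-descriptor selection report (DataFrame)

    @classmethod
    def fit(cls, train_samples, config: TrainConfig, seed: int) -> "FeatureContext":
        desc = np.stack([s.descriptors for s in train_samples])
        labels = np.array([s.label for s in train_samples])
        report = None
        if config.feature_selection:
            mask, report = featurize.select_features(
                desc, labels, k=config.n_selected, seed=seed, return_report=True)
        else:
            mask = np.ones(desc.shape[1], dtype=bool)
        std = featurize.Standardizer().fit(desc[:, mask])
        return cls(mask, std, report)

    @property
    def n_desc(self) -> int:
        return int(self.selected_mask.sum())

    def transform(self, samples) -> tuple:
        desc = np.stack([s.descriptors for s in samples])[:, self.selected_mask]
        fps = np.stack([s.fingerprint for s in samples])
        return self.standardizer.transform(desc), fps


def _batches_for(samples) -> dict:
    return {ent: GraphBatch.from_graphs([s.graphs[ent] for s in samples])
            for ent in ("PROTAC", "POI", "E3")}


def predict_proba(model: DegradationModel, ctx: FeatureContext, samples,
                  chunk: int = 200) -> np.ndarray:
    out = []
    for i in range(0, len(samples), chunk):
        part = samples[i:i + chunk]
        desc_z, fps = ctx.transform(part)
        out.append(model.predict_proba(_batches_for(part), desc_z, fps))
    return np.concatenate(out) if out else np.zeros(0)


# ---------------------------------------------------------------------------
# supervised training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: DegradationModel
    feature_ctx: FeatureContext
    history: list
    metrics: dict


def train_supervised(train_samples, config: TrainConfig, seed: int,
                     test_samples=None, epoch_hook=None,
                     feature_ctx: FeatureContext | None = None) -> TrainResult:
    """Train the classifier on labeled samples.

    Minimizes class-weighted cross-entropy with Adam, carving out a
    validation fraction for early stopping on AUROC.  Fully
    deterministic given ``seed``: split, initialization, and batch order
    all derive from it.  ``epoch_hook(epoch, model, ctx)`` runs after
    every epoch (used by the pseudolabeling loop to record training
    dynamics).
    """
    labeled = [s for s in train_samples if s.label is not None]
    if not labeled:
        raise ValueError("training set has no labeled samples")
    labeled = sorted(labeled, key=lambda s: s.entry_id)

    if feature_ctx is None:
        feature_ctx = FeatureContext.fit(labeled, config, seed)
    ctx = feature_ctx

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labeled))
    n_val = int(round(config.val_fraction * len(labeled)))
    val = [labeled[i] for i in perm[:n_val]]
    fit = [labeled[i] for i in perm[n_val:]]
    val_labels = np.array([s.label for s in val])
    use_val = n_val >= 4 and len(np.unique(val_labels)) == 2

    y_fit = np.array([s.label for s in fit])
    counts = np.bincount(y_fit, minlength=2).astype(float)
    class_weights = len(y_fit) / (2.0 * np.maximum(counts, 1.0))

    model = DegradationModel(config.model, n_desc=ctx.n_desc, seed=seed)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)

    best_state = model.state_arrays()
    best_val = -np.inf
    stale = 0
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(fit))
        epoch_loss = 0.0
        for start in range(0, len(fit), config.batch_size):
            batch = [fit[i] for i in order[start:start + config.batch_size]]
            desc_z, fps = ctx.transform(batch)
            labels = np.array([s.label for s in batch])
            logits, _ = model.forward(_batches_for(batch), desc_z, fps)
            loss = model.loss(logits, labels, class_weights)
            if not np.isfinite(loss.value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (batch starting {start}); "
                    f"lr={config.lr}, batch={len(batch)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value) * len(batch)
        entry = {"epoch": epoch, "loss": epoch_loss / len(fit)}
        if use_val:
            val_probs = predict_proba(model, ctx, val)
            entry["val_auroc"] = evaluate(val_probs, val_labels)["auroc"]
            if entry["val_auroc"] > best_val + 1e-12:
                best_val = entry["val_auroc"]
                best_state = model.state_arrays()
                stale = 0
            else:
                stale += 1
        history.append(entry)
        if epoch_hook is not None:
            epoch_hook(epoch, model, ctx)
        if use_val and stale >= config.patience:
            break
    if use_val and config.epochs > 0:
        model.load_state_arrays(best_state)

    metrics = {}
    if test_samples:
        probs = predict_proba(model, ctx, test_samples)
        metrics = evaluate(probs, np.array([s.label for s in test_samples]))
    return TrainResult(model=model, feature_ctx=ctx, history=history, metrics=metrics)


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------

ABLATION_TOGGLES = ("feature_selection", "attention_pooling",
                    "equivariant_encoder", "label_enrichment")


def ablation_run(train_samples, test_samples, config: TrainConfig, toggles,
                 seed: int = 0, unlabeled_samples=None) -> dict:
    """Metrics for the full model and each requested single-component
    ablation.

    Toggle fallbacks: all 11 descriptors instead of the selected 6;
    mean pooling instead of mutual attention; a coordinate-blind
    encoder instead of the equivariant one; K=0 instead of
    pseudolabeling.
    """
    from copy import deepcopy

    unknown = set(toggles) - set(ABLATION_TOGGLES)
    if unknown:
        raise ValueError(f"unknown ablation toggles: {sorted(unknown)}")

    def run(cfg: TrainConfig) -> dict:
        if cfg.pseudo_k > 0 and unlabeled_samples:
            from .semisup import semisupervised_loop
            res = semisupervised_loop(train_samples, unlabeled_samples, cfg, seed,
                                      test_samples=test_samples)
            return res.result.metrics
        return train_supervised(train_samples, cfg, seed,
                                test_samples=test_samples).metrics

    results = {"full": run(config)}
    for toggle in toggles:
        cfg = deepcopy(config)
        if toggle == "feature_selection":
            cfg.feature_selection = False
        elif toggle == "attention_pooling":
            cfg.model.attention_pooling = False
        elif toggle == "equivariant_encoder":
            cfg.model.geometric = False
        elif toggle == "label_enrichment":
            cfg.pseudo_k = 0
        results[f"no_{toggle}"] = run(cfg)
    return results


def history_to_jsonl(history, path) -> None:
    with open(path, "w") as fh:
        for entry in history:
            fh.write(json.dumps(entry) + "\n")
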