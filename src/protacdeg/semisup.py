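"""Memory-enhanced pseudolabeling for semisupervised training.

The loop pretrains the classifier on the labeled training pool, records
each unlabeled entry's predicted label, logits, and latent embedding
over the final pretraining epochs, and scores every unlabeled entry by

* a *disagreement* score s_dis: the entropy (natural log) of the
  relative class frequencies among its recorded epoch predictions —
  higher means the prediction flipped more across epochs, marking a
  stronger pseudolabeling candidate;
* a *memory* score s_mem: the maximum cosine similarity between the
  entry's latent embedding and a bank of prototype vectors summarizing
  the labeled data's latent space.

The combined score s = (s_dis + s_mem) / 2 ranks the pool; the top-K
entries receive the majority-vote label of their recorded predictions
and are added to the training set for a full retraining from scratch.
The test split never enters any step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import TrainConfig
from .pipeline import TrainResult, predict_proba, train_supervised

__all__ = [
    "PseudolabelRecord",
    "MemoryBank",
    "disagreement_score",
    "init_memory_bank",
    "update_prototypes",
    "memory_score",
    "combined_score",
    "select_pseudolabels",
    "semisupervised_loop",
    "SemisupResult",
]


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def disagreement_score(epoch_labels, n_classes: int = 2) -> float:
    """Entropy of the class frequencies among recorded epoch predictions.

    0 when all epochs agree; ln 2 for a 50/50 split over two classes.
    Natural log; 0·log 0 := 0.
    """
    labels = np.asarray(epoch_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("need at least one recorded epoch")
    freq = np.bincount(labels, minlength=n_classes) / labels.size
    nz = freq[freq > 0]
    return max(0.0, float(-(nz * np.log(nz)).sum()))


@dataclass
class MemoryBank:
    """R unit-norm prototype vectors summarizing labeled embeddings."""

    prototypes: np.ndarray  # (R, d)

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if self.prototypes.ndim != 2 or self.prototypes.shape[0] < 1:
            raise ValueError("need at least one prototype")
        if not np.all(np.isfinite(self.prototypes)):
            raise ValueError("prototypes must be finite")

    @property
    def R(self) -> int:
        return self.prototypes.shape[0]


def init_memory_bank(embeddings: np.ndarray, R: int, seed: int = 0) -> MemoryBank:
    """Prototype initialization by k-means++ seeding on labeled
    embeddings, renormalized to unit norm."""
    from sklearn.cluster import kmeans_plusplus

    embeddings = np.asarray(embeddings, dtype=float)
    R = min(R, embeddings.shape[0])
    centers, _ = kmeans_plusplus(embeddings, n_clusters=R, random_state=seed)
    norms = np.linalg.norm(centers, axis=1, keepdims=True)
    return MemoryBank(prototypes=centers / np.maximum(norms, 1e-12))


def update_prototypes(bank: MemoryBank, labeled_embeddings: np.ndarray) -> MemoryBank:
    """One prototype update from a set of labeled-sample embeddings.

    Soft assignment weights normalize over samples:
    w(i,r) = exp(cos(z_i, u_r)) / sum_i' exp(cos(z_i', u_r)); each
    prototype accumulates its weighted embedding sum and is renormalized
    to unit length (the raw accumulation grows without bound otherwise).
    Zero-norm embeddings are excluded (cosine undefined).
    """
    Z = np.asarray(labeled_embeddings, dtype=float)
    norms = np.linalg.norm(Z, axis=1)
    bad = norms < 1e-12
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} zero-norm embeddings from "
                      "prototype update")
        Z, norms = Z[~bad], norms[~bad]
    if Z.shape[0] == 0:
        return bank
    U = bank.prototypes
    cos = (Z / norms[:, None]) @ (U / np.linalg.norm(U, axis=1, keepdims=True)).T  # (n, R)
    e = np.exp(cos - cos.max(axis=0, keepdims=True))
    W = e / e.sum(axis=0, keepdims=True)  # normalize over samples i
    new = U + W.T @ Z
    new /= np.maximum(np.linalg.norm(new, axis=1, keepdims=True), 1e-12)
    return MemoryBank(prototypes=new)


def memory_score(embedding: np.ndarray, bank: MemoryBank) -> float:
    """Max cosine similarity between the embedding and the prototypes."""
    z = np.asarray(embedding, dtype=float)
    nz = np.linalg.norm(z)
    if nz < 1e-12:
        raise ValueError("memory score undefined for a zero-norm embedding")
    U = bank.prototypes
    cos = U @ z / (np.linalg.norm(U, axis=1) * nz)
    return float(cos.max())


def combined_score(s_dis: float, s_mem: float) -> float:
    return 0.5 * (s_dis + s_mem)


# ---------------------------------------------------------------------------
# records and selection
# ---------------------------------------------------------------------------

@dataclass
class PseudolabelRecord:
    """Training-dynamics record for one unlabeled entry."""

    entry_id: str
    epoch_labels: list            # predicted class per recorded epoch (set M)
    epoch_logits: list            # per-epoch logit pairs
    embedding: np.ndarray         # latent z at the final recorded epoch
    s_dis: float = 0.0
    s_mem: float = 0.0
    s: float = 0.0
    selected: bool = False
    assigned_label: int | None = None

    @property
    def pred_dist(self) -> np.ndarray:
        labels = np.asarray(self.epoch_labels, dtype=int)
        return np.bincount(labels, minlength=2) / labels.size

    def majority_label(self) -> int:
        """Majority vote over epoch predictions; ties break to the
        latest epoch's prediction."""
        freq = np.bincount(np.asarray(self.epoch_labels, dtype=int), minlength=2)
        if freq[0] == freq[1]:
            return int(self.epoch_labels[-1])
        return int(freq.argmax())


def select_pseudolabels(records, K: int) -> list:
    """Top-K records by combined score s; returns (entry_id, label) pairs.

    Ties break on entry_id so selection is invariant to record order.
    K=0 selects nothing; K beyond the pool selects everything with a
    warning.
    """
    if K < 0:
        raise ValueError("K must be nonnegative")
    records = list(records)
    if K > len(records):
        warnings.warn(f"K={K} exceeds {len(records)} available records; selecting all")
        K = len(records)
    ranked = sorted(records, key=lambda r: (-r.s, r.entry_id))
    out = []
    for r in ranked[:K]:
        r.selected = True
        r.assigned_label = r.majority_label()
        out.append((r.entry_id, r.assigned_label))
    return out


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

@dataclass
class SemisupResult:
    result: TrainResult               # final retrained model
    pretrain: TrainResult
    records: list                     # PseudolabelRecord per unlabeled entry
    selected: list                    # (entry_id, label) pairs
    bank: MemoryBank | None = None
    audit: object = None              # DataFrame written by audit export

    def write_audit(self, path) -> None:
        import pandas as pd

        rows = [{
            "entry_id": r.entry_id,
            "epoch_labels": "|".join(map(str, r.epoch_labels)),
            "s_dis": r.s_dis, "s_mem": r.s_mem, "s": r.s,
            "selected": r.selected, "assigned_label": r.assigned_label,
        } for r in self.records]
        pd.DataFrame(rows).to_csv(path, index=False)


def semisupervised_loop(labeled_samples, unlabeled_samples, config: TrainConfig,
                        seed: int, test_samples=None) -> SemisupResult:
    """Pretrain, score the unlabeled pool, pseudolabel top-K, retrain.

    With K=0 or an empty unlabeled pool the final model comes from a
    retraining call identical to plain supervised training under the
    same seed, so results are bit-for-bit the supervised ones.  Only the
    training pools enter any step; ``test_samples`` are used solely for
    final metrics.
    """
    labeled_samples = [s for s in labeled_samples if s.label is not None]
    unlabeled_samples = list(unlabeled_samples)
    K = config.pseudo_k

    records: dict = {}
    epoch_embeddings_labeled: dict = {}  # epoch -> (n_labeled, 3d')

    def hook(epoch, model, ctx):
        if not unlabeled_samples:
            return
        # record unlabeled dynamics
        from .pipeline import _batches_for

        for chunk_start in range(0, len(unlabeled_samples), 200):
            chunk = unlabeled_samples[chunk_start:chunk_start + 200]
            desc_z, fps = ctx.transform(chunk)
            logits, z = model.forward(_batches_for(chunk), desc_z, fps)
            preds = logits.value.argmax(axis=1)
            for s, pred, lg, emb in zip(chunk, preds, logits.value, z.value):
                rec = records.setdefault(s.entry_id, PseudolabelRecord(
                    entry_id=s.entry_id, epoch_labels=[], epoch_logits=[],
                    embedding=emb))
                rec.epoch_labels.append(int(pred))
                rec.epoch_logits.append(lg.tolist())
                rec.embedding = emb
        desc_z, fps = ctx.transform(labeled_samples)
        _, zl = model.forward(_batches_for(labeled_samples), desc_z, fps)
        epoch_embeddings_labeled[epoch] = zl.value

    pretrain = train_supervised(labeled_samples, config, seed,
                                epoch_hook=hook if (unlabeled_samples and K > 0) else None)

    bank = None
    selected: list = []
    rec_list: list = []
    if unlabeled_samples and K > 0:
        # keep only the final t_epochs of the recorded dynamics
        epochs = sorted(epoch_embeddings_labeled)
        kept = epochs[-config.t_epochs:]
        first_kept = len(epochs) - len(kept)
        for rec in records.values():
            rec.epoch_labels = rec.epoch_labels[first_kept:]
            rec.epoch_logits = rec.epoch_logits[first_kept:]

        bank = init_memory_bank(epoch_embeddings_labeled[kept[-1]],
                                R=config.n_prototypes, seed=seed)
        for ep in kept:
            bank = update_prototypes(bank, epoch_embeddings_labeled[ep])

        for rec in records.values():
            rec.s_dis = disagreement_score(rec.epoch_labels)
            if config.invert_disagreement:
                rec.s_dis = np.log(2.0) - rec.s_dis
            rec.s_mem = memory_score(rec.embedding, bank)
            rec.s = combined_score(rec.s_dis, rec.s_mem)
        rec_list = sorted(records.values(), key=lambda r: r.entry_id)
        selected = select_pseudolabels(rec_list, K)

    # assemble the enriched training set and retrain from scratch
    assigned = dict(selected)
    from copy import copy

    enriched = list(labeled_samples)
    for s in unlabeled_samples:
        if s.entry_id in assigned:
            s2 = copy(s)
            s2.label = assigned[s.entry_id]
            enriched.append(s2)

    final = train_supervised(enriched, config, seed, test_samples=test_samples)
    return SemisupResult(result=final, pretrain=pretrain, records=rec_list,
                         selected=selected, bank=bank)
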