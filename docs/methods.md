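# Methods

## Problem

A PROTAC (proteolysis-targeting chimera) degrades a protein of interest
(POI) by recruiting an E3 ubiquitin ligase into a ternary
POI–PROTAC–E3 complex.  The package predicts, from 3D structure,
whether a PROTAC shows *high* or *low* degradation activity.  Activity
is binarized from the standard potency annotations: an entry is **low**
iff DC50 ≥ 100 nM **and** Dmax < 80 %, otherwise **high**; if only one
annotation exists the conjunction degenerates to the available clause,
and with neither the entry is *unlabeled* (eligible for pseudolabeling).

## Inputs and graph construction

Each sample is three attributed 3D molecule graphs:

* **PROTAC** — atoms as nodes, covalent bonds as edges, coordinates from
  a docked mol2 file (or, as a flagged convenience, an ETKDG-embedded
  conformer from SMILES).
* **POI pocket** and **E3 pocket** — all residues with a heavy atom
  within 5 Å of the bound ligand, kept or dropped as whole residues.
  Edges are *intra-residue* (heavy-atom pairs of one residue within
  1.9 Å, a covalent-range distance rule) and *inter-residue* (pairs of
  different residues within 4.5 Å).  The inter-residue cutoff is a
  design choice surfaced in the config; 4.5 Å is a common heavy-atom
  contact definition.

Hydrogens are dropped everywhere (configurable), waters and common ions
are stripped, altLoc duplicates resolve to the highest-occupancy copy
(ties: first listed), and insertion codes fold into residue ordering.
Coordinates stay exactly as stored — no recentering; the encoder is the
only component that touches geometry.

Node features (31 dims): element class one-hot (C, N, O, S, P, halogen,
other), degree, aromatic and in-ring flags, and a residue-type one-hot
for protein atoms.  Edge attributes (7 dims): bond-order / edge-class
one-hot (single, double, triple, aromatic, intra-residue,
inter-residue) plus the interatomic distance.  The attribute vector
contents are a design choice — the architecture only requires that they
are rigid-motion invariant, which element types, bond orders, and
distances are.

## E(3)-equivariant encoder

Each of the L layers updates features and coordinates:

    m_ij = phi_e(a_ij, h_i, h_j, ||x_i − x_j||²)
    x_i ← x_i + Σ_j (x_i − x_j)/(||x_i − x_j|| + ε) · phi_x(m_ij)
    h_i ← phi_h(h_i ‖ Σ_j m_ij)

with ε = 1e-8 guarding coincident atoms.  The coordinate sum is
unnormalized by default; `normalize_coord_update` enables a 1/n_i
(mean-over-neighbors) variant — both are tested against a naive
double-loop oracle.  phi_e, phi_x, phi_h are 2-layer perceptrons with
SiLU activations; phi_x's final layer is zero-initialized so early
coordinate updates are small.  Features touch geometry only through
squared distances and the edge-attribute distance, so node embeddings
are invariant under any rotation, reflection, or translation of the
input, while output coordinates are equivariant; `check_equivariance`
asserts both numerically (≤ 1e-8 in float64).  The three entities use
separate encoder weights (the feature distributions of a small molecule
and two pockets differ; sharing is possible but not default).

The whole stack runs on a small reverse-mode autodiff core over
float64 NumPy arrays, written for this package.  Batches are disjoint
graph unions with segment reductions, so one minibatch is one set of
array ops.  Single-threaded float64 arithmetic makes every run
bit-reproducible from its seed, which the determinism and
ablation-identity tests assert literally.

## Descriptors, selection, and the attribute vector

Eleven candidate physicochemical descriptors (H-bond donors/acceptors,
rotatable bonds, TPSA, molecular weight, cLogP, ring and aromatic-ring
counts, heavy atoms, formal charge, fraction sp3 — RDKit
implementations) are reduced to k = 6 by a two-step selection: (1) drop
near-zero-variance columns and score survivors by chi-square against
the binary label (columns min-max scaled and decile-binned so the
statistic sees nonnegative values); (2) keep the top-k by gradient
boosted tree impurity importance (100 trees, depth 3, learning rate
0.1, fixed seed), chi-square breaking ties.  The 11-descriptor list is
itself config-overridable; it is a reasonable standard panel, not a
canonical set.

Selected descriptors are z-scored on training-split statistics only.
Descriptors and a Morgan fingerprint (radius 2, 2048 bits by default)
pass through two independent one-layer perceptrons whose outputs
(d′/2 each) concatenate into the attribute vector f_P of size d′.
Making the attribute size equal the hidden size is forced by the
pooling formula, which adds f to a d′-sized weighted sum of node
embeddings; any other size would make that addition ill-typed.

## Mutual attention pooling and classification

For each graph, node relevance weights come from the interaction of
node embeddings with the graph's attribute vector:

    q_i = WQ h_i,  k = WK f,  w_i = softmax_i(aᵀ tanh(q_i ‖ k)),
    z = Σ_i w_i h_i + f.

Protein graphs have no chemical descriptors, so f_T and f_E are free
learned d′-vectors — the attention key must exist for the same pooling
to apply to all three graphs.  The final representation is
z = z_P ‖ z_T ‖ z_E, classified by a 2-layer perceptron into two logits
(low/high) with class-weighted cross-entropy (inverse-frequency
weights) and a 0.5 decision threshold.  The per-node weights are
exported as per-edge attention maps ((w_i + w_j)/2) for visualization.
Mean pooling (uniform weights) is the ablation fallback; a
coordinate-blind encoder (no distance input, no coordinate update,
distance attribute zeroed) is the geometry ablation; using all 11
descriptors disables selection; K = 0 disables pseudolabeling.

## Memory-enhanced pseudolabeling

Pretraining on the labeled pool records, for every unlabeled entry,
the predicted label, logits, and fused embedding at each of the final
T = 10 pretraining epochs, and the labeled-pool embeddings at the same
epochs.  Scores:

* **Disagreement** s_dis: entropy (natural log) of the relative class
  frequencies among the recorded epoch predictions.  The method's
  defining choice is that *higher* entropy marks a stronger candidate;
  the conventional confidence-based direction is available as
  `invert_disagreement` (which maps s_dis to ln 2 − s_dis).
* **Memory** s_mem: maximum cosine similarity between the entry's
  final-epoch embedding and R = 4 prototype vectors.  Prototypes are
  initialized by k-means++ seeding on the final-epoch labeled
  embeddings, then updated once per recorded epoch with soft-assignment
  weights that normalize over samples,
  w(i,r) = exp(cos(z_i, u_r)) / Σ_i′ exp(cos(z_i′, u_r)), and
  u_r ← normalize(u_r + Σ_i w(i,r) z_i).  The renormalization is
  required: the raw accumulation grows without bound.

The combined score is s = (s_dis + s_mem)/2, exactly.  The top-K
entries by s (ties broken by entry id, so selection is order-invariant)
receive the majority-vote label of their recorded predictions (ties:
latest epoch), and the model retrains from scratch on the enriched set
under the same seed.  With K = 0 or an empty pool the retraining call
is argument-for-argument the supervised one, so results are
bit-identical to supervised training — the pseudolabeling ablation is
literally the same code path.  Test entries never enter scoring,
selection, or retraining.

## Training

Adam (lr 1e-3, optional decoupled-into-gradient weight decay), batch
size 50, class-weighted cross-entropy, a 10 % validation carve-out from
the training split for early stopping on validation AUROC (patience
20), best-validation weights restored.  All randomness — split,
initialization, batch order — derives from one seed.  Splits are
random 80/20 over labeled entries; any test entry sharing
(POI id, canonical SMILES) with a training entry moves to an excluded
list.  Metrics are accuracy at 0.5, AUROC as the rank statistic with
half credit for ties, and F1 on the high class; all three are
cross-checked against scikit-learn to 1e-9.

## Synthetic data: what it emulates and what it does not

The generator emits complete datasets — mol2 PROTACs, PDB pockets with
a bound ligand, a manifest with DC50/Dmax columns — from one seed, with
byte-identical reruns.  Molecules are worm-like heavy-atom chains
(path backbone plus occasional short ring closures) whose per-molecule
bond step (1.3–1.9 Å) emulates conformer compactness, so the global
extent of the molecule is recoverable from the local distances a
message-passing encoder actually sees.  Pockets place residues on a
near shell (< 5 Å of the ligand) or far shell, with the planted inside
count recorded for pocket-rule tests.

The planted activity score is
signal_strength · (z_geom + z_tpsa)/√2 + noise, where z_geom
standardizes the PROTAC's mean pairwise atom distance and z_tpsa its
TPSA; labels threshold the score at the 1 − label_balance quantile, and
DC50/Dmax annotations are drawn on the matching side of the activity
rule so labeling recovers the planted label exactly.  Defaults
(600 samples, signal_strength 3, noise 1) put the Bayes ceiling near
AUROC 0.96 and the locally-visible ceiling near 0.95, so a correctly
implemented model can reach the required learning-sanity level
while label noise keeps the task non-degenerate.

These fixtures establish that the pipeline learns a planted
3D-geometry + descriptor signal end to end.  They do not emulate real
PROTAC chemistry: valences are not enforced, pocket residues are random
shells, the protein graphs carry no signal, and the SMILES column (used
for descriptors/fingerprints) is generated independently of the 3D
conformer.  Passing tests therefore validate the machinery, not
real-data accuracy.

## Problem sizes in tests and the acceptance script

Training-based checks use a down-scaled architecture (d′ = 32,
attention size 16, L = 2, 256 fingerprint bits) on the full-size
planted datasets (500 train / 100 test for supervised learning; 10 %
labeled + 90 % unlabeled pools for the semisupervised comparison over
5 seeds).  The architecture scale is the package's own choice for its
test suite; library defaults remain d′ = 128, attention 64, L = 3,
2048 bits.

## Known limitations

* No docking and no structure prediction: structures are consumed, not
  produced; SMILES-only conformers are flagged non-canonical.
* The mol2 reader covers the ATOM/BOND sections it needs, not the full
  TRIPOS spec; the PDB reader covers fixed-column ATOM/HETATM records.
* Benchmark accuracy on real PROTAC corpora (e.g., PROTAC-DB) is out of
  scope here; measuring it requires the external corpus, an upstream
  docking pipeline, and full-scale training.
* Preferring high-disagreement entries for pseudolabeling is unusual
  relative to confidence-based selection; both directions are
  implemented, and the high-disagreement direction is the default.
  A measured consequence on the planted-signal data: the selected
  top-K's majority-vote labels are *less* accurate than the unselected
  pool's (≈0.6 vs ≈0.75) — even though the enriched retraining still
  improves median test AUROC.  Two mechanisms stack: the disagreement
  term targets entries whose predictions flip most, and the memory term
  also favors uncertain entries, because the prototypes summarize
  class-mixed labeled embeddings and therefore sit centrally in latent
  space, closest to boundary-region samples.  Inverting the
  disagreement direction alone does not reliably restore the
  conventional precision ordering for the same reason.
* Because selected pseudolabels are that noisy, the semisupervised
  AUROC gain on the planted-signal conditions is modest (≈ +0.03 median
  over five training seeds at the suite's study conditions) and is not
  robust across dataset realizations — on some generator seeds the
  median comparison ties or reverses.  The acceptance script recomputes
  both medians for whatever seed it is given and reports them as
  measured.
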