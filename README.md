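# protacdeg

Predicting PROTAC-mediated target degradation from 3D structure.

PROTACs (proteolysis-targeting chimeras) are heterobifunctional
molecules — warhead, linker, E3-ligase ligand — that recruit an E3
ubiquitin ligase to a protein of interest (POI) and route it to the
proteasome.  Given the 3D structures of the PROTAC, the POI binding
pocket, and the E3 binding pocket, this package classifies degradation
activity as *high* or *low* (low iff DC50 ≥ 100 nM and Dmax < 80 %).

The model is an E(3)-equivariant graph network with mutual attention
pooling and a memory-enhanced pseudolabeling loop for semisupervised
training:

* **Encoder** (per entity): L message-passing layers with
  `m_ij = φ_e(a_ij, h_i, h_j, ‖x_i−x_j‖²)`, coordinate updates
  `x_i ← x_i + Σ_j (x_i−x_j)/(‖x_i−x_j‖+ε)·φ_x(m_ij)`, and feature
  updates `h_i ← φ_h(h_i ‖ Σ_j m_ij)`.  Node embeddings are invariant
  and coordinates equivariant under all rigid motions and reflections,
  checked numerically to 1e-8.
* **Pooling**: `w_i = softmax_i(aᵀ tanh(W_Q h_i ‖ W_K f))`,
  `z = Σ w_i h_i + f`, with the attribute vector `f` built from six
  selected physicochemical descriptors plus a Morgan fingerprint
  (PROTAC) or learned free vectors (proteins).  The ternary embedding
  is `z_P ‖ z_T ‖ z_E` → 2-layer head → P(high).
* **Pseudolabeling**: rank unlabeled entries by
  `s = (s_dis + s_mem)/2` — prediction-flip entropy across the last
  pretraining epochs plus max cosine similarity to labeled-latent
  prototypes — pseudolabel the top K by majority vote, retrain from
  scratch.

Everything runs on plain NumPy (float64, bit-reproducible from a seed)
via a small built-in reverse-mode autodiff core; RDKit handles
chemistry, scikit-learn the feature selection.

## Worked example

```python
import tempfile
import numpy as np

from protacdeg.synthetic import SyntheticConfig, planted_signal_dataset
from protacdeg import pipeline
from protacdeg.config import TrainConfig, ModelConfig

# a self-contained dataset: mol2 PROTACs, PDB pockets, DC50/Dmax labels
out = tempfile.mkdtemp()
manifest, truth = planted_signal_dataset(SyntheticConfig(n_samples=600, seed=1), out)

cfg = TrainConfig(model=ModelConfig(d_hidden=24, d_attention=12,
                                    n_layers=2, fp_bits=128),
                  epochs=200, lr=1e-3, weight_decay=3e-4,
                  patience=60, val_fraction=0.15)
samples = pipeline.build_samples(manifest, cfg)
split = pipeline.make_split([s.record for s in samples], test_fraction=1/6, seed=1)
by_id = {s.entry_id: s for s in samples}
train = [by_id[i] for i in split.train_ids]
test = [by_id[i] for i in split.test_ids]

result = pipeline.train_supervised(train, cfg, seed=1, test_samples=test)
print(result.metrics)
```

Output of this exact run (other seeds vary by a few points):

```
{'accuracy': 0.778, 'auroc': 0.954, 'f1': 0.788}
```

AUROC 0.95 against a Bayes ceiling of ≈ 0.99 on this generator means
the model recovered most of the planted 3D-geometry + descriptor
signal; accuracy is measured at the fixed 0.5 probability threshold,
which is stricter than the ranking metric when probabilities are
miscalibrated.

The same flow is available from the shell:

```bash
protacdeg simulate data/ --n-samples 600 --seed 1
protacdeg train data/manifest.csv model.npz --seed 0
protacdeg predict data/manifest.csv model.npz predictions.csv
protacdeg explain data/manifest.csv model.npz attention.csv
protacdeg ablate data/manifest.csv
```

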