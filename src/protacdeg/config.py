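"""Configuration objects (YAML-serializable) for the model and training."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    d_hidden is the encoder hidden size d' (also the attribute-vector
    size, required by the pooling addition); d_attention the attention
    projection size; n_layers the number of equivariant layers.
    ``geometric=False`` and ``attention_pooling=False`` are the ablation
    switches (coordinate-blind encoder, mean pooling).
    """

    d_hidden: int = 128
    d_attention: int = 64
    n_layers: int = 3
    fp_bits: int = 2048
    fp_radius: int = 2
    geometric: bool = True
    attention_pooling: bool = True
    normalize_coord_update: bool = False  # 1/n_i variant of the coordinate sum

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        names = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


@dataclass
class TrainConfig:
    """Training, data-preparation, and semisupervised hyperparameters."""

    model: ModelConfig = field(default_factory=ModelConfig)
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 50
    epochs: int = 200
    patience: int = 20        # early stopping on validation AUROC
    val_fraction: float = 0.1  # carve-out from the training split
    n_selected: int = 6        # descriptors kept by feature selection
    feature_selection: bool = True
    # structure preparation
    pocket_cutoff: float = 5.0       # Å, ligand-to-residue pocket rule
    inter_residue_cutoff: float = 4.5  # Å
    intra_residue_cutoff: float = 1.9  # Å
    # memory-enhanced pseudolabeling
    pseudo_k: int = 0          # top-K pseudolabels added (0 = supervised)
    n_prototypes: int = 4      # R
    t_epochs: int = 10         # number of final pretraining epochs recorded
    invert_disagreement: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        model = ModelConfig.from_dict(d.pop("model", {}))
        names = {f.name for f in fields(cls)} - {"model"}
        return cls(model=model, **{k: v for k, v in d.items() if k in names})

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
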