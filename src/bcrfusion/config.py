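"""Structured run configuration (YAML) shared by the CLI and the scripts."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .synthetic import PhantomParams
from .training import TrainConfig

__all__ = ["RunConfig", "desk_config", "load_config", "save_config"]


@dataclass
class RunConfig:
    phantom: PhantomParams = field(default_factory=PhantomParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    margin_mm: float = 5.0
    variants: tuple[str, ...] = ("itr", "ptr", "ppr", "combined")
    include_clinical: bool = False
    augment: bool = True

    def to_dict(self) -> dict:
        d = {
            "phantom": asdict(self.phantom),
            "model": self.model.to_dict(),
            "train": asdict(self.train),
            "margin_mm": self.margin_mm,
            "variants": list(self.variants),
            "include_clinical": self.include_clinical,
            "augment": self.augment,
        }
        for key in ("grid_shape", "spacing", "prostate_semiaxis_mm", "tumor_radius_mm"):
            d["phantom"][key] = list(d["phantom"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        ph = d.get("phantom", {})
        for key in ("grid_shape", "spacing", "prostate_semiaxis_mm", "tumor_radius_mm"):
            if key in ph:
                ph[key] = tuple(ph[key])
        return cls(
            phantom=PhantomParams(**ph),
            model=ModelConfig.from_dict(d.get("model", {})),
            train=TrainConfig(**d.get("train", {})),
            margin_mm=float(d.get("margin_mm", 5.0)),
            variants=tuple(d.get("variants", ("itr", "ptr", "ppr", "combined"))),
            include_clinical=bool(d.get("include_clinical", False)),
            augment=bool(d.get("augment", True)),
        )


def desk_config(seed: int = 0, n_patients: int = 120) -> RunConfig:
    """CPU-scale configuration: tiny backbone, 64-px inputs, 8 slices, a
    small transformer, 3-fold CV repeated once, 15 epochs."""
    return RunConfig(
        phantom=PhantomParams(n_patients=n_patients, seed=seed),
        model=ModelConfig(backbone="tiny", input_size=64, n_slices=8,
                          transformer_layers=2, transformer_heads=4,
                          model_dim=64, d_emb=8, freeze_prefix=0),
        train=TrainConfig(lr0=3e-4, batch_size=8, max_epochs=15, patience=10,
                          k=3, repeats=2, seed=seed),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path
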