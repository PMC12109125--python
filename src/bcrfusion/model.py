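"""The multi-region, multi-sequence CNN–transformer fusion network.

Architecture, per axial position of a patient:

1. a *shared* dual-channel CNN slice encoder (an 18-layer residual network,
   or a lighter residual "tiny" variant for CPU-scale work) maps each
   region's (H, W, 2) slice to a feature map of shape (C_I, h, w);
2. the per-region maps are fused by channel concatenation in the fixed
   order ITR, PTR, PPR;
3. a learned axial-position embedding table (one (h, w) plane per slice
   position) is added, broadcast across channels, restoring through-plane
   context lost in the 3D-to-2D conversion;
4. the encoded clinical vector is linearly mapped to D_emb values, each
   replicated over the (h, w) plane, and concatenated along channels;
5. the fused map is read as S = h·w tokens of width C_total, linearly
   projected to the transformer model dimension, summed with learned
   positional embeddings, passed through a stack of transformer encoder
   layers, mean-pooled over tokens, and mapped by a fully connected layer
   to a scalar slice score r_i;
6. the per-patient score vector R = (r_1 … r_N) (padding positions forced
   to zero) passes through a final fully connected layer + sigmoid to give
   the patient recurrence probability.

Training minimises binary cross-entropy between patient probabilities and
recurrence labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .preprocessing import ClinicalVector, SlicePair

__all__ = [
    "ModelConfig",
    "PredictionResult",
    "PatientInput",
    "FusionNet",
    "ClinicalMLP",
    "adapt_first_conv",
    "slice_encode",
    "add_axial_embedding",
    "expand_clinical",
    "fuse",
    "transformer_slice_head",
    "aggregate_patient",
    "bce_loss",
    "forward_patient",
    "save_checkpoint",
    "load_checkpoint",
]

_BACKBONES = {
    # name -> (downsampling factor, output channels)
    "resnet18": (32, 512),
    "tiny": (16, 64),
}

_EPS = 1e-7  # probability clamp inside the loss


@dataclass
class ModelConfig:
    backbone: str = "resnet18"
    input_size: int = 224
    n_slices: int = 8
    regions: tuple[str, ...] = ("ITR", "PTR", "PPR")
    use_clinical: bool = False
    d_cli: int = 6
    d_emb: int = 16
    transformer_layers: int = 4
    transformer_heads: int = 8
    model_dim: int = 256
    ffn_dim: int | None = None
    dropout: float = 0.1
    freeze_prefix: int = 2
    pretrained: bool = False

    def __post_init__(self):
        if self.backbone not in _BACKBONES:
            raise ValueError(f"unknown backbone '{self.backbone}'")
        if not self.regions:
            raise ValueError("at least one region must be configured")
        self.regions = tuple(r.upper() for r in self.regions)
        if self.model_dim % self.transformer_heads:
            raise ValueError(
                f"model_dim {self.model_dim} not divisible by heads {self.transformer_heads}"
            )
        factor, _ = _BACKBONES[self.backbone]
        if self.input_size % factor:
            raise ValueError(
                f"input_size {self.input_size} not divisible by backbone factor {factor}"
            )

    @property
    def feature_hw(self) -> int:
        factor, _ = _BACKBONES[self.backbone]
        return self.input_size // factor

    @property
    def encoder_channels(self) -> int:
        return _BACKBONES[self.backbone][1]

    @property
    def n_tokens(self) -> int:
        return self.feature_hw * self.feature_hw

    @property
    def fused_channels(self) -> int:
        c = len(self.regions) * self.encoder_channels
        if self.use_clinical:
            c += self.d_emb
        return c

    def to_dict(self) -> dict:
        return {
            "backbone": self.backbone, "input_size": self.input_size,
            "n_slices": self.n_slices, "regions": list(self.regions),
            "use_clinical": self.use_clinical, "d_cli": self.d_cli,
            "d_emb": self.d_emb, "transformer_layers": self.transformer_layers,
            "transformer_heads": self.transformer_heads, "model_dim": self.model_dim,
            "ffn_dim": self.ffn_dim, "dropout": self.dropout,
            "freeze_prefix": self.freeze_prefix, "pretrained": self.pretrained,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "regions" in d:
            d["regions"] = tuple(d["regions"])
        return cls(**d)


@dataclass
class PredictionResult:
    slice_scores: np.ndarray
    patient_prob: float
    patient_id: str = ""

    def __post_init__(self):
        if not (0.0 <= self.patient_prob <= 1.0):
            raise ValueError(f"patient_prob must be in [0, 1], got {self.patient_prob}")
        if not np.all(np.isfinite(self.slice_scores)):
            raise ValueError("slice scores must be finite")


@dataclass
class PatientInput:
    """Model-ready inputs for one patient: per-region slice stacks plus the
    encoded clinical vector."""

    patient_id: str
    slices: dict[str, list[SlicePair]]  # region -> n_slices SlicePairs
    clinical: ClinicalVector | None = None

    def stack(self, regions: tuple[str, ...], augment_fn=None) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, pad) with x of shape (R, N, 2, H, W) and pad of shape
        (N,), where pad marks positions at which every region is padding."""
        per_region = []
        pad = None
        for r in regions:
            if r not in self.slices:
                raise KeyError(f"patient {self.patient_id}: missing region input '{r}'")
            sps = self.slices[r]
            if augment_fn is not None:
                sps = [augment_fn(sp) for sp in sps]
            arr = np.stack([sp.pixels for sp in sps]).astype(np.float32)
            per_region.append(arr)
            flags = np.array([sp.is_padding for sp in sps], dtype=bool)
            pad = flags if pad is None else (pad & flags)
        return np.stack(per_region), pad


# ---------------------------------------------------------------------------
# backbones


class _BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.down = None
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch),
            )

    def forward(self, x):
        identity = x if self.down is None else self.down(x)
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        return (out + identity).relu()


class ResNet18Encoder(nn.Module):
    """18-layer residual slice encoder with a dual-channel stem;
    maps (B, 224, 224, 2) -> (B, 7, 7, 512)."""

    def __init__(self, rng, in_ch: int = 2):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Conv2d(in_ch, 64, 7, stride=2, padding=3, bias=False, rng=rng),
            nn.BatchNorm2d(64),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, padding=1),
        )
        def stage(ic, oc, stride):
            return nn.Sequential(_BasicBlock(ic, oc, stride, rng),
                                 _BasicBlock(oc, oc, 1, rng))
        self.stage1 = stage(64, 64, 1)
        self.stage2 = stage(64, 128, 2)
        self.stage3 = stage(128, 256, 2)
        self.stage4 = stage(256, 512, 2)

    @property
    def stages(self):
        return [self.stem, self.stage1, self.stage2, self.stage3, self.stage4]

    def forward(self, x):
        for s in self.stages:
            x = s(x)
        return x


class TinyEncoder(nn.Module):
    """Light residual encoder for CPU-scale runs;
    maps (B, 64, 64, 2) -> (B, 4, 4, 64)."""

    def __init__(self, rng, in_ch: int = 2):
        super().__init__()
        self.stem = nn.Sequential(
            nn.Conv2d(in_ch, 16, 4, stride=4, padding=0, bias=False, rng=rng),
            nn.BatchNorm2d(16),
            nn.ReLU(),
        )
        self.stage1 = nn.Sequential(_BasicBlock(16, 32, 2, rng))
        self.stage2 = nn.Sequential(_BasicBlock(32, 64, 2, rng))

    @property
    def stages(self):
        return [self.stem, self.stage1, self.stage2]

    def forward(self, x):
        for s in self.stages:
            x = s(x)
        return x


def make_encoder(cfg: ModelConfig, rng) -> nn.Module:
    enc = ResNet18Encoder(rng) if cfg.backbone == "resnet18" else TinyEncoder(rng)
    for stage in enc.stages[: cfg.freeze_prefix]:
        stage.freeze()
    return enc


def adapt_first_conv(rgb_kernels: np.ndarray, bias: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray | None]:
    """Convert RGB first-layer kernels to dual-channel kernels.

    The three input-channel kernels of each filter are averaged and the mean
    duplicated into both new input channels; the bias is unchanged.  A
    two-channel input whose channels both equal image x then produces 2/3 of
    the original pre-bias response to the RGB-replicated x.
    """
    rgb_kernels = np.asarray(rgb_kernels)
    if rgb_kernels.ndim != 4 or rgb_kernels.shape[1] != 3:
        raise ValueError(
            f"expected kernels of shape (out, 3, kh, kw), got {rgb_kernels.shape}"
        )
    mean = rgb_kernels.mean(axis=1, keepdims=True)
    return np.repeat(mean, 2, axis=1), bias


class TransformerSliceHead(nn.Module):
    """Token projection + positional embedding + transformer stack + slice FC.

    The fused (C_total, h, w) map is read as S = h·w spatial tokens of width
    C_total, projected to the model dimension, combined with learned
    positional embeddings, encoded, mean-pooled over tokens, and mapped to a
    scalar slice score.  Transformer weights are Xavier-uniform initialised.
    """

    def __init__(self, c_total: int, n_tokens: int, model_dim: int, layers: int,
                 heads: int, ffn_dim: int | None, dropout_p: float, rng):
        super().__init__()
        self.n_tokens = n_tokens
        ffn_dim = ffn_dim or 2 * model_dim
        self.proj = nn.Linear(c_total, model_dim, rng, init="xavier")
        self.pos = nn.Parameter(
            (0.02 * rng.standard_normal((n_tokens, model_dim))).astype(np.float32))
        self.layers = [
            nn.TransformerEncoderLayer(model_dim, heads, ffn_dim, dropout_p, rng)
            for _ in range(layers)
        ]
        self.fc = nn.Linear(model_dim, 1, rng, init="xavier")

    def forward(self, f: Tensor) -> Tensor:
        """f: (B, h, w, C_total) -> slice scores (B,)."""
        B, h, w, C = f.shape
        tokens = f.reshape(B, h * w, C)  # (B, S, C)
        x = self.proj(tokens) + self.pos
        for layer in self.layers:
            x = layer(x)
        pooled = x.mean(axis=1)  # (B, D)
        return self.fc(pooled).reshape(B)


class FusionNet(nn.Module):
    """The full patient-level network (shared encoder + fusion + heads)."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = make_encoder(cfg, rng)
        hw = cfg.feature_hw
        self.axial = nn.Parameter(
            (0.02 * rng.standard_normal((cfg.n_slices, hw, hw))).astype(np.float32))
        self.clin_lin = (nn.Linear(cfg.d_cli, cfg.d_emb, rng, init="xavier")
                         if cfg.use_clinical else None)
        self.head = TransformerSliceHead(
            cfg.fused_channels, cfg.n_tokens, cfg.model_dim, cfg.transformer_layers,
            cfg.transformer_heads, cfg.ffn_dim, cfg.dropout, rng)
        self.agg = nn.Linear(cfg.n_slices, 1, rng, init="xavier")

    def _fuse(self, x: Tensor, clinical: Tensor | None) -> Tensor:
        """x: (B, R, N, H, W, 2) -> fused per-position maps (B*N, h, w, C_total)."""
        B, R, N, H, W, C2 = x.shape
        cfg = self.cfg
        feats = self.encoder(x.reshape(B * R * N, H, W, C2))  # (BRN, h, w, C)
        _, h, w, C = feats.shape
        feats = feats.reshape(B, R, N, h, w, C).transpose(0, 2, 3, 4, 1, 5)
        fused = feats.reshape(B, N, h, w, R * C)
        fused = fused + self.axial.reshape(1, N, h, w, 1)
        if cfg.use_clinical:
            if clinical is None:
                raise ValueError("config uses clinical data but none was supplied")
            emb = self.clin_lin(clinical)  # (B, d_emb)
            plane = emb.reshape(B, 1, 1, 1, cfg.d_emb) * np.ones(
                (1, N, h, w, 1), dtype=np.float32)
            fused = nn.concat([fused, plane], axis=4)
        return fused.reshape(B * N, h, w, cfg.fused_channels)

    def forward(self, x: Tensor, pad: np.ndarray, clinical: Tensor | None = None) -> Tensor:
        """x: (B, R, N, H, W, 2); pad: (B, N) bool; clinical: (B, D_cli).

        Returns patient probabilities (B,).
        """
        B, R, N = x.shape[:3]
        r = self.head(self._fuse(x, clinical)).reshape(B, N)
        keep = (~pad).astype(np.float32)
        r = r * keep  # padded positions contribute zeros to the aggregator
        return self.agg(r).reshape(B).sigmoid()

    def slice_scores(self, x: Tensor, pad: np.ndarray,
                     clinical: Tensor | None = None) -> np.ndarray:
        """Per-slice scores R = (r_1 … r_N) for one batch, padding zeroed."""
        B, R, N = x.shape[:3]
        r = self.head(self._fuse(x, clinical)).reshape(B, N)
        return r.data * (~pad)


class ClinicalMLP(nn.Module):
    """Clinical-only baseline: a two-layer perceptron D_cli -> 16 -> 1."""

    def __init__(self, d_cli: int, seed: int = 0, hidden: int = 16):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(d_cli, hidden, rng, init="xavier")
        self.fc2 = nn.Linear(hidden, 1, rng, init="xavier")

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu()).reshape(x.shape[0]).sigmoid()


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: FusionNet, path) -> None:
    """Single-file weight archive carrying the exact ModelConfig."""
    import json

    state = model.state_dict()
    np.savez_compressed(path, __config__=json.dumps(model.cfg.to_dict()), **state)


def load_checkpoint(path) -> FusionNet:
    import json

    with np.load(path, allow_pickle=False) as archive:
        cfg = ModelConfig.from_dict(json.loads(str(archive["__config__"])))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model = FusionNet(cfg, seed=0)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# loss


def bce_loss(probs, labels) -> float | Tensor:
    """Binary cross-entropy −(1/N) Σ [y·log ŷ + (1−y)·log(1−ŷ)], with the
    probabilities clamped to [eps, 1−eps] for numerical safety."""
    if isinstance(probs, Tensor):
        y = np.asarray(labels, dtype=probs.dtype)
        if probs.shape[0] != y.shape[0]:
            raise ValueError(f"length mismatch: {probs.shape[0]} probs, {len(y)} labels")
        p = probs.clip(_EPS, 1.0 - _EPS)
        terms = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p + 0.0).log()
        return -terms.mean()
    p = np.clip(np.asarray(probs, dtype=float), _EPS, 1.0 - _EPS)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} probs, {y.shape} labels")
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


# ---------------------------------------------------------------------------
# functional views of the individual architecture pieces (channel-last
# (W, H, C) feature maps, matching the in-memory FeatureMap convention)


def slice_encode(sp: SlicePair, model: FusionNet) -> np.ndarray:
    """Encode one slice pair through the shared encoder -> (h, w, C_I)."""
    cfg = model.cfg
    if sp.pixels.shape[:2] != (cfg.input_size, cfg.input_size):
        raise ValueError(
            f"slice shape {sp.pixels.shape[:2]} != configured input "
            f"{(cfg.input_size, cfg.input_size)}"
        )
    model.eval()
    with nn.no_grad():
        out = model.encoder(Tensor(sp.pixels[None].astype(np.float32)))
    return out.data[0]


def add_axial_embedding(f: np.ndarray, axial_index: int, table: np.ndarray) -> np.ndarray:
    """f: (h, w, C); table: (n_slices, h, w) broadcast along channels."""
    table = np.asarray(table)
    if not (0 <= axial_index < table.shape[0]):
        raise IndexError(f"axial_index {axial_index} out of range [0, {table.shape[0]})")
    if table.shape[1:] != f.shape[:2]:
        raise ValueError(f"table plane {table.shape[1:]} != feature plane {f.shape[:2]}")
    return f + table[axial_index][:, :, None]


def expand_clinical(cv: ClinicalVector, w_i: int, h_i: int,
                    transform: np.ndarray) -> np.ndarray:
    """Linear map D_cli -> D_emb, then replicate each value over the plane."""
    transform = np.asarray(transform)
    if transform.shape[1] != len(cv.values):
        raise ValueError(
            f"transform expects {transform.shape[1]} inputs, vector has {len(cv.values)}"
        )
    emb = transform @ cv.values  # (D_emb,)
    return np.broadcast_to(emb, (w_i, h_i, emb.shape[0])).copy()


def fuse(region_maps: dict[str, np.ndarray],
         clinical_map: np.ndarray | None = None,
         regions: tuple[str, ...] = ("ITR", "PTR", "PPR")) -> np.ndarray:
    """Channel concatenation in the fixed order ITR, PTR, PPR, clinical."""
    maps = []
    shape = None
    for r in regions:
        if r not in region_maps:
            raise KeyError(f"missing region feature map '{r}'")
        m = region_maps[r]
        if shape is None:
            shape = m.shape[:2]
        elif m.shape[:2] != shape:
            raise ValueError(f"spatial extent mismatch: {m.shape[:2]} vs {shape}")
        maps.append(m)
    if clinical_map is not None:
        if clinical_map.shape[:2] != shape:
            raise ValueError(
                f"clinical map extent {clinical_map.shape[:2]} != {shape}")
        maps.append(clinical_map)
    return np.concatenate(maps, axis=-1)


def transformer_slice_head(f: np.ndarray, head: TransformerSliceHead) -> float:
    """Run one fused (h, w, C_total) map through the transformer head."""
    head.eval()
    with nn.no_grad():
        r = head(Tensor(np.asarray(f)[None].astype(np.float32)))
    val = float(r.data[0])
    if not np.isfinite(val):
        raise FloatingPointError("non-finite slice score from transformer head")
    return val


def aggregate_patient(r: np.ndarray, pad: np.ndarray,
                      weights: np.ndarray, bias: float) -> float:
    """FC over the slice-score vector followed by a sigmoid."""
    r = np.asarray(r, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if r.shape != weights.shape:
        raise ValueError(f"length mismatch: scores {r.shape}, weights {weights.shape}")
    r = np.where(np.asarray(pad, dtype=bool), 0.0, r)
    return float(1.0 / (1.0 + np.exp(-(weights @ r + bias))))


def forward_patient(model: FusionNet, patient: PatientInput) -> PredictionResult:
    """Full eval-mode forward pass for one patient."""
    cfg = model.cfg
    x, pad = patient.stack(cfg.regions)
    clin = None
    if cfg.use_clinical:
        if patient.clinical is None:
            raise ValueError(f"patient {patient.patient_id}: clinical vector required")
        clin = Tensor(patient.clinical.values[None].astype(np.float32))
    model.eval()
    with nn.no_grad():
        xt = Tensor(x[None])
        prob = model(xt, pad[None], clin)
        scores = model.slice_scores(xt, pad[None], clin)
    return PredictionResult(slice_scores=scores[0], patient_prob=float(prob.data[0]),
                            patient_id=patient.patient_id)
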