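"""Configuration dataclasses for data generation, model architecture and training.

Every experiment is fully described by an :class:`ExperimentConfig`, which
round-trips losslessly through YAML.  Validation is eager: constructing an
invalid config raises :class:`ConfigError` naming the offending field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

VARIANT_NAMES = ("cnn_only", "vit_only", "static_concat", "adaptive_no_sarm", "full_adsaf")

#: Variants that contain the adaptive fusion gate (and hence may carry lambda > 0).
GATED_VARIANTS = ("adaptive_no_sarm", "full_adsaf")


class ConfigError(ValueError):
    """Raised when a configuration field violates its contract."""


@dataclass
class DomainShiftParams:
    """Simulated acquisition-domain change: gamma contrast warp + extra noise."""

    gamma: float = 1.0
    extra_noise_std: float = 0.0

    def validate(self) -> None:
        if self.gamma <= 0:
            raise ConfigError(f"domain_shift.gamma must be > 0, got {self.gamma}")
        if self.extra_noise_std < 0:
            raise ConfigError(
                f"domain_shift.extra_noise_std must be >= 0, got {self.extra_noise_std}"
            )


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic lung-image generator.

    ``regime`` selects how the class signal is encoded:

    * ``local`` — class 1 carries a small zero-mean, band-limited speckle
      lesion inside the elliptical lung field (fine local texture).
    * ``global`` — classes differ only in the direction of a diffuse
      large-scale intensity gradient (global layout); local texture
      statistics are matched between classes.
    * ``mixed`` — each image independently draws one of the two signal types
      with probability ``mixed_local_fraction`` for the local type.
    """

    n_subjects: int = 20
    images_per_subject: int = 10
    image_size: int = 64
    regime: str = "local"
    mixed_local_fraction: float = 0.5
    lesion_size: int = 9
    lesion_contrast: float = 0.25
    diffuse_gradient_strength: float = 0.15
    subject_offset_std: float = 0.02
    background_noise_std: float = 0.03
    n_classes: int = 2
    domain_shift: Optional[DomainShiftParams] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.images_per_subject < 1:
            raise ConfigError(f"images_per_subject must be >= 1, got {self.images_per_subject}")
        if self.image_size < 16:
            raise ConfigError(f"image_size must be >= 16, got {self.image_size}")
        if self.regime not in ("local", "global", "mixed"):
            raise ConfigError(f"regime must be one of local/global/mixed, got {self.regime!r}")
        if not 0.0 <= self.mixed_local_fraction <= 1.0:
            raise ConfigError(
                f"mixed_local_fraction must lie in [0, 1], got {self.mixed_local_fraction}"
            )
        if not 1 <= self.lesion_size < self.image_size:
            raise ConfigError(
                f"lesion_size must lie in [1, image_size), got {self.lesion_size}"
            )
        for name in ("lesion_contrast", "diffuse_gradient_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("subject_offset_std", "background_noise_std"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if not 2 <= self.n_classes <= 4:
            raise ConfigError(f"n_classes must be in {{2, 3, 4}}, got {self.n_classes}")
        if self.domain_shift is not None:
            self.domain_shift.validate()


@dataclass
class StreamConfig:
    """Architecture of the two feature streams and their common output grid.

    The CNN stream is ``cnn_blocks`` stride-``s`` conv+ReLU stages whose last
    stage outputs ``common_channels``; the ViT stream is a pre-norm
    transformer over non-overlapping ``patch_size`` patches, later projected
    to ``common_channels`` and resized onto the CNN grid.
    """

    common_channels: int = 128
    cnn_blocks: tuple = ((32, 2), (64, 2), (128, 2), (128, 2))
    patch_size: int = 8
    embed_dim: int = 128
    n_heads: int = 4
    n_layers: int = 4
    mlp_ratio: float = 2.0
    kernel_size: int = 3
    conv_padding: str = "wrap"   # exact translation covariance; "constant" for zero-pad

    def validate(self) -> None:
        if self.conv_padding not in ("wrap", "constant", "edge"):
            raise ConfigError(
                f"conv_padding must be wrap/constant/edge, got {self.conv_padding!r}"
            )
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError(
                f"embed_dim ({self.embed_dim}) must be divisible by n_heads ({self.n_heads})"
            )
        if not self.cnn_blocks:
            raise ConfigError("cnn_blocks must contain at least one (out_channels, stride) pair")
        if self.cnn_blocks[-1][0] != self.common_channels:
            raise ConfigError(
                f"last cnn block must output common_channels={self.common_channels}, "
                f"got {self.cnn_blocks[-1][0]}"
            )
        if self.kernel_size % 2 != 1:
            raise ConfigError(f"kernel_size must be odd, got {self.kernel_size}")

    @property
    def downsample_factor(self) -> int:
        f = 1
        for _, s in self.cnn_blocks:
            f *= s
        return f


@dataclass
class ModelConfig:
    """Full network: stream architecture + variant routing + loss weights."""

    variant: str = "full_adsaf"
    lambda_entropy: float = 0.1
    n_classes: int = 2
    stream: StreamConfig = field(default_factory=StreamConfig)
    gate_hidden: Optional[int] = None   # default: common_channels // 2
    sarm_reduction: int = 8
    sarm_kernel: int = 7

    def validate(self) -> None:
        if self.variant not in VARIANT_NAMES:
            raise ConfigError(
                f"unknown variant {self.variant!r}; valid names: {', '.join(VARIANT_NAMES)}"
            )
        if self.lambda_entropy < 0:
            raise ConfigError(f"lambda_entropy must be >= 0, got {self.lambda_entropy}")
        if self.variant not in GATED_VARIANTS and self.lambda_entropy != 0:
            raise ConfigError(
                f"variant {self.variant!r} has no adaptive gate; lambda_entropy must be 0"
            )
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        self.stream.validate()
        C = self.stream.common_channels
        if C % self.sarm_reduction != 0:
            raise ConfigError(
                f"common_channels ({C}) must be divisible by sarm_reduction ({self.sarm_reduction})"
            )
        if self.sarm_kernel % 2 != 1:
            raise ConfigError(f"sarm_kernel must be odd, got {self.sarm_kernel}")

    @property
    def gate_hidden_width(self) -> int:
        return self.gate_hidden if self.gate_hidden is not None else max(1, self.stream.common_channels // 2)


@dataclass
class AugmentConfig:
    """Stochastic training-time augmentation; each transform fires with p=0.5."""

    hflip: bool = True
    rotate_deg: float = 15.0
    zoom_range: float = 0.10
    shift_range: float = 0.10

    def validate(self) -> None:
        if self.rotate_deg < 0 or self.zoom_range < 0 or self.shift_range < 0:
            raise ConfigError("augmentation magnitudes must be >= 0")


@dataclass
class TrainConfig:
    batch_size: int = 32
    lr: float = 0.001
    lr_factor: float = 0.1
    lr_patience: int = 5
    early_stop_patience: int = 7
    max_epochs: int = 50
    split: tuple = (0.7, 0.2, 0.1)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    image_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError(f"split proportions must sum to 1, got {self.split}")
        if any(p < 0 for p in self.split):
            raise ConfigError(f"split proportions must be >= 0, got {self.split}")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ConfigError("patience values must be >= 1")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.max_epochs < 1:
            raise ConfigError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if not 0 < self.lr_factor <= 1:
            raise ConfigError(f"lr_factor must lie in (0, 1], got {self.lr_factor}")
        self.augment.validate()


@dataclass
class ExperimentConfig:
    """One reproducible experiment: data source, model, training, outputs."""

    synthetic: Optional[SyntheticSpec] = None
    data_dir: Optional[str] = None
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    noise_std: float = 0.05
    eval_domain_shift: Optional[DomainShiftParams] = None
    out_dir: str = "adsaf_out"

    def validate(self) -> None:
        if self.synthetic is None and self.data_dir is None:
            raise ConfigError("either 'synthetic' or 'data_dir' must be provided")
        if self.synthetic is not None:
            self.synthetic.validate()
        self.model.validate()
        self.train.validate()
        if self.noise_std < 0:
            raise ConfigError(f"noise_std must be >= 0, got {self.noise_std}")
        if self.eval_domain_shift is not None:
            self.eval_domain_shift.validate()


# ---------------------------------------------------------------------------
# (de)serialization


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def _tupled(x):
    return tuple(tuple(v) if isinstance(v, list) else v for v in x)


def experiment_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    syn = d.get("synthetic")
    if syn is not None:
        syn = dict(syn)
        if syn.get("domain_shift") is not None:
            syn["domain_shift"] = DomainShiftParams(**syn["domain_shift"])
        syn = SyntheticSpec(**syn)
    model = d.get("model", {})
    if not isinstance(model, ModelConfig):
        model = dict(model)
        stream = model.get("stream", {})
        if not isinstance(stream, StreamConfig):
            stream = dict(stream)
            if "cnn_blocks" in stream:
                stream["cnn_blocks"] = _tupled(stream["cnn_blocks"])
            stream = StreamConfig(**stream)
        model["stream"] = stream
        model = ModelConfig(**model)
    train = d.get("train", {})
    if not isinstance(train, TrainConfig):
        train = dict(train)
        if "split" in train:
            train["split"] = tuple(train["split"])
        if "augment" in train and not isinstance(train["augment"], AugmentConfig):
            train["augment"] = AugmentConfig(**train["augment"])
        train = TrainConfig(**train)
    shift = d.get("eval_domain_shift")
    if shift is not None and not isinstance(shift, DomainShiftParams):
        shift = DomainShiftParams(**shift)
    return ExperimentConfig(
        synthetic=syn,
        data_dir=d.get("data_dir"),
        model=model,
        train=train,
        noise_std=d.get("noise_std", 0.05),
        eval_domain_shift=shift,
        out_dir=d.get("out_dir", "adsaf_out"),
    )


def load_experiment(path: str) -> ExperimentConfig:
    """Load and validate an experiment config from a YAML (or JSON) file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    try:
        cfg = experiment_from_dict(d)
    except TypeError as exc:  # unknown/missing field
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    cfg.validate()
    return cfg


def save_experiment(cfg: ExperimentConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def config_hash(cfg) -> str:
    """Stable short hash of a config, recorded in output manifests."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
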