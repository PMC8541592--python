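"""Model components: feature extractor, regressor head, discriminator.

The feature extractor maps a preprocessed image batch to fixed-length feature
vectors of dimension ``F``; the regressor head turns a feature vector into a
single unbounded real (the holistic count estimate); the discriminator scores
a feature vector with a probability in (0, 1) of being a *source* feature.

Head layouts follow a 2048 -> 1024 -> 512 -> 1 dense stack (ReLU/ReLU/linear
for the regressor; LeakyReLU(0.01)x2 + sigmoid for the discriminator); for
other feature dimensions the hidden widths scale by the same 1/2 and 1/4
ratios.  The default backbone is a four-block strided convolutional network
with global average pooling, sized for desk-scale experiments (F = 128,
64x64 inputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "FeatureExtractor",
    "RegressorHead",
    "Discriminator",
    "build_models",
    "extract_features",
    "discriminate",
    "save_checkpoint",
    "load_checkpoint",
]

LEAKY_ALPHA = 0.01


class ConfigurationError(ValueError):
    """Unknown backbone or inconsistent model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_cnn"
    feature_dim: int = 128
    image_size: int = 64

    def head_widths(self) -> tuple[int, int]:
        return max(1, self.feature_dim // 2), max(1, self.feature_dim // 4)


class _NetModel:
    """Shared thin wrapper around a Sequential network."""

    def __init__(self, net: nn.Sequential):
        self.net = net

    def params(self):
        return self.net.params()

    def get_state(self):
        return self.net.get_state()

    def set_state(self, state):
        self.net.set_state(state)

    def zero_grad(self):
        self.net.zero_grad()

    def param_hash(self) -> int:
        """Cheap content hash used to assert which stage touched what."""
        h = 0
        for p in self.net.params():
            h ^= hash(p.value.tobytes())
        return h


class FeatureExtractor(_NetModel):
    def __init__(self, net: nn.Sequential, config: ModelConfig):
        super().__init__(net)
        self.output_dim = config.feature_dim
        self.image_size = config.image_size
        self.config = config

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError("expected images of shape (B, 3, H, W)")
        if images.shape[2] != self.image_size or images.shape[3] != self.image_size:
            raise ValueError(
                f"expected {self.image_size}x{self.image_size} images, "
                f"got {images.shape[2]}x{images.shape[3]}"
            )
        return self.net.forward(images.astype(np.float32, copy=False), train=train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def clone(self) -> "FeatureExtractor":
        """Independent copy (used to initialise the target extractor)."""
        other = _build_backbone(self.config, np.random.default_rng(0))
        clone = FeatureExtractor(other, self.config)
        clone.set_state(self.get_state())
        return clone


class RegressorHead(_NetModel):
    def __init__(self, net: nn.Sequential, feature_dim: int):
        super().__init__(net)
        self.feature_dim = feature_dim

    def forward(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        _check_width(feats, self.feature_dim)
        return self.net.forward(feats, train=train)[:, 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(np.asarray(grad, dtype=np.float32)[:, None])

    def copy(self) -> "RegressorHead":
        rng = np.random.default_rng(0)
        h1 = self.net.layers[0].W.value.shape[1]
        h2 = self.net.layers[2].W.value.shape[1]
        net = nn.Sequential([
            nn.Dense(self.feature_dim, h1, rng), nn.ReLU(),
            nn.Dense(h1, h2, rng), nn.ReLU(),
            nn.Dense(h2, 1, rng),
        ])
        out = RegressorHead(net, self.feature_dim)
        out.set_state(self.get_state())
        return out


class Discriminator(_NetModel):
    def __init__(self, net: nn.Sequential, feature_dim: int):
        super().__init__(net)
        self.feature_dim = feature_dim

    def forward(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        _check_width(feats, self.feature_dim)
        return self.net.forward(feats, train=train)[:, 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(np.asarray(grad, dtype=np.float32)[:, None])


def _check_width(feats: np.ndarray, width: int) -> None:
    if feats.ndim != 2 or feats.shape[1] != width:
        raise ValueError(f"expected feature matrix of width {width}, got shape {feats.shape}")


def _build_backbone(config: ModelConfig, rng: np.random.Generator) -> nn.Sequential:
    f = config.feature_dim
    channels = [max(4, f // 8), max(4, f // 4), max(4, f // 2), f]
    layers: list[nn.Layer] = []
    cin = 3
    for cout in channels:
        layers.append(nn.Conv2d(cin, cout, rng, stride=2))
        layers.append(nn.ReLU())
        cin = cout
    layers.append(nn.GlobalAvgPool2d())
    return nn.Sequential(layers)


def build_models(config: ModelConfig, seed: int = 0):
    """Freshly initialised (feature extractor, regressor, discriminator).

    Initialisation is He-normal from a generator seeded with ``seed``; the
    same (config, seed) pair always yields identical parameters.
    """
    if config.backbone != "small_cnn":
        raise ConfigurationError(f"unknown backbone {config.backbone!r}")
    if config.feature_dim < 4:
        raise ConfigurationError("feature_dim must be >= 4")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2024]))
    fe = FeatureExtractor(_build_backbone(config, rng), config)
    h1, h2 = config.head_widths()
    f = config.feature_dim
    reg = RegressorHead(nn.Sequential([
        nn.Dense(f, h1, rng), nn.ReLU(),
        nn.Dense(h1, h2, rng), nn.ReLU(),
        nn.Dense(h2, 1, rng),
    ]), f)
    disc = Discriminator(nn.Sequential([
        nn.Dense(f, h1, rng), nn.LeakyReLU(LEAKY_ALPHA),
        nn.Dense(h1, h2, rng), nn.LeakyReLU(LEAKY_ALPHA),
        nn.Dense(h2, 1, rng), nn.Sigmoid(),
    ]), f)
    return fe, reg, disc


def extract_features(fe: FeatureExtractor, images: np.ndarray) -> np.ndarray:
    """Evaluation-mode (B, F) feature matrix for an image batch."""
    feats = fe.forward(images, train=False)
    if not np.all(np.isfinite(feats)):
        raise FloatingPointError("non-finite features")
    return feats


def discriminate(d: Discriminator, feats: np.ndarray) -> np.ndarray:
    """Evaluation-mode source-probabilities in (0, 1) for a feature batch."""
    return d.forward(feats, train=False)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, config: ModelConfig, **models) -> None:
    """Save named model states plus optional metadata to an ``.npz`` file.

    ``models`` maps names (e.g. ``fe``, ``regressor``) to model objects; extra
    scalar metadata can be passed via the reserved key ``meta`` (a dict).
    """
    path = Path(path)
    meta = models.pop("meta", {})
    arrays: dict[str, np.ndarray] = {}
    for name, model in models.items():
        for i, arr in enumerate(model.get_state()):
            arrays[f"{name}__{i}"] = arr
    arrays["__meta__"] = np.frombuffer(
        json.dumps({"config": asdict(config), "meta": meta}).encode(), dtype=np.uint8
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    """Load a checkpoint; returns (config, states, meta).

    ``states`` maps each saved model name to its ordered weight list; rebuild
    the models with :func:`build_models` and apply ``set_state``.
    """
    path = Path(path)
    with np.load(path) as data:
        blob = json.loads(bytes(data["__meta__"].tobytes()).decode())
        states: dict[str, list[np.ndarray]] = {}
        for key in data.files:
            if key == "__meta__":
                continue
            name, idx = key.rsplit("__", 1)
            states.setdefault(name, []).append((int(idx), data[key]))
    ordered = {name: [a for _, a in sorted(items)] for name, items in states.items()}
    cfg = ModelConfig(**blob["config"])
    return cfg, ordered, blob["meta"]
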