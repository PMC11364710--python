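"""CNN + bidirectional LSTM sequence-labelling model.

A per-window CNN backbone (VGG16, ResNet18 or SE-ResNet18) embeds each
three-frame window into a 1024-dimensional feature vector via a learned
linear projection of the pooled backbone output; a bidirectional LSTM reads
the window sequence; a single dense unit per timestep performs logistic
regression, emitting one probability per window.

A desk-scale ``tiny`` preset (64 x 64 input, width-reduced backbone, smaller
embedding and hidden state) exists so the whole pipeline trains in minutes
on one CPU; the full-scale spec remains the default.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .preprocess import NormalizationStats

BACKBONES = ("vgg16", "resnet18", "se_resnet18")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``width`` is the backbone's base channel count (64 reproduces the
    standard VGG16/ResNet18 widths).  ``feature_dim`` is the embedding each
    window is compressed to before the recurrent pass.
    """

    backbone: str = "se_resnet18"
    feature_dim: int = 1024
    se_reduction: int = 16
    recurrent_hidden: int = 512
    recurrent_layers: int = 1
    bidirectional: bool = True
    image_size: int = 256
    width: int = 64

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {BACKBONES}")
        if not self.bidirectional:
            raise ValueError("the recurrent stage is bidirectional by design")
        if self.feature_dim <= 0 or self.recurrent_hidden <= 0:
            raise ValueError("feature_dim and recurrent_hidden must be positive")
        if self.recurrent_layers != 1:
            raise ValueError("only single-layer recurrence is implemented")

    @classmethod
    def full(cls, backbone: str = "se_resnet18") -> "ModelSpec":
        return cls(backbone=backbone)

    @classmethod
    def tiny(cls, backbone: str = "se_resnet18") -> "ModelSpec":
        """Width-reduced preset for CPU-scale training and tests."""
        return cls(backbone=backbone, feature_dim=128, recurrent_hidden=64,
                   image_size=64, width=8)


# --- backbones -------------------------------------------------------------------


class BasicBlock(nn.Module):
    """ResNet basic block, optionally with a squeeze-and-excitation gate."""

    def __init__(self, cin: int, cout: int, stride: int, *, se: bool,
                 se_reduction: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(cout, cout, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        self.se = nn.SEBlock(cout, reduction=se_reduction, rng=rng) if se else None
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None
        self.relu_out = nn.ReLU()

    def forward(self, x):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.bn2.forward(self.conv2.forward(out))
        if self.se is not None:
            out = self.se.forward(out)
        if self.down_conv is not None:
            shortcut = self.down_bn.forward(self.down_conv.forward(x))
        else:
            shortcut = x
        return self.relu_out.forward(out + shortcut)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        dres = dsum
        if self.se is not None:
            dres = self.se.backward(dres)
        dres = self.bn2.backward(dres)
        dres = self.conv2.backward(dres)
        dres = self.relu1.backward(dres)
        dres = self.bn1.backward(dres)
        dres = self.conv1.backward(dres)
        if self.down_conv is not None:
            dshort = self.down_conv.backward(self.down_bn.backward(dsum))
        else:
            dshort = dsum
        return dres + dshort


def _resnet18(width: int, feature_dim: int, *, se: bool, se_reduction: int,
              rng: np.random.Generator) -> nn.Sequential:
    w = width
    layers: list[nn.Module] = [
        nn.Conv2d(3, w, 7, stride=2, padding=3, bias=False, rng=rng),
        nn.BatchNorm2d(w),
        nn.ReLU(),
        nn.MaxPool2d(3, stride=2, padding=1),
    ]
    cin = w
    for stage, (cout, stride) in enumerate([(w, 1), (2 * w, 2), (4 * w, 2), (8 * w, 2)]):
        for b in range(2):
            layers.append(BasicBlock(cin, cout, stride if b == 0 else 1,
                                     se=se, se_reduction=se_reduction, rng=rng))
            cin = cout
    layers += [nn.GlobalAvgPool(), nn.Linear(8 * w, feature_dim, rng=rng)]
    return nn.Sequential(*layers)


def _vgg16(width: int, feature_dim: int, *, rng: np.random.Generator) -> nn.Sequential:
    w = width
    plan = [w, w, "M", 2 * w, 2 * w, "M", 4 * w, 4 * w, 4 * w, "M",
            8 * w, 8 * w, 8 * w, "M", 8 * w, 8 * w, 8 * w, "M"]
    layers: list[nn.Module] = []
    cin = 3
    for item in plan:
        if item == "M":
            layers.append(nn.MaxPool2d(2))
        else:
            layers += [nn.Conv2d(cin, item, 3, padding=1, rng=rng),
                       nn.BatchNorm2d(item), nn.ReLU()]
            cin = item
    hidden = 64 * w  # 4096 at the standard width
    layers += [nn.GlobalAvgPool(),
               nn.Linear(8 * w, hidden, rng=rng), nn.ReLU(),
               nn.Linear(hidden, feature_dim, rng=rng)]
    return nn.Sequential(*layers)


class CNNLSTMNetwork(nn.Module):
    """Backbone (with the 1024-d projection) + BiLSTM + per-timestep
    logistic head.  Sequence input is (T, N, 3, S, S); output logits (T, N)."""

    def __init__(self, spec: ModelSpec, seed: int):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        if spec.backbone == "vgg16":
            self.backbone = _vgg16(spec.width, spec.feature_dim, rng=rng)
        else:
            self.backbone = _resnet18(
                spec.width, spec.feature_dim,
                se=(spec.backbone == "se_resnet18"),
                se_reduction=spec.se_reduction, rng=rng,
            )
        self.rnn = nn.BiLSTM(spec.feature_dim, spec.recurrent_hidden, rng=rng)
        self.head = nn.Linear(2 * spec.recurrent_hidden, 1, rng=rng)

    # parameter groups for the differential learning rate
    def backbone_parameters(self):
        return list(self.backbone.parameters())

    def recurrent_parameters(self):
        return list(self.rnn.parameters()) + list(self.head.parameters())

    def forward_features(self, windows: np.ndarray) -> np.ndarray:
        """(B, 3, S, S) -> (B, feature_dim)."""
        if windows.ndim != 4 or windows.shape[1] != 3:
            raise ValueError(f"expected (B, 3, S, S) windows, got {windows.shape}")
        s = self.spec.image_size
        if windows.shape[2] != s or windows.shape[3] != s:
            raise ValueError(
                f"window resolution {windows.shape[2:]} does not match model input {s}x{s}"
            )
        return self.backbone.forward(windows.astype(np.float32, copy=False))

    def forward_sequence(self, windows: np.ndarray) -> np.ndarray:
        """(T, N, 3, S, S) -> logits (T, N)."""
        t, n = windows.shape[:2]
        feats = self.forward_features(windows.reshape(t * n, *windows.shape[2:]))
        feats = feats.reshape(t, n, -1)
        h = self.rnn.forward(feats)
        logits = self.head.forward(h)[..., 0]
        self._seq_shape = (t, n)
        return logits

    def backward_sequence(self, dlogits: np.ndarray) -> np.ndarray:
        """Backprop from (T, N) logit gradients; returns input-pixel grads
        (T, N, 3, S, S) for saliency."""
        t, n = self._seq_shape
        dh = self.head.backward(dlogits[..., None])
        dfeats = self.rnn.backward(dh)
        dx = self.backbone.backward(dfeats.reshape(t * n, -1))
        return dx.reshape(t, n, *dx.shape[1:])

    def forward(self, x):  # feature path, for Module compatibility
        return self.forward_features(x)

    def backward(self, dy):
        return self.backbone.backward(dy)


def build_model(spec: ModelSpec, seed: int = 0) -> CNNLSTMNetwork:
    """Deterministically initialise the architecture described by ``spec``."""
    return CNNLSTMNetwork(spec, seed)


def extract_features(model: CNNLSTMNetwork, window: np.ndarray) -> np.ndarray:
    """Embed one (3, S, S) window (or a (B, 3, S, S) batch) to feature_dim."""
    single = window.ndim == 3
    batch = window[None] if single else window
    feats = model.forward_features(batch)
    return feats[0] if single else feats


def sequence_probabilities(model: CNNLSTMNetwork, windows: list) -> "WindowProbabilities":
    """Run the full per-series pass over a list of :class:`Window` objects."""
    if len(windows) == 0:
        raise ValueError("need at least one window")
    stack = np.stack([w.channels for w in windows])[:, None]  # (T, 1, 3, S, S)
    logits = model.forward_sequence(stack)[:, 0]
    return WindowProbabilities(
        values=nn.sigmoid(logits.astype(np.float64)),
        centre_tis=np.array([w.centre_ti for w in windows], dtype=float),
    )


def count_parameters(model: nn.Module, trainable_only: bool = True) -> int:
    return model.num_parameters(trainable_only=trainable_only)


@dataclass(frozen=True)
class WindowProbabilities:
    """One probability per window plus the centre-frame TIs (ms)."""

    values: np.ndarray
    centre_tis: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        tis = np.asarray(self.centre_tis, dtype=float)
        if values.shape != tis.shape:
            raise ValueError("one centre TI per probability is required")
        if np.any((values < 0) | (values > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "centre_tis", tis)

    def __len__(self):
        return len(self.values)


# --- model bundle ----------------------------------------------------------------


@dataclass
class ModelBundle:
    """A trained model plus everything inference needs: the architecture
    spec, learned parameters (and normalisation-layer running statistics),
    corpus normalisation stats and the training seed."""

    spec: ModelSpec
    network: CNNLSTMNetwork
    norm_stats: NormalizationStats
    seed: int
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> Path:
        """Serialise to one self-describing .npz archive."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": asdict(self.spec),
            "norm_stats": {"mean": self.norm_stats.mean, "std": self.norm_stats.std},
            "seed": self.seed,
            "metadata": self.metadata,
        }
        arrays = {f"param::{k}": v for k, v in self.network.state_dict().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
        spec = ModelSpec(**meta["spec"])
        network = build_model(spec, seed=meta["seed"])
        network.load_state_dict(state)
        network.eval()
        stats = NormalizationStats(**meta["norm_stats"])
        return cls(spec=spec, network=network, norm_stats=stats,
                   seed=meta["seed"], metadata=meta.get("metadata", {}))
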