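"""The attention-MIL architecture fusing plot imagery with genotypes.

Every data source of a plot (each image, plus the SNP dosage vector) is one
*instance*.  Channel-specific encoders map instances to 256-dimensional
embeddings; a gated attention mechanism pools the resulting embedding bag
into one vector per head,

    z = sum_i a_i h_i,        a_i = softmax_i( w^T tanh(V h_i^T) ),

with V in R^{l x m} and w in R^l; the per-head pooled vectors are
concatenated and fed to a fully connected regressor that outputs grain yield
in t/ha.  Because pooling is a convex combination over an unordered set, the
prediction is permutation-invariant in the instances, and the weights a_i
expose which instances the model relied on.

Optionally, a one-hot encoding of the acquisition date and/or of the data
channel is appended to each embedding before pooling (the genotype instance
gets an all-zero date block and its own channel category).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .io_core import CHANNEL_BANDS, ImageInstance, PlotSample
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "AttentionResult",
    "ForwardResult",
    "PheGeMIL",
    "attention_pool",
    "multi_head_pool",
    "sample_bag",
    "mse_loss",
    "predict_yield",
    "save_checkpoint",
    "load_checkpoint",
]

#: channel categories for the one-hot channel encoding (genotype is its own)
CHANNEL_CATEGORIES = ("multispectral", "thermal", "dem", "genotype")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    `date_vocabulary` is fixed at training time; under temporal encoding an
    unseen date at inference maps to a reserved "other" slot.
    """

    n_markers: int
    embedding_dim: int = 256
    genotype_hidden: tuple[int, int] = (1024, 512)
    n_heads: int = 4
    bag_size: int = 16
    temporal_encoding: bool = False
    channel_encoding: bool = False
    attention_width: int = 128
    image_encoder: str = "tiny"  # "tiny" | "resnet18"
    channels: tuple[str, ...] = ("multispectral", "thermal", "dem")
    use_genotype: bool = True
    date_vocabulary: tuple[str, ...] = ()
    tiny_widths: tuple[int, int] = (8, 16)
    input_downsample: int = 8
    regressor_hidden: int = 128

    def __post_init__(self):
        if self.n_heads < 1:
            raise ValueError("need at least one attention head")
        if self.bag_size < 1:
            raise ValueError("bag_size must be >= 1")
        if not self.channels and not self.use_genotype:
            raise ValueError("model needs at least one data source")

    @property
    def extended_dim(self) -> int:
        m = self.embedding_dim
        if self.temporal_encoding:
            m += len(self.date_vocabulary) + 1  # + "other" slot
        if self.channel_encoding:
            m += len(CHANNEL_CATEGORIES)
        return m


@dataclass
class AttentionResult:
    """Pooled vector and per-instance weights for one attention head."""

    z: np.ndarray
    weights: np.ndarray
    head: int


@dataclass
class ForwardResult:
    prediction: float
    heads: list[AttentionResult]
    provenance: list[tuple[str, _dt.date | None]]  # (channel, date) per instance


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def attention_pool(H: Tensor, V: Tensor, w: Tensor) -> tuple[Tensor, Tensor]:
    """Gated attention pooling of an embedding bag H (k x m).

    Returns (z, a) with z = sum_i a_i h_i and a the softmax of the gated
    scores w^T tanh(V h_i^T); the softmax subtracts the max logit for
    numerical stability.
    """
    H = H if isinstance(H, Tensor) else Tensor(H)
    k, m = H.shape
    if V.shape[1] != m:
        raise ValueError(f"V has {V.shape[1]} columns but embeddings have dim {m}")
    if w.shape[0] != V.shape[0]:
        raise ValueError("w and V disagree on the attention width l")
    scores = (V @ H.T).tanh()  # (l, k)
    logits = w @ scores  # (k,)
    shifted = logits - float(logits.data.max())
    expd = shifted.exp()
    a = expd / expd.sum()
    z = a @ H  # (m,)
    return z, a


def multi_head_pool(
    H: Tensor, heads: list[tuple[Tensor, Tensor]]
) -> tuple[Tensor, list[tuple[Tensor, Tensor]]]:
    """Pool H with each (V, w) head independently; concatenate the pooled
    vectors (output dim = n_heads x m)."""
    if not heads:
        raise ValueError("need at least one attention head")
    results = [attention_pool(H, V, w) for V, w in heads]
    pooled = nn.concatenate([z for z, _ in results], axis=0)
    return pooled, results


def sample_bag(instances: list, bag_size: int, rng: np.random.Generator) -> list:
    """Uniform subsample without replacement down to `bag_size` instances;
    bags at or under the limit pass through unchanged."""
    if bag_size < 1:
        raise ValueError("bag_size must be >= 1")
    if len(instances) <= bag_size:
        return list(instances)
    idx = rng.choice(len(instances), size=bag_size, replace=False)
    return [instances[i] for i in idx]


def mse_loss(predictions, observations):
    """Mean squared error; differentiable when given Tensors."""
    if isinstance(predictions, Tensor) or isinstance(observations, Tensor):
        pred = predictions if isinstance(predictions, Tensor) else Tensor(predictions)
        obs = observations if isinstance(observations, Tensor) else Tensor(observations)
        if pred.shape != obs.shape:
            raise ValueError(f"shape mismatch {pred.shape} vs {obs.shape}")
        return ((pred - obs) ** 2).mean()
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {obs.shape}")
    return float(np.mean((pred - obs) ** 2))


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class TinyImageEncoder(nn.Module):
    """Small residual CNN for desk-scale experiments.

    Single-band inputs pass through a learned 1->3 channel-adapter
    convolution before the shared-stem layout.  Images are average-pooled
    down by `input_downsample` first: the synthetic imagery carries its
    signal in channel statistics, not in fine texture.
    """

    def __init__(self, in_bands: int, cfg: ModelConfig, rng: np.random.Generator):
        w1, w2 = cfg.tiny_widths
        self.target_downsample = cfg.input_downsample
        self.adapter = nn.Conv2d(1, 3, 1, rng) if in_bands == 1 else None
        stem_in = 3 if in_bands == 1 else in_bands
        self.stem = nn.Conv2d(stem_in, w1, 3, rng, padding=1)
        self.block1 = nn.ResidualBlock(w1, rng)
        self.block2 = nn.ResidualBlock(w1, rng, out_channels=w2)
        self.head = nn.Linear(w2, cfg.embedding_dim, rng)

    @staticmethod
    def _pool_factor(h: int, w: int, target: int) -> int:
        # keep at least a 4x4 grid for the convolutions
        f = max(1, target)
        while f > 1 and (h % f or w % f or h // f < 4 or w // f < 4):
            f -= 1
        return f

    def forward(self, x: Tensor) -> Tensor:  # x: (N, bands, H, W)
        _, _, h, w = x.shape
        f = self._pool_factor(h, w, self.target_downsample)
        if f > 1:
            x = nn.AvgPool2d(f)(x)
        if self.adapter is not None:
            x = self.adapter(x)
        x = self.stem(x).relu()
        x = self.block1(x)
        _, _, h, w = x.shape
        if h % 2 == 0 and w % 2 == 0 and h >= 4 and w >= 4:
            x = nn.AvgPool2d(2)(x)
        x = self.block2(x)
        x = nn.GlobalAvgPool()(x)
        return self.head(x)


class ResNet18Encoder(nn.Module):
    """18-layer residual image encoder (4 stages of 2 basic blocks)."""

    def __init__(self, in_bands: int, cfg: ModelConfig, rng: np.random.Generator):
        self.adapter = nn.Conv2d(1, 3, 1, rng) if in_bands == 1 else None
        stem_in = 3 if in_bands == 1 else in_bands
        self.stem = nn.Conv2d(stem_in, 64, 7, rng, stride=2, padding=3)
        self.pool = nn.AvgPool2d(2)
        stages = []
        widths = (64, 128, 256, 512)
        prev = 64
        for i, width in enumerate(widths):
            stages.append(nn.ResidualBlock(prev, rng, out_channels=width,
                                           stride=1 if i == 0 else 2))
            stages.append(nn.ResidualBlock(width, rng))
            prev = width
        self.stages = stages
        self.head = nn.Linear(512, cfg.embedding_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.adapter is not None:
            x = self.adapter(x)
        x = self.stem(x).relu()
        x = self.pool(x)
        for block in self.stages:
            x = block(x)
        x = nn.GlobalAvgPool()(x)
        return self.head(x)


class GenotypeEncoder(nn.Module):
    """Fully connected SNP-dosage encoder: hidden layers 1024 and 512, then
    projection to the shared 256-dimensional embedding space."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        h1, h2 = cfg.genotype_hidden
        self.fc1 = nn.Linear(cfg.n_markers, h1, rng)
        self.fc2 = nn.Linear(h1, h2, rng)
        self.fc3 = nn.Linear(h2, cfg.embedding_dim, rng)

    def forward(self, x: Tensor) -> Tensor:  # x: (N, n_markers)
        return self.fc3(self.fc2(self.fc1(x).relu()).relu())


class AttentionHead(nn.Module):
    def __init__(self, m: int, l: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / m)
        self.V = nn.Parameter(rng.uniform(-bound, bound, (l, m)))
        self.w = nn.Parameter(rng.uniform(-np.sqrt(6.0 / l), np.sqrt(6.0 / l), l))


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class PheGeMIL(nn.Module):
    """Multi-channel attention-MIL yield predictor."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        enc_cls = TinyImageEncoder if config.image_encoder == "tiny" else ResNet18Encoder
        self.image_encoders = {
            ch: enc_cls(CHANNEL_BANDS[ch], config, rng) for ch in config.channels
        }
        self.genotype_encoder = (
            GenotypeEncoder(config, rng) if config.use_genotype else None
        )
        m = config.extended_dim
        self.heads = [
            AttentionHead(m, config.attention_width, rng)
            for _ in range(config.n_heads)
        ]
        self.reg1 = nn.Linear(config.n_heads * m, config.regressor_hidden, rng)
        self.reg2 = nn.Linear(config.regressor_hidden, 1, rng)
        self._date_slot = {d: i for i, d in enumerate(config.date_vocabulary)}

    # -- encodings ----------------------------------------------------------
    def encode_image(self, images: list[ImageInstance], channel: str) -> Tensor:
        """Encode a batch of same-channel images to (k, 256) embeddings."""
        if channel not in self.image_encoders:
            raise ValueError(f"model has no encoder for channel {channel!r}")
        stack = np.stack([img.pixels for img in images])  # (k, H, W, B)
        x = Tensor(stack.transpose(0, 3, 1, 2))  # NCHW
        return self.image_encoders[channel](x)

    def encode_genotype(self, dosage: np.ndarray) -> Tensor:
        dosage = np.asarray(dosage, dtype=float)
        squeeze = dosage.ndim == 1
        if squeeze:
            dosage = dosage[None, :]
        if dosage.shape[1] != self.config.n_markers:
            raise ValueError(
                f"genotype has {dosage.shape[1]} markers but the model was "
                f"trained on {self.config.n_markers}; align with "
                "training_eval.harmonize_markers"
            )
        out = self.genotype_encoder(Tensor(dosage - 1.0))  # center dosages
        return out[0] if squeeze else out

    def augment_embedding(
        self, h: Tensor, dates: list[_dt.date | None], channel: str
    ) -> Tensor:
        """Append the configured one-hot blocks to a (k, 256) batch.

        Genotype instances (date None) receive an all-zero date block;
        unseen dates map to the reserved "other" slot.
        """
        blocks = [h]
        k = h.shape[0]
        if self.config.temporal_encoding:
            D = len(self.config.date_vocabulary)
            onehot = np.zeros((k, D + 1))
            for i, d in enumerate(dates):
                if d is None:
                    continue
                onehot[i, self._date_slot.get(d.isoformat(), D)] = 1.0
            blocks.append(Tensor(onehot))
        if self.config.channel_encoding:
            onehot = np.zeros((k, len(CHANNEL_CATEGORIES)))
            onehot[:, CHANNEL_CATEGORIES.index(channel)] = 1.0
            blocks.append(Tensor(onehot))
        if len(blocks) == 1:
            return h
        return nn.concatenate(blocks, axis=1)

    # -- forward ------------------------------------------------------------
    def forward(
        self,
        sample: PlotSample,
        train: bool = False,
        rng: np.random.Generator | None = None,
        genotype_only: bool = False,
    ) -> tuple[Tensor, ForwardResult]:
        """Encode all instances of a plot, pool, and regress the yield.

        During training each channel's bag is subsampled to `bag_size`;
        at inference every instance is used.
        """
        embeddings: list[Tensor] = []
        provenance: list[tuple[str, _dt.date | None]] = []
        if not genotype_only:
            for ch in self.config.channels:
                instances = sample.bags.get(ch, [])
                if train and instances:
                    instances = sample_bag(instances, self.config.bag_size, rng)
                if not instances:
                    continue
                h = self.encode_image(instances, ch)
                h = self.augment_embedding(h, [i.date for i in instances], ch)
                embeddings.append(h)
                provenance.extend((ch, i.date) for i in instances)
        if self.genotype_encoder is not None and sample.genotype is not None:
            h = self.encode_genotype(sample.genotype[None, :])
            h = self.augment_embedding(h, [None], "genotype")
            embeddings.append(h)
            provenance.append(("genotype", None))
        if not embeddings:
            raise ValueError(f"plot {sample.plot_id}: empty bag (no instances at all)")
        H = embeddings[0] if len(embeddings) == 1 else nn.concatenate(embeddings, axis=0)
        pooled, head_results = multi_head_pool(
            H, [(hd.V, hd.w) for hd in self.heads]
        )
        yhat = self.reg2(self.reg1(pooled.reshape(1, -1)).relu()).reshape(())
        result = ForwardResult(
            prediction=float(yhat.data),
            heads=[
                AttentionResult(z=z.data.copy(), weights=a.data.copy(), head=i)
                for i, (z, a) in enumerate(head_results)
            ],
            provenance=provenance,
        )
        return yhat, result


def predict_yield(
    sample: PlotSample, model: PheGeMIL, genotype_only: bool = False
) -> float:
    """Deterministic full-bag prediction for one plot, in t/ha."""
    yhat, _ = model.forward(sample, train=False, genotype_only=genotype_only)
    return float(yhat.data)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(model: PheGeMIL, path, marker_ids=None, extra=None) -> None:
    """Single-file archive: config, optional marker-id list, and weights."""
    meta = {
        "version": _CKPT_VERSION,
        "config": asdict(model.config),
        "marker_ids": list(marker_ids) if marker_ids is not None else None,
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(Path(path), __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[PheGeMIL, dict]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        if meta["version"] != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg_dict = meta["config"]
        for key in ("genotype_hidden", "channels", "date_vocabulary",
                    "tiny_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        model = PheGeMIL(config, np.random.default_rng(0))
        state = {
            k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
        }
        model.load_state_dict(state)
    return model, meta
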