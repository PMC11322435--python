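"""Contrastive learning of a shared 1-channel representation space.

Two encoders (one per modality, sharing no weights) are trained on aligned
patch pairs with an InfoNCE objective whose critic is the negative mean
squared error between representations: corresponding patches are pulled
together, mismatched patches within the batch act as negatives.  During
training one randomly chosen side of each batch is rotated by a random C4
element ({0, 90, 180, 270} degrees) before encoding and the produced
representation is rotated back before the loss, which enforces rotational
equivariance of the learned maps.

Trained encoders turn the cross-modality retrieval problem into a
monomodal one: both modalities map to representation images on which
ordinary rotation-invariant descriptors can be compared.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .image_io import ImageRecord
from .nn import Adam, UNetSmall

__all__ = [
    "TrainConfig",
    "Encoder",
    "EncoderPair",
    "Representation",
    "infonce_loss",
    "train_comir",
    "compute_representation",
    "equivariance_error",
    "save_encoders",
    "load_encoders",
]

CHECKPOINT_FORMAT_VERSION = 1


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of contrastive training.

    Defaults follow the reference protocol: temperature 0.5, 46 negative
    pairs per iteration (so batches of 47 aligned patch pairs), 128-px
    training patches.  Encoder size, optimizer settings and step count are
    desk-scale choices.
    """

    temperature: float = 0.5
    n_negatives: int = 46
    patch_px: int = 128
    steps: int = 300
    learning_rate: float = 1e-3
    seed: int = 0
    critic: str = "neg_mse"
    base_channels: int = 8
    depth: int = 3

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_negatives < 1:
            raise ValueError("n_negatives must be >= 1")
        if self.patch_px < 32:
            raise ValueError("patch_px must be >= 32")
        if self.critic != "neg_mse":
            raise ValueError(f"unknown critic {self.critic!r}")


@dataclass
class Representation:
    """A 1-channel learned representation image."""

    pixels: np.ndarray
    source_id: str
    modality: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("representation must be 2-D (1 channel)")
        if not np.all(np.isfinite(px)):
            raise ValueError("representation values must be finite")
        self.pixels = px

    # mirror the ImageRecord surface so downstream feature code is agnostic
    @property
    def id(self) -> str:
        return self.source_id

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        return self.pixels


class Encoder:
    """One modality's image-to-representation map (a small U-Net)."""

    def __init__(self, modality: str, net: UNetSmall) -> None:
        self.modality = modality
        self.net = net

    def __call__(self, pixels: np.ndarray) -> np.ndarray:
        return self.net.apply(np.asarray(pixels, dtype=np.float32))


@dataclass
class EncoderPair:
    encoder_A: Encoder
    encoder_B: Encoder
    config: TrainConfig = field(default_factory=TrainConfig)

    def for_modality(self, modality: str) -> Encoder:
        if modality == self.encoder_A.modality:
            return self.encoder_A
        if modality == self.encoder_B.modality:
            return self.encoder_B
        raise ValueError(
            f"no encoder for modality {modality!r}; have "
            f"{self.encoder_A.modality!r} and {self.encoder_B.modality!r}"
        )


def _critic_neg_mse(u: np.ndarray, v: np.ndarray) -> float:
    return -float(np.mean((np.asarray(u, float) - np.asarray(v, float)) ** 2))


def infonce_loss(
    pos_pair: Tuple[np.ndarray, np.ndarray],
    negatives: Sequence[Tuple[np.ndarray, np.ndarray]],
    temperature: float = 0.5,
) -> float:
    """Symmetrized InfoNCE with a negative-MSE critic.

    ``loss = -log( e^{h(x,y)/t} / (e^{h(x,y)/t} + sum_j e^{h(x,y'_j)/t}) )``
    averaged over both directions (x against the negatives' second elements,
    y against their first elements).  With M negatives whose critic values
    all equal the positive's, the loss is exactly ``ln(M + 1)``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    x, y = (np.asarray(p, dtype=np.float64) for p in pos_pair)
    if x.shape != y.shape:
        raise ValueError("positive pair shapes differ")
    for nx, ny in negatives:
        if np.shape(nx) != x.shape or np.shape(ny) != y.shape:
            raise ValueError("negative representation shape mismatch")
    h_pos = _critic_neg_mse(x, y) / temperature
    h_neg_xy = [_critic_neg_mse(x, ny) / temperature for _, ny in negatives]
    h_neg_yx = [_critic_neg_mse(nx, y) / temperature for nx, _ in negatives]
    loss = 0.0
    for h_negs in (h_neg_xy, h_neg_yx):
        logits = np.array([h_pos] + list(h_negs))
        m = logits.max()
        loss += -(h_pos - (m + np.log(np.exp(logits - m).sum())))
    return loss / 2.0


def _batched_infonce(
    ra: np.ndarray, rb: np.ndarray, temperature: float
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Loss and gradients for a batch of aligned representation pairs.

    ``ra``/``rb`` are (B, 1, H, W); pair i is positive, all i != j are
    negatives, symmetrized over rows (A anchors) and columns (B anchors).
    """
    bsz = ra.shape[0]
    npx = ra.shape[2] * ra.shape[3]
    fa = ra.reshape(bsz, -1).astype(np.float64)
    fb = rb.reshape(bsz, -1).astype(np.float64)
    a2 = (fa**2).sum(axis=1)
    b2 = (fb**2).sum(axis=1)
    sq = a2[:, None] + b2[None, :] - 2.0 * fa @ fb.T
    s = -sq / npx / temperature  # scaled critic matrix

    srow = s - s.max(axis=1, keepdims=True)
    prow = np.exp(srow)
    prow /= prow.sum(axis=1, keepdims=True)
    scol = s - s.max(axis=0, keepdims=True)
    pcol = np.exp(scol)
    pcol /= pcol.sum(axis=0, keepdims=True)

    diag = np.arange(bsz)
    loss = 0.5 * (
        -np.log(prow[diag, diag] + 1e-300).mean()
        - np.log(pcol[diag, diag] + 1e-300).mean()
    )
    eye = np.eye(bsz)
    ds = 0.5 * ((prow - eye) + (pcol - eye)) / bsz  # d loss / d s
    dsq = ds * (-1.0 / npx / temperature)  # d loss / d ||.||^2
    dfa = 2.0 * (dsq.sum(axis=1)[:, None] * fa - dsq @ fb)
    dfb = 2.0 * (dsq.sum(axis=0)[:, None] * fb - dsq.T @ fa)
    return float(loss), dfa.reshape(ra.shape), dfb.reshape(rb.shape)


def train_comir(
    train_pairs: Sequence[Tuple[ImageRecord, ImageRecord]],
    config: TrainConfig = TrainConfig(),
) -> Tuple[EncoderPair, List[float]]:
    """Train the two encoders on aligned image pairs; returns the loss trace.

    Each step samples ``n_negatives + 1`` aligned patch pairs at random
    positions, applies the C4 rotation augmentation to one side, and takes
    one Adam step on the symmetrized InfoNCE loss.  Fully deterministic
    given the config seed.
    """
    if len(train_pairs) < 2:
        raise ConfigurationError(
            "contrastive training needs at least 2 aligned pairs so that "
            "negatives come from distinct scenes; provide more pairs or "
            "generate a larger synthetic dataset"
        )
    p = config.patch_px
    for rec_a, rec_b in train_pairs:
        if rec_a.pixels.shape != rec_b.pixels.shape:
            raise ValueError(f"pair {rec_a.id}/{rec_b.id} not pixel-aligned")
        if min(rec_a.height, rec_a.width) < p:
            raise ConfigurationError(
                f"image {rec_a.id} smaller than patch_px={p}"
            )

    mod_a = train_pairs[0][0].modality
    mod_b = train_pairs[0][1].modality
    rng = np.random.default_rng(config.seed)
    net_a = UNetSmall(1, config.base_channels, seed=int(rng.integers(2**31)))
    net_b = UNetSmall(1, config.base_channels, seed=int(rng.integers(2**31)))
    opt = Adam(net_a.params() + net_b.params(), lr=config.learning_rate)

    imgs_a = [rec.gray().astype(np.float32) for rec, _ in train_pairs]
    imgs_b = [rec.gray().astype(np.float32) for _, rec in train_pairs]

    batch = config.n_negatives + 1
    trace: List[float] = []
    for _ in range(config.steps):
        idx = rng.integers(0, len(train_pairs), size=batch)
        xa = np.empty((batch, 1, p, p), dtype=np.float32)
        xb = np.empty((batch, 1, p, p), dtype=np.float32)
        for j, i in enumerate(idx):
            h, w = imgs_a[i].shape
            r0 = int(rng.integers(0, h - p + 1))
            c0 = int(rng.integers(0, w - p + 1))
            xa[j, 0] = imgs_a[i][r0 : r0 + p, c0 : c0 + p]
            xb[j, 0] = imgs_b[i][r0 : r0 + p, c0 : c0 + p]

        k = int(rng.integers(0, 4))  # C4 element
        side = int(rng.integers(0, 2))  # 0: rotate A side, 1: rotate B side
        if side == 0:
            xa = np.ascontiguousarray(np.rot90(xa, k, axes=(2, 3)))
        else:
            xb = np.ascontiguousarray(np.rot90(xb, k, axes=(2, 3)))

        ra = net_a.forward(xa, train=True)
        rb = net_b.forward(xb, train=True)
        # restore alignment before the loss by inverse-rotating the
        # augmented side's representation
        if side == 0:
            ra_aligned = np.rot90(ra, -k, axes=(2, 3))
        else:
            ra_aligned = ra
        rb_aligned = np.rot90(rb, -k, axes=(2, 3)) if side == 1 else rb

        loss, dra, drb = _batched_infonce(
            np.ascontiguousarray(ra_aligned),
            np.ascontiguousarray(rb_aligned),
            config.temperature,
        )
        if side == 0:
            dra = np.rot90(dra, k, axes=(2, 3))
        else:
            drb = np.rot90(drb, k, axes=(2, 3))
        net_a.backward(np.ascontiguousarray(dra, dtype=np.float32))
        net_b.backward(np.ascontiguousarray(drb, dtype=np.float32))
        opt.step()
        trace.append(loss)

    pair = EncoderPair(
        encoder_A=Encoder(mod_a, net_a),
        encoder_B=Encoder(mod_b, net_b),
        config=config,
    )
    return pair, trace


def compute_representation(encoder: Encoder, img) -> Representation:
    """Apply one trained encoder to an image (any size); 1-channel output."""
    if img.modality != encoder.modality:
        raise ValueError(
            f"image modality {img.modality!r} does not match encoder "
            f"modality {encoder.modality!r}"
        )
    out = encoder(img.gray())
    return Representation(
        pixels=out.astype(np.float64), source_id=img.id, modality=img.modality
    )


def equivariance_error(encoder: Encoder, img, k: int) -> float:
    """Mean absolute deviation between rot_k(f(img)) and f(rot_k(img)).

    ``k`` counts 90-degree counterclockwise rotations (a C4 element);
    identity maps and k = 0 give exactly zero.
    """
    k = int(k) % 4
    px = np.asarray(img.gray() if hasattr(img, "gray") else img, dtype=np.float32)
    f_img = encoder(px)
    f_rot = encoder(np.ascontiguousarray(np.rot90(px, k)))
    return float(np.mean(np.abs(np.rot90(f_img, k) - f_rot)))


def save_encoders(pair: EncoderPair, path) -> None:
    """Single-file checkpoint with an embedded config snapshot."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(pair.config),
        "modality_A": pair.encoder_A.modality,
        "modality_B": pair.encoder_B.modality,
    }
    arrays = {"meta": np.frombuffer(json.dumps(payload).encode(), dtype=np.uint8)}
    for tag, enc in (("A", pair.encoder_A), ("B", pair.encoder_B)):
        for key, val in enc.net.state_dict().items():
            if isinstance(val, np.ndarray):
                arrays[f"{tag}_{key}"] = val
    np.savez(path, **arrays)


def load_encoders(path) -> EncoderPair:
    data = np.load(path)
    payload = json.loads(bytes(data["meta"]).decode())
    if payload["format_version"] != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(
            f"unsupported checkpoint format version {payload['format_version']}"
        )
    config = TrainConfig(**payload["config"])
    encoders = {}
    for tag, modality in (("A", payload["modality_A"]), ("B", payload["modality_B"])):
        net = UNetSmall(1, config.base_channels, seed=0)
        state = {k[2:]: data[k] for k in data.files if k.startswith(f"{tag}_")}
        net.load_state_dict(state)
        encoders[tag] = Encoder(modality, net)
    return EncoderPair(encoder_A=encoders["A"], encoder_B=encoders["B"], config=config)
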