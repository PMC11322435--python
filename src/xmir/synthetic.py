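"""Synthetic aligned pseudo-multimodal image pairs.

Emulates the statistical structure of a brightfield / second-harmonic
microscopy benchmark: each latent scene contains curvilinear fibers
(collagen-like strands) and blobs (cell-like masses).  Modality A is a
dense, texture-like rendering (inverted, blurred scene over a smooth
background texture with additive noise, like H&E brightfield); modality B
is sparse and structure-like (the fiber channel only, with multiplicative
speckle, like an SHG collagen signal).  The two share latent structure but
have very different raw appearance, which is exactly the gap the retrieval
pipeline has to bridge.

All randomness flows from one master seed through counter-based child
seeds, so regenerating a dataset is bit-exact and adding pairs does not
reshuffle existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .image_io import (
    DatasetManifest,
    ImageRecord,
    ManifestRow,
    RigidTransform,
    apply_rigid_transform,
    write_image,
    write_manifest,
)

__all__ = [
    "SceneParams",
    "LatentScene",
    "generate_latent_scene",
    "render_modality_pair",
    "sample_rigid_transform",
    "largest_remainder_split",
    "generate_pairs",
    "generate_dataset",
]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene; identical params => identical output."""

    size: int = 512
    n_fibers: int = 12
    fiber_width_px: float = 2.5
    n_blobs: int = 10
    blob_sigma_px: float = 12.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.n_fibers < 0 or self.n_blobs < 0:
            raise ValueError("object counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class LatentScene:
    """Latent structure shared by both rendered modalities.

    ``fibers`` and ``blobs`` are the two structural channels; ``combined``
    is their 2-D superposition clipped to [0, 1].
    """

    fibers: np.ndarray
    blobs: np.ndarray
    params: SceneParams

    @property
    def combined(self) -> np.ndarray:
        return np.clip(self.fibers + self.blobs, 0.0, 1.0)


def generate_latent_scene(params: SceneParams) -> LatentScene:
    """Draw random curvilinear fibers and Gaussian blobs on a zero background."""
    rng = np.random.default_rng(params.seed)
    n = params.size
    fiber_mask = np.zeros((n, n), dtype=np.float64)
    for _ in range(params.n_fibers):
        # smoothed random-walk stroke: unit steps with slowly drifting heading
        length = int(rng.uniform(0.5, 1.5) * n)
        y, x = rng.uniform(0, n, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        curvature = rng.normal(0.0, 0.02)
        for _ in range(length):
            heading += curvature + rng.normal(0.0, 0.01)
            y += np.sin(heading)
            x += np.cos(heading)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < n and 0 <= ix < n:
                fiber_mask[iy, ix] = 1.0
    if params.n_fibers > 0 and fiber_mask.any():
        fibers = ndimage.gaussian_filter(fiber_mask, params.fiber_width_px / 2.0)
        fibers /= fibers.max()
    else:
        fibers = fiber_mask

    blobs = np.zeros((n, n), dtype=np.float64)
    sig = params.blob_sigma_px
    half = max(1, int(np.ceil(3 * sig)))
    for _ in range(params.n_blobs):
        cy, cx = rng.uniform(0, n, size=2)
        amp = rng.uniform(0.4, 0.9)
        y0, y1 = max(0, int(cy) - half), min(n, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(n, int(cx) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        blobs[y0:y1, x0:x1] += amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2)
        )
    blobs = np.clip(blobs, 0.0, 1.0)
    return LatentScene(fibers=np.clip(fibers, 0.0, 1.0), blobs=blobs, params=params)


def render_modality_pair(
    scene: LatentScene,
    pair_id: str = "pair",
    *,
    texture: bool = True,
    blur_sigma: float = 1.5,
) -> Tuple[ImageRecord, ImageRecord]:
    """Render the dense (A) and sparse (B) modality from one latent scene.

    A = 1 - blur(latent) + smooth background texture + additive Gaussian
    noise; B = fibers channel with multiplicative speckle.  With
    ``noise_sd=0`` and ``texture=False``, A is exactly ``1 - blur(latent)``.
    The pair is pixel-aligned by construction.
    """
    params = scene.params
    rng = np.random.default_rng([params.seed, 1])
    latent = scene.combined

    a = 1.0 - ndimage.gaussian_filter(latent, blur_sigma)
    if texture:
        field = ndimage.gaussian_filter(rng.standard_normal(latent.shape), 12.0)
        span = np.abs(field).max()
        if span > 0:
            field = field / span  # smooth field in [-1, 1]
        a = a + 0.18 * field
    if params.noise_sd > 0:
        a = a + rng.normal(0.0, params.noise_sd, size=latent.shape)
    a = np.clip(a, 0.0, 1.0)

    b = scene.fibers.copy()
    if params.noise_sd > 0:
        speckle = 1.0 + rng.normal(0.0, 2.0 * params.noise_sd, size=latent.shape)
        b = b * np.clip(speckle, 0.0, None)
    b = np.clip(b, 0.0, 1.0)

    rec_a = ImageRecord(id=pair_id, modality="A", pixels=a)
    rec_b = ImageRecord(id=pair_id, modality="B", pixels=b)
    return rec_a, rec_b


def sample_rigid_transform(
    max_angle_deg: float,
    max_trans_px: float,
    rng,
) -> RigidTransform:
    """Uniform rotation in ±max_angle_deg and translations in ±max_trans_px."""
    if max_angle_deg < 0 or max_trans_px < 0:
        raise ValueError("transform bounds must be >= 0")
    rng = np.random.default_rng(rng)
    angle = rng.uniform(-max_angle_deg, max_angle_deg) if max_angle_deg > 0 else 0.0
    tx = rng.uniform(-max_trans_px, max_trans_px) if max_trans_px > 0 else 0.0
    ty = rng.uniform(-max_trans_px, max_trans_px) if max_trans_px > 0 else 0.0
    return RigidTransform(angle_deg=angle, tx=tx, ty=ty)


def largest_remainder_split(n: int, fractions: Sequence[float]) -> list:
    """Apportion n items to the fractions by the largest-remainder method.

    Leftover seats go to the largest fractional remainders; ties are broken
    by position (earlier fraction wins), which keeps the result deterministic.
    """
    fr = np.asarray(fractions, dtype=float)
    if not np.isclose(fr.sum(), 1.0):
        raise ValueError("split fractions must sum to 1")
    quotas = n * fr
    counts = np.floor(quotas).astype(int)
    remainder = quotas - counts
    for _ in range(n - counts.sum()):
        i = int(np.argmax(remainder))
        counts[i] += 1
        remainder[i] = -1.0
    return counts.tolist()


def generate_pairs(
    n_pairs: int,
    *,
    params: SceneParams = SceneParams(),
    master_seed: int = 0,
) -> list:
    """Generate n_pairs aligned (A, B) ImageRecord pairs in memory.

    Pair i is derived from counter-based child seed i of the master seed,
    exactly as :func:`generate_dataset` does before writing to disk.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    width = max(3, len(str(n_pairs - 1)))
    out = []
    for i in range(n_pairs):
        pid = f"p{i:0{width}d}"
        scene = generate_latent_scene(
            replace(params, seed=_child_seed(master_seed, i))
        )
        out.append(render_modality_pair(scene, pair_id=pid))
    return out


def generate_dataset(
    n_pairs: int,
    out_dir,
    *,
    params: SceneParams = SceneParams(),
    splits: Sequence[float] = (0.2, 0.15, 0.65),
    master_seed: int = 0,
    max_angle_deg: float = 30.0,
    max_trans_px: float = 100.0,
    transform_splits: Sequence[str] = ("test",),
) -> DatasetManifest:
    """Write n_pairs aligned (A, B) PNG pairs plus rigidly transformed query
    copies, and the CSV manifest describing them.

    Transformed copies are materialized on disk under the modality labels
    ``A_T``/``B_T`` (one transform per pair, applied to both modalities), so
    experiments re-run bit-exactly.  ``transform_splits`` selects which
    splits receive query copies; pass ``("train", "val", "test")`` to
    transform every pair.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    counts = largest_remainder_split(n_pairs, splits)
    split_labels = []
    for label, cnt in zip(("train", "val", "test"), counts):
        split_labels.extend([label] * cnt)

    rows = []
    width = max(3, len(str(n_pairs - 1)))
    for i in range(n_pairs):
        pid = f"p{i:0{width}d}"
        split = split_labels[i]
        scene = generate_latent_scene(
            replace(params, seed=_child_seed(master_seed, i))
        )
        rec_a, rec_b = render_modality_pair(scene, pair_id=pid)
        for rec, mod in ((rec_a, "A"), (rec_b, "B")):
            rel = f"images/{pid}_{mod}.png"
            write_image(rec, out_dir / rel)
            rows.append(ManifestRow(pair_id=pid, modality=mod, path=rel, split=split))
        if split in transform_splits:
            t = sample_rigid_transform(
                max_angle_deg, max_trans_px, [master_seed, i, 1]
            )
            for rec, mod in ((rec_a, "A"), (rec_b, "B")):
                rel = f"images/{pid}_{mod}_T.png"
                write_image(apply_rigid_transform(rec, t), out_dir / rel)
                rows.append(
                    ManifestRow(
                        pair_id=pid,
                        modality=f"{mod}_T",
                        path=rel,
                        split=split,
                        transform=t,
                    )
                )

    manifest = DatasetManifest(rows=rows, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def _child_seed(master_seed: int, index: int) -> int:
    # counter-based fan-out: adding pairs never reshuffles existing ones
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])
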