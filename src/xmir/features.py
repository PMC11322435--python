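"""Dense-grid extraction of sparse, rotation-invariant local descriptors.

Keypoints are placed on a regular grid at several patch scales (no
interest-point detection): a keypoint at grid node ``(x, y)`` with scale
``s`` describes the ``s x s`` window whose top-left corner is the node.
Two descriptor families are provided:

* ``surf_like`` (64-D): 4x4 subregions of first-derivative response sums
  ``(sum dx, sum |dx|, sum dy, sum |dy|)``, computed from Gaussian-smoothed
  gradients sampled on a rotated grid and steered to the keypoint's
  dominant orientation; strength is the determinant-of-Hessian response.
* ``sift_like`` (128-D): 4x4 spatial cells x 8 orientation bins of
  gradient-magnitude histograms; strength is the difference-of-Gaussians
  magnitude.

Dominant-orientation normalization makes both descriptors rotation
invariant (exactly so, up to interpolation, for 90-degree multiples); it
can be disabled to obtain a deliberately non-invariant variant for
ablation experiments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractorConfig",
    "FeatureSet",
    "detect_and_describe",
    "filter_strongest",
]


@dataclass(frozen=True)
class ExtractorConfig:
    """Configuration of the dense-grid descriptor extractor.

    ``scales`` are descriptor support sizes in px; ``grid_spacing`` is the
    (row, col) node spacing.  ``n_samples`` is the per-axis count of
    response samples inside the support window (must be a multiple of the
    4x4 subregion grid).  ``initial_sigma`` sets the Gaussian smoothing
    scale at ``sigma_ref_scale`` px support; smoothing grows linearly with
    the support size (one octave per doubling).
    """

    kind: str = "surf_like"
    grid_spacing: Tuple[int, int] = (8, 8)
    scales: Tuple[int, ...] = (32, 64, 96, 128)
    n_samples: int = 20
    orientation_normalize: bool = True
    n_orientation_bins: int = 8
    initial_sigma: float = 1.6
    sigma_ref_scale: int = 32

    def __post_init__(self) -> None:
        if self.kind not in ("surf_like", "sift_like"):
            raise ValueError(f"unknown extractor kind {self.kind!r}")
        if min(self.grid_spacing) < 1:
            raise ValueError("grid spacing must be >= 1")
        if list(self.scales) != sorted(self.scales):
            raise ValueError("scales must be sorted ascending")
        if self.n_samples % 4 != 0:
            raise ValueError("n_samples must be a multiple of 4")

    @property
    def descriptor_length(self) -> int:
        return 64 if self.kind == "surf_like" else 16 * self.n_orientation_bins

    def smoothing_sigma(self, scale: int) -> float:
        return self.initial_sigma * scale / self.sigma_ref_scale


@dataclass
class FeatureSet:
    """Keypoints and fixed-length descriptors for one image.

    ``keypoints`` has columns (x, y, scale, strength); row i corresponds to
    descriptor row i.  May be empty (e.g. a uniform image at all scales
    too large).
    """

    image_id: str
    keypoints: np.ndarray
    descriptors: np.ndarray

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=np.float64).reshape(-1, 4)
        self.descriptors = np.asarray(self.descriptors, dtype=np.float32)
        if self.descriptors.ndim == 1:
            self.descriptors = self.descriptors.reshape(0, 0)
        if len(self.keypoints) != len(self.descriptors):
            raise ValueError("keypoint/descriptor count mismatch")

    def __len__(self) -> int:
        return len(self.keypoints)

    @property
    def strengths(self) -> np.ndarray:
        return self.keypoints[:, 3]

    @property
    def zero_strength(self) -> bool:
        """True when no keypoint carries any detector response."""
        return len(self) > 0 and not np.any(self.strengths > 0)


def _as_gray(img) -> np.ndarray:
    if hasattr(img, "gray"):
        return np.asarray(img.gray(), dtype=np.float64)
    arr = np.asarray(img, dtype=np.float64)
    return arr.mean(axis=2) if arr.ndim == 3 else arr


def _minmax_rescale(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _bilinear(map2d: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    h, w = map2d.shape
    ys = np.clip(ys, 0.0, h - 1.000001)
    xs = np.clip(xs, 0.0, w - 1.000001)
    y0 = ys.astype(np.int64)
    x0 = xs.astype(np.int64)
    fy = (ys - y0).astype(np.float32)
    fx = (xs - x0).astype(np.float32)
    v00 = map2d[y0, x0]
    v01 = map2d[y0, x0 + 1]
    v10 = map2d[y0 + 1, x0]
    v11 = map2d[y0 + 1, x0 + 1]
    return (
        v00 * (1 - fy) * (1 - fx)
        + v01 * (1 - fy) * fx
        + v10 * fy * (1 - fx)
        + v11 * fy * fx
    )


def _grid_nodes(extent: int, scale: int, spacing: int) -> np.ndarray:
    if extent < scale:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, extent - scale + 1, spacing, dtype=np.int64)


def _sample_offsets(scale: int, n: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axis-aligned sample offsets relative to the window center, the
    Gaussian window weights, and the flattened sample order (row-major)."""
    u = (np.arange(n) + 0.5) / n * scale - scale / 2.0
    uy, ux = np.meshgrid(u, u, indexing="ij")
    w = np.exp(-(ux**2 + uy**2) / (2.0 * (0.4 * scale) ** 2)).astype(np.float32)
    return ux.ravel(), uy.ravel(), w.ravel()


def _describe_scale(
    gray: np.ndarray, scale: int, cfg: ExtractorConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """All keypoints and descriptors for a single scale."""
    h, w = gray.shape
    sy, sx = cfg.grid_spacing
    xs = _grid_nodes(w, scale, sx)
    ys = _grid_nodes(h, scale, sy)
    if len(xs) == 0 or len(ys) == 0:
        return np.empty((0, 4)), np.empty((0, cfg.descriptor_length), np.float32)
    gx_nodes, gy_nodes = np.meshgrid(xs, ys, indexing="xy")
    nodes_x = gx_nodes.ravel().astype(np.float64)
    nodes_y = gy_nodes.ravel().astype(np.float64)
    ctr_x = nodes_x + (scale - 1) / 2.0
    ctr_y = nodes_y + (scale - 1) / 2.0
    n_kp = len(nodes_x)

    sigma = cfg.smoothing_sigma(scale)
    smooth = ndimage.gaussian_filter(gray, sigma)
    gy_map, gx_map = np.gradient(smooth)
    gx_map = gx_map.astype(np.float32)
    gy_map = gy_map.astype(np.float32)

    # detector response
    if cfg.kind == "surf_like":
        lxx = ndimage.gaussian_filter(gray, sigma, order=(0, 2))
        lyy = ndimage.gaussian_filter(gray, sigma, order=(2, 0))
        lxy = ndimage.gaussian_filter(gray, sigma, order=(1, 1))
        resp = np.abs(sigma**4 * (lxx * lyy - lxy**2)).astype(np.float32)
    else:
        k = 2.0 ** 0.25  # 4 steps per octave
        resp = np.abs(smooth - ndimage.gaussian_filter(gray, k * sigma)).astype(
            np.float32
        )
    strength = _bilinear(resp, ctr_y, ctr_x).astype(np.float64)

    ux, uy, wgt = _sample_offsets(scale, cfg.n_samples)

    if cfg.orientation_normalize:
        oy = ctr_y[:, None] + uy[None, :]
        ox = ctr_x[:, None] + ux[None, :]
        sgx = (_bilinear(gx_map, oy, ox) * wgt).sum(axis=1)
        sgy = (_bilinear(gy_map, oy, ox) * wgt).sum(axis=1)
        theta = np.arctan2(sgy, sgx)
    else:
        theta = np.zeros(n_kp)

    ct = np.cos(theta).astype(np.float32)[:, None]
    st = np.sin(theta).astype(np.float32)[:, None]
    # rotate the sampling grid into the keypoint frame
    rx = ct * ux[None, :] - st * uy[None, :]
    ry = st * ux[None, :] + ct * uy[None, :]
    py = ctr_y[:, None] + ry
    px = ctr_x[:, None] + rx
    gx_s = _bilinear(gx_map, py, px)
    gy_s = _bilinear(gy_map, py, px)
    # steer responses to the keypoint orientation
    gxr = ct * gx_s + st * gy_s
    gyr = -st * gx_s + ct * gy_s

    n = cfg.n_samples
    q = n // 4
    if cfg.kind == "surf_like":
        gxw = (gxr * wgt).reshape(n_kp, 4, q, 4, q)
        gyw = (gyr * wgt).reshape(n_kp, 4, q, 4, q)
        parts = [
            gxw.sum(axis=(2, 4)),
            np.abs(gxw).sum(axis=(2, 4)),
            gyw.sum(axis=(2, 4)),
            np.abs(gyw).sum(axis=(2, 4)),
        ]
        desc = np.stack(parts, axis=-1).reshape(n_kp, 64)
    else:
        nb = cfg.n_orientation_bins
        mag = np.hypot(gxr, gyr) * wgt
        phi = np.arctan2(gyr, gxr) % (2 * np.pi)
        fb = phi / (2 * np.pi) * nb
        b0 = np.floor(fb).astype(np.int64) % nb
        frac = (fb - np.floor(fb)).astype(np.float32)
        b1 = (b0 + 1) % nb
        cell = (
            (np.arange(n) // q)[:, None].repeat(n, 1) * 4
            + (np.arange(n) // q)[None, :]
        ).ravel()  # spatial cell id 0..15, row-major over (iy, ix)
        flat0 = cell[None, :] * nb + b0
        flat1 = cell[None, :] * nb + b1
        desc = np.zeros((n_kp, 16 * nb), dtype=np.float32)
        rows = np.repeat(np.arange(n_kp), n * n)
        np.add.at(desc, (rows, flat0.ravel()), (mag * (1 - frac)).ravel())
        np.add.at(desc, (rows, flat1.ravel()), (mag * frac).ravel())

    desc = _l2_normalize(desc)
    if cfg.kind == "sift_like":
        # standard illumination clamp: limit single-bin dominance
        desc = _l2_normalize(np.minimum(desc, 0.2))

    kps = np.column_stack([nodes_x, nodes_y, np.full(n_kp, scale, float), strength])
    return kps, desc.astype(np.float32)


def _l2_normalize(desc: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, desc / norms, desc)
    return out.astype(np.float32)


def detect_and_describe(img, cfg: ExtractorConfig = ExtractorConfig()) -> FeatureSet:
    """Extract grid keypoints with descriptors at every configured scale.

    Image intensities are min-max rescaled to [0, 1] before description
    (constant images yield zero responses).  Scales larger than the image
    are skipped with a warning; if all are skipped the set is empty.
    """
    gray = _minmax_rescale(_as_gray(img))
    h, w = gray.shape
    image_id = getattr(img, "id", "image")
    all_kps: List[np.ndarray] = []
    all_desc: List[np.ndarray] = []
    for scale in cfg.scales:
        if scale > min(h, w):
            logger.warning(
                "scale %d skipped for image %s (%dx%d too small)",
                scale, image_id, h, w,
            )
            continue
        kps, desc = _describe_scale(gray, int(scale), cfg)
        all_kps.append(kps)
        all_desc.append(desc)
    if not all_kps:
        return FeatureSet(
            image_id=image_id,
            keypoints=np.empty((0, 4)),
            descriptors=np.empty((0, cfg.descriptor_length), np.float32),
        )
    return FeatureSet(
        image_id=image_id,
        keypoints=np.concatenate(all_kps, axis=0),
        descriptors=np.concatenate(all_desc, axis=0),
    )


def filter_strongest(
    feature_sets: Sequence[FeatureSet], fraction: float
) -> List[FeatureSet]:
    """Keep the ceil(fraction * n) strongest features pooled across sets.

    The cutoff is global over the whole repository; ties at the cutoff are
    all kept, and the original order within each image is preserved.
    Queries are never passed through this filter - it applies only to the
    repository pool the vocabulary is built from.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    pooled = np.concatenate([fs.strengths for fs in feature_sets]) if feature_sets else np.empty(0)
    if pooled.size == 0:
        return list(feature_sets)
    if fraction == 1.0:
        return list(feature_sets)
    n_keep = math.ceil(fraction * pooled.size)
    cutoff = np.sort(pooled)[::-1][n_keep - 1]
    out = []
    for fs in feature_sets:
        mask = fs.strengths >= cutoff
        out.append(
            FeatureSet(
                image_id=fs.image_id,
                keypoints=fs.keypoints[mask],
                descriptors=fs.descriptors[mask],
            )
        )
    return out
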