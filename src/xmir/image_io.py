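"""Image and manifest I/O, preprocessing and rigid query transforms.

Conventions used throughout the package: pixel arrays are float64 in
[0, 1], 0-based row-major indexing with ``(row=y, col=x)``; rotations are
counterclockwise (as displayed) about the exact image center
``((H-1)/2, (W-1)/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageRecord",
    "RigidTransform",
    "DatasetManifest",
    "ManifestRow",
    "read_image",
    "write_image",
    "log_preprocess",
    "apply_rigid_transform",
    "crop_center",
    "load_manifest",
    "write_manifest",
]

VALID_SPLITS = ("train", "val", "test")

MANIFEST_COLUMNS = ["pair_id", "modality", "path", "split", "angle_deg", "tx", "ty"]


class FormatError(ValueError):
    """Raised for image files with unsupported layouts or bit depths."""


@dataclass
class ImageRecord:
    """A single 2-D image: grayscale ``(H, W)`` or RGB ``(H, W, 3)`` in [0, 1]."""

    id: str
    modality: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(
                f"pixels must be (H, W) or (H, W, 3); got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def gray(self) -> np.ndarray:
        """Single-channel view: RGB images are averaged over channels."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.mean(axis=2)


@dataclass(frozen=True)
class RigidTransform:
    """Counterclockwise rotation about the image center followed by a
    translation of ``(tx, ty)`` pixels (x = columns, y = rows)."""

    angle_deg: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def inverse(self) -> "RigidTransform":
        """Analytic inverse: undo the translation, then the rotation.

        Composing a transform with its inverse is the identity map; since
        :func:`apply_rigid_transform` rotates first, the inverse transform
        carries the back-rotated translation.
        """
        a = math.radians(self.angle_deg)
        # forward: p' = R(p - c) + c + t  =>  inverse: rotate by -angle,
        # translate by -R^{-1} t (expressed in the rotated frame).
        ca, sa = math.cos(a), math.sin(a)
        # y-down frame: displayed-CCW rotation matrix is [[ca, sa], [-sa, ca]]
        itx = -(ca * self.tx - sa * self.ty)
        ity = -(sa * self.tx + ca * self.ty)
        return RigidTransform(angle_deg=-self.angle_deg, tx=itx, ty=ity)


@dataclass(frozen=True)
class ManifestRow:
    pair_id: str
    modality: str
    path: str
    split: str
    transform: Optional[RigidTransform] = None


@dataclass
class DatasetManifest:
    """Rows describing a two-modality paired image dataset.

    ``(pair_id, modality)`` is unique; ``split`` is one of train/val/test.
    ``root`` is the directory image paths are resolved against.
    """

    rows: list = field(default_factory=list)
    root: Optional[Path] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen = set()
        for row in self.rows:
            if row.split not in VALID_SPLITS:
                raise ValueError(
                    f"unknown split {row.split!r} for pair {row.pair_id!r}; "
                    f"expected one of {VALID_SPLITS}"
                )
            key = (row.pair_id, row.modality)
            if key in seen:
                raise ValueError(f"duplicate (pair_id, modality) entry: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def modalities(self) -> list:
        out = []
        for row in self.rows:
            if row.modality not in out:
                out.append(row.modality)
        return out

    def select(self, modality: Optional[str] = None, split: Optional[str] = None):
        """Rows filtered by modality and/or split, in manifest order."""
        out = []
        for row in self.rows:
            if modality is not None and row.modality != modality:
                continue
            if split is not None and row.split != split:
                continue
            out.append(row)
        return out

    def resolve_path(self, row: ManifestRow) -> Path:
        p = Path(row.path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p


def read_image(path, modality: str, image_id: Optional[str] = None) -> ImageRecord:
    """Read a PNG or TIFF image, rescaling integer dtypes by their full range.

    8-bit data is divided by 255, 16-bit by 65535; per-image min-max scaling
    is deliberately avoided so that global intensity information is not
    leaked across the query/repository split.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(str(path))
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"could not read image {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        px = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        px = arr.astype(np.float64) / 65535.0
    elif arr.dtype == np.int32:
        # PIL mode "I" (32-bit) PNGs written from 16-bit data
        if arr.min() < 0 or arr.max() > 65535:
            raise FormatError(f"unsupported integer range in {path}")
        px = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        px = arr.astype(np.float64)
        if not np.all(np.isfinite(px)) or px.min() < 0 or px.max() > 1:
            raise FormatError(
                f"floating-point image {path} must already be in [0, 1]"
            )
    else:
        raise FormatError(f"unsupported bit depth/dtype {arr.dtype} in {path}")
    return ImageRecord(id=image_id or path.stem, modality=modality, pixels=px)


def write_image(img: ImageRecord, path, bit_depth: int = 16) -> None:
    """Write an image as 8- or 16-bit PNG (or TIFF by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bit_depth == 16:
        arr = np.round(img.pixels * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(img.pixels * 255.0).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), arr)
        return
    if arr.ndim == 3 and bit_depth != 8:
        raise ValueError("RGB PNG output supports bit_depth=8 only")
    Image.fromarray(arr).save(path)


def log_preprocess(img: ImageRecord, c: float = 255.0) -> ImageRecord:
    """Logarithmic dynamic-range compression: x -> log(1 + c*x) / log(1 + c).

    Monotone and endpoint-preserving on [0, 1]; used for the sparse
    high-dynamic-range modality (SHG-like images) before representation
    learning.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    px = np.log1p(c * img.pixels) / np.log1p(c)
    return ImageRecord(id=img.id, modality=img.modality, pixels=np.clip(px, 0.0, 1.0))


def _warp_channel(ch: np.ndarray, t: RigidTransform) -> np.ndarray:
    h, w = ch.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a = math.radians(t.angle_deg)
    ca, sa = math.cos(a), math.sin(a)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # inverse map of: rotate CCW (displayed) about center, then translate
    xq = xx - t.tx - cx
    yq = yy - t.ty - cy
    # displayed-CCW forward matrix in (x, y-down) is [[ca, sa], [-sa, ca]];
    # its inverse is the transpose
    xs = ca * xq - sa * yq + cx
    ys = sa * xq + ca * yq + cy
    # snap to the grid where rounding error alone moved a coordinate off an
    # integer, so 90-degree multiples permute pixels exactly
    xs_r = np.round(xs)
    ys_r = np.round(ys)
    xs = np.where(np.abs(xs - xs_r) < 1e-9, xs_r, xs)
    ys = np.where(np.abs(ys - ys_r) < 1e-9, ys_r, ys)
    return ndimage.map_coordinates(
        ch, [ys, xs], order=1, mode="constant", cval=0.0, prefilter=False
    )


def apply_rigid_transform(img: ImageRecord, t: RigidTransform) -> ImageRecord:
    """Rotate about the image center, then translate; bilinear, zero fill.

    Multiples of 90 degrees with zero translation permute pixels exactly.
    """
    if img.pixels.ndim == 2:
        px = _warp_channel(img.pixels, t)
    else:
        px = np.stack(
            [_warp_channel(img.pixels[:, :, k], t) for k in range(3)], axis=2
        )
    return ImageRecord(
        id=img.id, modality=img.modality, pixels=np.clip(px, 0.0, 1.0)
    )


def crop_center(img: ImageRecord, size: int) -> ImageRecord:
    """Central ``size``-square window, top-left at ``((H-size)//2, (W-size)//2)``."""
    if size < 1:
        raise ValueError("size must be >= 1")
    if size > min(img.height, img.width):
        raise ValueError(
            f"crop size {size} exceeds image extent {img.height}x{img.width}"
        )
    r0 = (img.height - size) // 2
    c0 = (img.width - size) // 2
    return ImageRecord(
        id=img.id,
        modality=img.modality,
        pixels=img.pixels[r0 : r0 + size, c0 : c0 + size].copy(),
    )


def load_manifest(path) -> DatasetManifest:
    """Load a CSV manifest (``pair_id,modality,path,split,angle_deg,tx,ty``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"pair_id": str, "modality": str, "path": str, "split": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    rows = []
    for rec in df.itertuples(index=False):
        angle, tx, ty = rec.angle_deg, rec.tx, rec.ty
        has_t = not (pd.isna(angle) and pd.isna(tx) and pd.isna(ty))
        transform = None
        if has_t:
            transform = RigidTransform(
                angle_deg=float(0.0 if pd.isna(angle) else angle),
                tx=float(0.0 if pd.isna(tx) else tx),
                ty=float(0.0 if pd.isna(ty) else ty),
            )
        rows.append(
            ManifestRow(
                pair_id=str(rec.pair_id),
                modality=str(rec.modality),
                path=str(rec.path),
                split=str(rec.split),
                transform=transform,
            )
        )
    return DatasetManifest(rows=rows, root=path.parent)


def write_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for row in manifest.rows:
        t = row.transform
        records.append(
            {
                "pair_id": row.pair_id,
                "modality": row.modality,
                "path": row.path,
                "split": row.split,
                "angle_deg": "" if t is None else repr(t.angle_deg),
                "tx": "" if t is None else repr(t.tx),
                "ty": "" if t is None else repr(t.ty),
            }
        )
    pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS).to_csv(
        path, index=False
    )
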