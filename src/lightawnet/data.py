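"""Data loading, normalization, dataset splits and synthetic fixtures.

Real inputs come as NIfTI volumes (CT/MR, sliced along the stacking axis),
PNG/JPEG photographs with mask images, or cached ``.npy`` arrays. Every
loaded sample is normalized to a float image in [0, 1] with a binary mask.
The synthetic generator produces seeded soft-edged elliptical blobs on noisy
backgrounds with exact masks, standing in for the clinical datasets in tests
and examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:  # nibabel is only needed for NIfTI volumes
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

from PIL import Image


@dataclass
class SliceSample:
    """One 2D training sample: image in [0,1], binary mask, identifiers."""

    image: np.ndarray            # (H, W) or (H, W, C), float32 in [0, 1]
    mask: np.ndarray             # (H, W), uint8 in {0, 1}
    case_id: str = ""
    slice_index: int = 0

    def validate(self) -> "SliceSample":
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} "
                f"disagree on H x W (case {self.case_id!r})")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError(f"image outside [0,1] (case {self.case_id!r})")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError(f"mask not binary (case {self.case_id!r})")
        return self

    def chw(self) -> np.ndarray:
        """Image as (C, H, W) float32 for the network."""
        img = self.image
        if img.ndim == 2:
            return img[None].astype(np.float32)
        return np.moveaxis(img, -1, 0).astype(np.float32)


def minmax_normalize(arr: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant array maps to zeros."""
    arr = arr.astype(np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def load_volume_slices(image_path, label_path) -> list[SliceSample]:
    """Slice a NIfTI image/label volume pair along the stacking axis.

    Intensities are min-max normalized per volume; labels are binarized
    (any nonzero structure counts as foreground). The stacking axis is the
    last array axis.
    """
    if nib is None:  # pragma: no cover
        raise ImportError("nibabel is required for NIfTI volumes")
    img_vol = np.asanyarray(nib.load(str(image_path)).dataobj)
    lab_vol = np.asanyarray(nib.load(str(label_path)).dataobj)
    if img_vol.shape != lab_vol.shape:
        raise ValueError(
            f"image {img_vol.shape} and label {lab_vol.shape} shapes differ "
            f"({image_path} vs {label_path})")
    img_vol = minmax_normalize(img_vol)
    case = Path(image_path).name.split(".")[0]
    samples = []
    for k in range(img_vol.shape[-1]):
        samples.append(SliceSample(
            image=img_vol[..., k],
            mask=(lab_vol[..., k] != 0).astype(np.uint8),
            case_id=case, slice_index=k).validate())
    return samples


def load_image_pair(img_path, mask_path, target_hw=None) -> SliceSample:
    """Load a photograph + mask image, optionally resizing to (H, W).

    The image is resized bilinearly and scaled by 1/255; the mask is resized
    with nearest-neighbour so it stays binary.
    """
    img = Image.open(img_path)
    mask = Image.open(mask_path).convert("L")
    if target_hw is not None:
        h, w = target_hw
        img = img.resize((w, h), Image.BILINEAR)
        mask = mask.resize((w, h), Image.NEAREST)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    m = (np.asarray(mask) > 127).astype(np.uint8)
    return SliceSample(image=np.clip(arr, 0.0, 1.0), mask=m,
                       case_id=Path(img_path).stem).validate()


def save_npy_cache(samples: list[SliceSample], directory) -> None:
    """Mirror a sample list as .npy files (image/mask pairs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in samples:
        stem = f"{s.case_id}_{s.slice_index:04d}"
        np.save(directory / f"{stem}_img.npy", s.image)
        np.save(directory / f"{stem}_mask.npy", s.mask)


def load_npy_cache(directory) -> list[SliceSample]:
    directory = Path(directory)
    samples = []
    for img_file in sorted(directory.glob("*_img.npy")):
        stem = img_file.name[:-8]
        case, _, idx = stem.rpartition("_")
        samples.append(SliceSample(
            image=np.load(img_file),
            mask=np.load(directory / f"{stem}_mask.npy"),
            case_id=case, slice_index=int(idx)).validate())
    return samples


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass
class SplitManifest:
    """Disjoint id partitions whose union is the full id list."""

    partitions: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self, all_ids=None) -> "SplitManifest":
        seen: list = []
        for ids in self.partitions.values():
            seen.extend(ids)
        if len(seen) != len(set(seen)):
            raise ValueError("partitions overlap")
        if all_ids is not None and set(seen) != set(all_ids):
            raise ValueError("partitions do not cover all ids")
        return self

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "partitions": self.partitions},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitManifest":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(partitions=doc["partitions"], seed=doc["seed"]).validate()


def make_splits(ids, scheme, seed: int = 0) -> SplitManifest:
    """Deterministic case-level splits.

    ``scheme`` is ``("ratio", (a, b, ...))`` for a proportional split (sizes
    by largest remainder after flooring) or ``("kfold", k)`` for k folds.
    """
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    kind, arg = scheme
    parts: dict[str, list] = {}
    if kind == "ratio":
        weights = np.asarray(arg, dtype=float)
        exact = weights / weights.sum() * len(ids)
        sizes = np.floor(exact).astype(int)
        for _ in range(len(ids) - sizes.sum()):
            j = int(np.argmax(exact - sizes))
            sizes[j] += 1
        names = (["train", "val", "test"] if len(weights) == 3
                 else ["train", "test"] if len(weights) == 2
                 else [f"part{i}" for i in range(len(weights))])
        pos = 0
        for name, n in zip(names, sizes):
            parts[name] = order[pos:pos + n]
            pos += n
    elif kind == "kfold":
        k = int(arg)
        if k > len(ids):
            raise ValueError(f"k={k} folds but only {len(ids)} cases")
        for i in range(k):
            parts[f"fold{i}"] = order[i::k]
    else:
        raise ValueError(f"unknown split scheme {kind!r}")
    return SplitManifest(partitions=parts, seed=seed).validate(ids)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def generate_synthetic(n: int, H: int = 224, W: int = 224, channels: int = 1,
                       seed: int = 0, noise_sd: float = 0.08,
                       max_blobs: int = 3) -> list[SliceSample]:
    """Seeded blob phantoms: soft-edged elliptical foregrounds on noise.

    Each image holds 1..max_blobs elliptical blobs. The noiseless blob field
    is thresholded at 0.5 for the exact ground-truth mask, then smoothed
    intensity contrast plus Gaussian background noise (sd ``noise_sd``)
    forms the image, clipped to [0, 1]. Bit-identical per (n, H, W, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float32)
    samples = []
    for i in range(n):
        nblob = int(rng.integers(1, max_blobs + 1))
        fieldmap = np.zeros((H, W), dtype=np.float32)
        for _ in range(nblob):
            cy = rng.uniform(0.2 * H, 0.8 * H)
            cx = rng.uniform(0.2 * W, 0.8 * W)
            ry = rng.uniform(0.08, 0.22) * H
            rx = rng.uniform(0.08, 0.22) * W
            theta = rng.uniform(0, np.pi)
            ct, st = np.cos(theta), np.sin(theta)
            u = (ct * (xx - cx) + st * (yy - cy)) / rx
            v = (-st * (xx - cx) + ct * (yy - cy)) / ry
            d2 = u * u + v * v
            # smooth radial profile: ~1 inside, 0.5 at the ellipse boundary
            z = np.clip(8.0 * (d2 - 1.0), -60.0, 60.0)
            fieldmap = np.maximum(fieldmap, 1.0 / (1.0 + np.exp(z)))
        mask = (fieldmap > 0.5).astype(np.uint8)
        img = 0.25 + 0.6 * fieldmap + rng.normal(
            0.0, noise_sd, size=(H, W)).astype(np.float32)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        if channels > 1:
            img = np.repeat(img[..., None], channels, axis=-1)
        samples.append(SliceSample(image=img, mask=mask,
                                   case_id=f"synth{i:03d}",
                                   slice_index=0).validate())
    return samples


def stack_batch(samples: list[SliceSample]):
    """(B, C, H, W) image batch and (B, 1, H, W) mask batch."""
    imgs = np.stack([s.chw() for s in samples])
    masks = np.stack([s.mask[None] for s in samples]).astype(np.float32)
    return imgs, masks
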