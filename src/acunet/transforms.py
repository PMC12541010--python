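"""Intensity normalisation, resampling and paired geometric augmentation.

Intensity standardisation is per-channel and per-slice over the whole slice
(no brain masking); constant channels map to all zeros under both modes.
Masks are always resampled with nearest-neighbour interpolation so the
categorical label set survives; images use linear interpolation.  Scaling
augmentation re-crops or zero-pads centrally back to the original shape so
batch shapes stay fixed.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .volumes import Sample2D

__all__ = ["normalize_intensity", "resample_to", "augment"]


def normalize_intensity(image, mode: str = "zscore") -> np.ndarray:
    """Standardise a (C, Y, X) image per channel.

    ``zscore`` maps each channel to mean 0 / std 1; ``minmax`` maps it into
    [0, 1].  Constant channels become all zeros in either mode.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if image.ndim == 2:
        return normalize_intensity(image[None], mode)[0]
    axes = tuple(range(1, image.ndim))
    if mode == "zscore":
        mu = image.mean(axis=axes, keepdims=True)
        sd = image.std(axis=axes, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return (image - mu) / sd
    if mode == "minmax":
        lo = image.min(axis=axes, keepdims=True)
        hi = image.max(axis=axes, keepdims=True)
        rng = np.where(hi - lo == 0, 1.0, hi - lo)
        return (image - lo) / rng
    raise ValueError("mode must be 'zscore' or 'minmax'")


def _resize_image(image: np.ndarray, shape) -> np.ndarray:
    out = np.empty(image.shape[:-2] + tuple(shape))
    for idx in np.ndindex(image.shape[:-2]):
        out[idx] = _sk_resize(image[idx], shape, order=1, mode="edge",
                              preserve_range=True, anti_aliasing=False)
    return out


def _resize_mask(mask: np.ndarray, shape) -> np.ndarray:
    res = _sk_resize(mask.astype(np.float64), shape, order=0, mode="edge",
                     preserve_range=True, anti_aliasing=False)
    return np.rint(res).astype(mask.dtype)


def resample_to(image, mask, target_shape):
    """Resample a (C, Y, X) image and (Y, X) mask to ``target_shape``.

    Linear interpolation for the image, nearest-neighbour for the mask; an
    identity target returns the inputs unchanged.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if any(t <= 0 for t in target_shape):
        raise ValueError("target shape must be positive")
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask)
    if image.shape[-2:] == target_shape and mask.shape == target_shape:
        return image.copy(), mask.copy()
    return _resize_image(image, target_shape), _resize_mask(mask, target_shape)


def _center_fit(arr: np.ndarray, shape) -> np.ndarray:
    """Centre-crop or zero-pad the trailing two axes of ``arr`` to ``shape``."""
    out = arr
    for ax, target in zip((-2, -1), shape):
        cur = out.shape[ax]
        if cur > target:
            a = (cur - target) // 2
            out = np.take(out, range(a, a + target), axis=ax)
        elif cur < target:
            a = (target - cur) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (a, target - cur - a)
            out = np.pad(out, pad)
    return out


def augment(sample: Sample2D, op: str, rng: np.random.Generator | None = None,
            k: int = 1, factor: float = 1.0) -> Sample2D:
    """Apply one geometric augmentation identically to image and mask.

    ``op`` is ``hflip``, ``vflip``, ``rotate90`` (quarter turns, ``k``) or
    ``scale`` (zoom by ``factor`` about the centre, then centre-crop/pad back
    to the original shape).  Flips and right-angle rotations are exact and
    preserve foreground pixel counts.
    """
    img, msk = sample.image, sample.mask
    if op == "hflip":
        img, msk = img[..., ::-1], msk[..., ::-1]
    elif op == "vflip":
        img, msk = img[..., ::-1, :], msk[..., ::-1, :]
    elif op == "rotate90":
        img = np.rot90(img, k=k, axes=(-2, -1))
        msk = np.rot90(msk, k=k, axes=(-2, -1))
    elif op == "scale":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        h, w = msk.shape
        zh, zw = max(1, round(h * factor)), max(1, round(w * factor))
        img = _center_fit(_resize_image(img, (zh, zw)), (h, w))
        msk = _center_fit(_resize_mask(msk, (zh, zw)), (h, w))
    else:
        raise ValueError(f"unknown augmentation {op!r}")
    return Sample2D(image=np.ascontiguousarray(img),
                    mask=np.ascontiguousarray(msk),
                    volume_id=sample.volume_id,
                    slice_index=sample.slice_index,
                    spacing=sample.spacing)


def random_augment(sample: Sample2D, rng: np.random.Generator) -> Sample2D:
    """Draw one augmentation (or identity) uniformly; used by the trainer."""
    choice = rng.integers(0, 5)
    if choice == 0:
        return sample
    if choice == 1:
        return augment(sample, "hflip")
    if choice == 2:
        return augment(sample, "vflip")
    if choice == 3:
        return augment(sample, "rotate90", k=int(rng.integers(1, 4)))
    return augment(sample, "scale", factor=float(rng.uniform(0.9, 1.1)))
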