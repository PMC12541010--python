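"""Synthetic multi-modal tumor phantoms for end-to-end testing and demos.

Each phantom is one axial pseudo-MRI slice with four co-registered channels
whose contrasts loosely emulate FLAIR / T1 / T1CE / T2, and a label mask with
three nested elliptical tumor subregions written in the BraTS convention:
label 2 on the WT rim (edema), 1 on the TC rim (necrotic core) and 4 in the
ET centre (enhancing tumor).  The background is a per-channel base level plus
a smooth low-frequency bias field and additive Gaussian noise.

The default contrasts make the whole tumor approximately recoverable by
thresholding channel 0, so a small network can learn the task in minutes on
a CPU; the generator emulates region topology and modality contrast, not MRI
physics (no Rician noise, partial volume or motion).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, MultiModalVolume, Sample2D, save_volume

__all__ = ["PhantomSpec", "generate_phantom", "generate_samples",
           "generate_dataset"]

# per-channel additive offset for membership in (WT, TC, ET); offsets of the
# nested regions accumulate, e.g. an ET pixel on channel 2 reads
# base + 0.10 + 0.05 + 0.60
DEFAULT_CONTRAST = (
    (0.60, 0.00, 0.00),   # ch0, FLAIR-like: bright across the whole tumor
    (-0.15, 0.00, 0.05),  # ch1, T1-like: mildly hypointense tumor
    (0.10, 0.05, 0.60),   # ch2, T1CE-like: strong enhancing-core signal
    (0.40, 0.15, 0.00),   # ch3, T2-like: bright edema, brighter core
)
BASE_LEVEL = 0.2
BIAS_AMPLITUDE = 0.05


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator (all randomness flows from seed)."""

    n_samples: int = 100
    shape: tuple = (64, 64)
    n_channels: int = 4
    noise_sigma: float = 0.05
    bias_amplitude: float = BIAS_AMPLITUDE
    wt_radius_range: tuple = (7.0, 14.0)
    tc_fraction_range: tuple = (0.55, 0.80)
    et_fraction_range: tuple = (0.45, 0.70)
    tumor_probability: float = 1.0
    contrast_table: tuple = DEFAULT_CONTRAST
    spacing: tuple = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")
        for name in ("tc_fraction_range", "et_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if not (0 <= self.tumor_probability <= 1):
            raise ValueError("tumor_probability must be in [0, 1]")
        lo, hi = self.wt_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("wt_radius_range must be positive and ordered")
        if 2 * hi + 2 >= min(self.shape):
            raise ValueError("wt_radius_range does not fit inside shape")
        tbl = np.asarray(self.contrast_table, dtype=np.float64)
        if tbl.shape != (self.n_channels, 3):
            raise ValueError("contrast_table must be (n_channels, 3)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _ellipse_mask(shape, center, axes, theta) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2 <= 1.0


def _tumor_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape
    a = rng.uniform(*spec.wt_radius_range)
    b = rng.uniform(*spec.wt_radius_range)
    theta = rng.uniform(0, np.pi)
    margin = int(np.ceil(max(a, b))) + 1
    if 2 * margin >= min(h, w):
        raise ValueError("tumor geometry cannot fit inside the image")
    # integer centre + >=1px semi-axes guarantee all three regions nonempty
    cy = int(rng.integers(margin, h - margin))
    cx = int(rng.integers(margin, w - margin))
    wt = _ellipse_mask(spec.shape, (cy, cx), (a, b), theta)
    f_tc = rng.uniform(*spec.tc_fraction_range)
    f_et = rng.uniform(*spec.et_fraction_range)
    tc = _ellipse_mask(spec.shape, (cy, cx),
                       (max(a * f_tc, 1.0), max(b * f_tc, 1.0)), theta)
    et = _ellipse_mask(spec.shape, (cy, cx),
                       (max(a * f_tc * f_et, 1.0), max(b * f_tc * f_et, 1.0)),
                       theta)
    tc &= wt
    et &= tc
    mask = np.zeros(spec.shape, dtype=np.int16)
    mask[wt] = 2
    mask[tc] = 1
    mask[et] = 4
    return mask


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    coarse = rng.standard_normal((4, 4))
    zoom = (shape[0] / 4, shape[1] / 4)
    return amplitude * ndimage.zoom(coarse, zoom, order=3,
                                    mode="nearest", grid_mode=True)


def generate_phantom(spec: PhantomSpec,
                     rng: np.random.Generator) -> Sample2D:
    """Draw one phantom slice from the spec using the supplied generator."""
    h, w = spec.shape
    has_tumor = rng.uniform() < spec.tumor_probability
    mask = _tumor_mask(spec, rng) if has_tumor else np.zeros((h, w), np.int16)
    wt, tc, et = mask > 0, np.isin(mask, (1, 4)), mask == 4
    tbl = np.asarray(spec.contrast_table, dtype=np.float64)
    image = np.empty((spec.n_channels, h, w))
    for c in range(spec.n_channels):
        chan = np.full((h, w), BASE_LEVEL)
        if spec.bias_amplitude > 0:
            chan += _bias_field((h, w), spec.bias_amplitude, rng)
        chan += tbl[c, 0] * wt + tbl[c, 1] * tc + tbl[c, 2] * et
        if spec.noise_sigma > 0:
            chan += spec.noise_sigma * rng.standard_normal((h, w))
        image[c] = chan
    return Sample2D(image=image, mask=mask, spacing=spec.spacing)


def generate_samples(spec: PhantomSpec) -> list:
    """Generate ``spec.n_samples`` phantoms from the spec's own seed."""
    rng = spec.rng()
    out = []
    for i in range(spec.n_samples):
        s = generate_phantom(spec, rng)
        s.volume_id = f"phantom_{i:04d}"
        s.slice_index = 0
        out.append(s)
    return out


def generate_dataset(spec: PhantomSpec, out_dir) -> Path:
    """Write a phantom dataset (NIfTI + CSV index + JSON manifest) to disk.

    Each phantom is stored as a single-slice 4-channel image volume plus a
    label volume, in the same on-disk dialect the volume loader consumes.
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries, index_rows = [], []
    for s in generate_samples(spec):
        vid = s.volume_id
        img_path = out_dir / f"{vid}_image.nii.gz"
        lab_path = out_dir / f"{vid}_label.nii.gz"
        spacing3 = (1.0,) + tuple(spec.spacing)
        save_volume(MultiModalVolume(s.image[:, None], spacing=spacing3),
                    img_path)
        save_volume(LabelVolume(s.mask[None], spacing=spacing3), lab_path)
        entries.append({"id": vid, "image": img_path.name,
                        "label": lab_path.name})
        index_rows.append((vid, 0, int(np.count_nonzero(s.mask))))
    manifest = out_dir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"samples": entries, "spec": {
            "n_samples": spec.n_samples, "shape": list(spec.shape),
            "n_channels": spec.n_channels, "noise_sigma": spec.noise_sigma,
            "tumor_probability": spec.tumor_probability, "seed": spec.seed,
        }}, fh, indent=2)
    with open(out_dir / "slice_index.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["volume_id", "slice_index", "foreground_pixels"])
        writer.writerows(index_rows)
    return manifest
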