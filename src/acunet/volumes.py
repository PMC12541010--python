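"""Volume containers, NIfTI I/O, slice extraction and tumor-region derivation.

Conventions
-----------
In memory, multi-modal images are channel-first ``(C, Z, Y, X)`` float grids
and label maps are ``(Z, Y, X)`` integer grids with the BraTS label set
{0: background, 1: necrotic/non-enhancing core, 2: edema, 4: enhancing
tumor}.  Axial slices are taken along the first spatial axis (Z), giving
``(C, Y, X)`` / ``(Y, X)`` planes with the origin at the top-left.

On disk, NIfTI files follow the nibabel axis order ``(X, Y, Z[, C])``; the
transpose between the two layouts is handled here.  Voxel spacing is carried
per spatial axis in millimetres, ``(z, y, x)`` ordered in memory.

The evaluation regions are nested: whole tumor WT = {1, 2, 4}, tumor core
TC = {1, 4}, enhancing tumor ET = {4}, so ET is a subset of TC is a subset
of WT by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib

__all__ = [
    "ALLOWED_LABELS",
    "REGION_ORDER",
    "REGION_LABELS",
    "MultiModalVolume",
    "LabelVolume",
    "Sample2D",
    "RegionMasks",
    "load_volume",
    "save_volume",
    "load_manifest",
    "load_slice_dataset",
    "extract_slices",
    "derive_regions",
]

ALLOWED_LABELS = (0, 1, 2, 4)
REGION_ORDER = ("WT", "TC", "ET")
REGION_LABELS = {"WT": (1, 2, 4), "TC": (1, 4), "ET": (4,)}
DEFAULT_CHANNELS = ("FLAIR", "T1", "T1CE", "T2")


def _validate_labels(arr: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(arr), ALLOWED_LABELS)
    if bad.size:
        raise ValueError(
            f"label value {bad[0]} outside allowed set {ALLOWED_LABELS}")


@dataclass
class MultiModalVolume:
    """Channel-first (C, Z, Y, X) intensity grid with physical voxel spacing."""

    intensities: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    channel_names: tuple = ()

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must be 4-D (C, Z, Y, X)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 strictly positive values")
        if not self.channel_names:
            n = self.intensities.shape[0]
            self.channel_names = tuple(DEFAULT_CHANNELS[:n]) if n <= 4 else \
                tuple(f"ch{i}" for i in range(n))

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def spatial_shape(self) -> tuple:
        return self.intensities.shape[1:]


@dataclass
class LabelVolume:
    """(Z, Y, X) integer label grid over the BraTS label set."""

    labels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (Z, Y, X)")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise ValueError("labels must be integer-valued")
            self.labels = rounded.astype(np.int16)
        _validate_labels(self.labels)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def spatial_shape(self) -> tuple:
        return self.labels.shape


@dataclass
class Sample2D:
    """One axial slice: (C, Y, X) image plus (Y, X) label mask."""

    image: np.ndarray
    mask: np.ndarray
    volume_id: str = ""
    slice_index: int = -1
    spacing: tuple = (1.0, 1.0)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.mask.ndim != 2:
            raise ValueError("image must be (C, Y, X) and mask (Y, X)")
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image/mask spatial shapes differ: "
                f"{self.image.shape[1:]} vs {self.mask.shape}")
        _validate_labels(self.mask)


@dataclass
class RegionMasks:
    """Nested binary evaluation regions (ET within TC within WT)."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __post_init__(self):
        for name in ("wt", "tc", "et"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if ((self.et & ~self.tc).any() or (self.tc & ~self.wt).any()):
            raise ValueError("regions must nest: ET within TC within WT")

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region.lower())


def derive_regions(labels) -> RegionMasks:
    """Map a BraTS label grid to nested WT/TC/ET binary masks."""
    labels = np.asarray(labels)
    _validate_labels(labels)
    return RegionMasks(wt=np.isin(labels, REGION_LABELS["WT"]),
                       tc=np.isin(labels, REGION_LABELS["TC"]),
                       et=np.isin(labels, REGION_LABELS["ET"]))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume(vol, path) -> Path:
    """Write a volume to NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    if isinstance(vol, MultiModalVolume):
        disk = vol.intensities.transpose(3, 2, 1, 0)        # (X, Y, Z, C)
        sx, sy, sz = vol.spacing[2], vol.spacing[1], vol.spacing[0]
    elif isinstance(vol, LabelVolume):
        disk = vol.labels.astype(np.int16).transpose(2, 1, 0)
        sx, sy, sz = vol.spacing[2], vol.spacing[1], vol.spacing[0]
    else:
        raise TypeError(f"cannot save {type(vol).__name__}")
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(disk, affine)
    img.header.set_zooms((sx, sy, sz) + ((1.0,) if disk.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_volume(path, kind: str = "auto"):
    """Load a NIfTI file as a :class:`MultiModalVolume` or :class:`LabelVolume`.

    ``kind`` is ``'image'``, ``'label'`` or ``'auto'`` (4-D files become
    images, 3-D files labels).  3-D files loaded with ``kind='image'`` become
    single-channel volumes.  Label files are validated against the allowed
    label set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))  # (z, y, x)
    if kind == "auto":
        kind = "image" if data.ndim == 4 else "label"
    if kind == "image":
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(f"expected 3-D or 4-D image, got {data.ndim}-D")
        return MultiModalVolume(data.transpose(3, 2, 1, 0), spacing=spacing)
    if kind == "label":
        if data.ndim != 3:
            raise ValueError(f"expected 3-D label map, got {data.ndim}-D")
        return LabelVolume(data.transpose(2, 1, 0), spacing=spacing)
    raise ValueError("kind must be 'auto', 'image' or 'label'")


def load_manifest(manifest_path):
    """Read a dataset manifest (JSON) into (volume, label, id) triples.

    Each manifest entry has an ``id``, either a 4-channel ``image`` path or a
    list of single-modality ``modalities`` paths, and a ``label`` path.
    Paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    out = []
    for entry in manifest["samples"]:
        if "image" in entry:
            vol = load_volume(base / entry["image"], kind="image")
        else:
            parts = [load_volume(base / p, kind="image")
                     for p in entry["modalities"]]
            vol = MultiModalVolume(
                np.concatenate([p.intensities for p in parts], axis=0),
                spacing=parts[0].spacing)
        lab = load_volume(base / entry["label"], kind="label")
        if vol.spatial_shape != lab.spatial_shape:
            raise ValueError(f"{entry['id']}: image/label shape mismatch")
        out.append((vol, lab, str(entry["id"])))
    return out


def extract_slices(vol: MultiModalVolume, lab: LabelVolume,
                   keep_empty: bool = False, volume_id: str = "") -> list:
    """Decompose a volume into axial :class:`Sample2D` slices.

    With ``keep_empty=False``, slices whose label plane is all background are
    dropped.  Slices come out in ascending axial order; provenance (volume id
    and slice index) is recorded on each sample.
    """
    if vol.spatial_shape != lab.spatial_shape:
        raise ValueError(
            f"shape mismatch: {vol.spatial_shape} vs {lab.spatial_shape}")
    samples = []
    vid = volume_id
    for z in range(vol.spatial_shape[0]):
        mask = lab.labels[z]
        if not keep_empty and not mask.any():
            continue
        samples.append(Sample2D(image=vol.intensities[:, z],
                                mask=mask, volume_id=vid, slice_index=z,
                                spacing=vol.spacing[1:]))
    return samples


def load_slice_dataset(manifest_path, keep_empty: bool = True):
    """Load a manifest into stacked arrays ready for the estimator.

    Returns ``(images, masks, provenance, spacing)`` with images
    ``(n, C, H, W)``, masks ``(n, H, W)``, provenance a list of
    ``(volume_id, slice_index)`` pairs and spacing the in-plane (y, x)
    voxel size of the first volume.
    """
    triples = load_manifest(manifest_path)
    images, masks, prov = [], [], []
    spacing = (1.0, 1.0)
    for vol, lab, vid in triples:
        spacing = vol.spacing[1:]
        for s in extract_slices(vol, lab, keep_empty=keep_empty,
                                volume_id=vid):
            images.append(s.image)
            masks.append(s.mask)
            prov.append((s.volume_id, s.slice_index))
    if not images:
        raise ValueError("manifest yielded no slices")
    return np.stack(images), np.stack(masks), prov, spacing
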