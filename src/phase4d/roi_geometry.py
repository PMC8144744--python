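"""Per-phase ROI geometry: mask translation, peritumoural band, density correction.

The tumour mask (GTV) is defined once on a reference phase and translated
rigidly onto every other phase — tumour deformation over the respiratory cycle
is assumed negligible, so translation preserves voxel count exactly.  The
peritumoural band is the shell of voxels within ``inner`` mm inside or
``outer`` mm outside the GTV surface, measured with a Euclidean distance
transform on the physical voxel spacing.  High-density normal tissue
(diaphragm, chest wall, bone) intersecting the band is removed together with
connected attached voxels, followed by a one-voxel interior erosion so that
only voxels fully inside the corrected border remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

HU_MIN, HU_MAX = -1100.0, 3100.0

#: Minimum ROI size for texture analysis (voxels below which texture is
#: meaningless); ROIs smaller than this are excluded.
MIN_VOXELS = 64


@dataclass
class ImageVolume:
    """A CT volume in Hounsfield units on an anisotropic voxel grid."""

    array: np.ndarray          # HU values, 3-D
    spacing: tuple[float, float, float]  # mm per axis
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 3:
            raise ValueError("image must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        lo, hi = np.nanmin(self.array), np.nanmax(self.array)
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU range [{lo:.0f}, {hi:.0f}] outside plausible CT range")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """Boolean mask grid-congruent with its paired :class:`ImageVolume`."""

    array: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=bool)
        if self.array.ndim != 3:
            raise ValueError("mask must be 3-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.array.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing)) / 1000.0


class OutOfBoundsError(ValueError):
    """A rigid shift pushed mask voxels off the image grid."""


def translate_mask(mask: BinaryMask, t: np.ndarray) -> BinaryMask:
    """Shift a mask by a physical translation ``t`` (mm), nearest-voxel rounding.

    No interpolation: the voxel count is preserved exactly.  If any ON voxel
    would leave the grid an :class:`OutOfBoundsError` is raised.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise ValueError("translation must be a finite 3-vector in mm")
    shift = np.round(t / np.asarray(mask.spacing)).astype(int)
    idx = np.argwhere(mask.array)
    if idx.size == 0:
        return BinaryMask(np.zeros_like(mask.array), mask.spacing)
    new = idx + shift
    if (new < 0).any() or (new >= np.array(mask.array.shape)).any():
        raise OutOfBoundsError(f"shift {shift.tolist()} moves mask off-grid")
    out = np.zeros_like(mask.array)
    out[tuple(new.T)] = True
    return BinaryMask(out, mask.spacing)


def motion_amplitude(translations: np.ndarray) -> float:
    """Tumour motion amplitude in mm from per-phase translations.

    The per-axis peak-to-peak ranges are combined as a vector:
    ``||(max-min)_x, (max-min)_y, (max-min)_z||_2``.
    """
    t = np.asarray(translations, dtype=float)
    if t.ndim != 2 or t.shape[1] != 3 or t.shape[0] < 2:
        raise ValueError("need >= 2 phases of 3-vector translations")
    span = t.max(axis=0) - t.min(axis=0)
    return float(np.linalg.norm(span))


def peritumour_band(gtv: BinaryMask, inner: float = 3.0,
                    outer: float = 3.0) -> BinaryMask:
    """Shell of voxels within ``inner`` mm inside or ``outer`` mm outside the GTV.

    Distances are centre-to-centre Euclidean distances on the physical spacing,
    computed with a distance transform of the mask and of its complement.
    """
    if gtv.n_voxels == 0:
        raise ValueError("empty GTV mask")
    sampling = gtv.spacing
    # distance from each outside voxel to the nearest GTV voxel
    d_out = ndimage.distance_transform_edt(~gtv.array, sampling=sampling)
    # distance from each inside voxel to the nearest non-GTV voxel
    d_in = ndimage.distance_transform_edt(gtv.array, sampling=sampling)
    band = (~gtv.array & (d_out <= outer)) | (gtv.array & (d_in <= inner))
    if not band.any():
        raise ValueError("peritumoural band is empty (sub-voxel structure)")
    return BinaryMask(band, gtv.spacing)


def correct_high_density(band: BinaryMask, gtv: BinaryMask, image: ImageVolume,
                         hu_threshold: float = 0.0,
                         erode: bool = True) -> BinaryMask:
    """Remove high-density normal tissue from the peritumoural band.

    Band voxels outside the GTV with HU above ``hu_threshold`` are removed
    together with band voxels 26-connected to the offending high-density
    structures.  The surviving band is then eroded by one voxel (face
    connectivity) against removed and exterior voxels, keeping only voxels
    fully inside the corrected border.  Returns a subset of ``band``; an empty
    result is returned as-is for the caller to flag the patient.
    """
    if band.array.shape != gtv.array.shape or band.array.shape != image.array.shape:
        raise ValueError("band, GTV and image must share one grid")
    dense = (image.array > hu_threshold) & ~gtv.array
    struct26 = np.ones((3, 3, 3), dtype=bool)
    # high-density structures plus their 26-neighbourhood, clipped to the band
    attached = ndimage.binary_dilation(dense, structure=struct26)
    removed = band.array & ~gtv.array & attached
    surviving = band.array & ~removed
    if erode:
        blocked = removed | ~band.array
        struct6 = ndimage.generate_binary_structure(3, 1)
        near_blocked = ndimage.binary_dilation(blocked, structure=struct6)
        surviving = surviving & ~near_blocked
    return BinaryMask(surviving, band.spacing)


def min_volume_check(mask: BinaryMask, min_voxels: int = MIN_VOXELS) -> bool:
    """True iff the mask holds at least ``min_voxels`` voxels (inclusive bound)."""
    return mask.n_voxels >= min_voxels


def load_nifti(path) -> ImageVolume:
    import nibabel as nib
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asanyarray(img.dataobj, dtype=float), spacing)


def load_nifti_mask(path) -> BinaryMask:
    import nibabel as nib
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return BinaryMask(np.asanyarray(img.dataobj) > 0.5, spacing)
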