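"""Per-phase, per-ROI radiomic feature extraction with a fixed configuration.

Configuration follows the study defaults: fixed bin width of 25 HU anchored at
the per-ROI minimum (no re-segmentation window — air is potentially
informative), features from the original image and a Laplacian-of-Gaussian
filtered image at sigma = 1.5 mm, no resampling, and six feature classes
(first order, GLCM, GLSZM, GLRLM, NGTDM, GLDM) giving 93 features per image
type per ROI — 372 per phase over two image types and two ROIs.  Shape
features are never extracted.

This module owns configuration, feature naming, phase/ROI looping and failure
accounting; the feature mathematics live in :mod:`phase4d.radiomics_features`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import radiomics_features as rf
from .core_data import PhaseFeatureTable, DEFAULT_PHASES
from .roi_geometry import BinaryMask, ImageVolume, min_volume_check

logger = logging.getLogger("phase4d")

#: Version of the feature definitions; recorded in output metadata because
#: feature counts and values are definition-dependent.
ENGINE_VERSION = "phase4d-features-1.0"


@dataclass
class ExtractionConfig:
    bin_width: float = 25.0           # HU
    log_sigma: float = 1.5            # mm
    image_types: tuple[str, ...] = ("original", "log-sigma-1.5")
    feature_classes: tuple[str, ...] = rf.FEATURE_CLASSES
    min_voxels: int = 64

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")

    def metadata(self) -> dict:
        return {"engine_version": ENGINE_VERSION,
                "bin_width": self.bin_width, "log_sigma": self.log_sigma,
                "image_types": list(self.image_types),
                "resampling": "none"}


class ROIVolumeError(ValueError):
    """ROI below the minimum voxel count for texture analysis."""


def _log_filter(image: ImageVolume, sigma_mm: float) -> np.ndarray:
    """Laplacian-of-Gaussian response with a physical (mm) scale per axis."""
    sigma_vox = [sigma_mm / s for s in image.spacing]
    return ndimage.gaussian_laplace(image.array, sigma=sigma_vox)


def extract_roi_features(image: ImageVolume, mask: BinaryMask,
                         config: ExtractionConfig | None = None,
                         roi: str = "tumour") -> dict[str, float]:
    """Feature vector for one ROI on one phase.

    Keys are ``roi|image_type|class_Name`` triplet names, stable across runs.
    Discretisation is anchored at the ROI minimum of each image type.
    """
    config = config or ExtractionConfig()
    if image.array.shape != mask.array.shape:
        raise ValueError("image and mask grids differ")
    if not min_volume_check(mask, config.min_voxels):
        raise ROIVolumeError(
            f"ROI has {mask.n_voxels} voxels, below {config.min_voxels}")
    out: dict[str, float] = {}
    for image_type in config.image_types:
        if image_type == "original":
            arr = image.array
        elif image_type.startswith("log-sigma"):
            arr = _log_filter(image, config.log_sigma)
        else:
            raise ValueError(f"unknown image type {image_type!r}")
        feats = rf.all_features(arr, mask.array, image.spacing,
                                bin_width=config.bin_width)
        for name, v in feats.items():
            if not np.isfinite(v):
                logger.warning("non-finite value for %s|%s|%s", roi, image_type, name)
            out[f"{roi}|{image_type}|{name}"] = v
    return out


def extract_cohort(images: dict, masks: dict,
                   config: ExtractionConfig | None = None,
                   phases: tuple[str, ...] = DEFAULT_PHASES) -> PhaseFeatureTable:
    """Extract a complete phase-feature table for a cohort.

    Parameters
    ----------
    images:
        ``images[patient][phase]`` -> :class:`ImageVolume`.
    masks:
        ``masks[patient][phase][roi]`` -> :class:`BinaryMask` for
        roi in {"tumour", "peritumour"}.

    Patients with any phase missing are skipped with a logged reason.
    """
    config = config or ExtractionConfig()
    rows = []
    for patient in sorted(images):
        if set(phases) - set(images[patient]):
            missing = sorted(set(phases) - set(images[patient]))
            logger.warning("patient %s skipped: missing phases %s", patient, missing)
            continue
        for phase in phases:
            image = images[patient][phase]
            for roi, mask in masks[patient][phase].items():
                vec = extract_roi_features(image, mask, config, roi=roi)
                for name, value in vec.items():
                    rows.append((patient, phase, roi, name, value))
        logger.info("extracted patient %s", patient)
    df = pd.DataFrame(rows, columns=["patient", "phase", "roi", "feature", "value"])
    # feature names already carry the ROI prefix; keep roi column consistent
    return PhaseFeatureTable(df, phases=phases)
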