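"""Preprocessing: FLAIR intensity normalization, smoothing, brain masks.

The statistical pipeline expects spatially normalized volumes.  What remains
here is the arithmetic that precedes the permutation tests: scaling FLAIR so
the robust mean of cerebellar white matter equals a fixed reference (FLAIR
is not quantitative, so a reference-region rescaling makes subjects
comparable), Gaussian smoothing, tissue-based brain-mask construction, and
the sign flip that orients every modality so an abnormality is a decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, VolumeGrid

__all__ = [
    "AnalysisParams",
    "gaussian_smooth",
    "robust_mean",
    "normalize_flair_intensity",
    "make_subject_brain_mask",
    "make_group_brain_mask",
    "orient_for_decrease_test",
    "apply_mask",
]

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AnalysisParams:
    """Shared analysis constants.

    Defaults follow the standard voxel-based protocol: 8 mm FWHM smoothing,
    robust mean over the 5th-95th percentile window, FLAIR reference
    intensity 1000, tissue threshold 0.5 on GMC+WMC, majority-vote group
    mask, alpha 0.05.  FLAIR and MD are sign-flipped so that all four NPC
    modalities are tested for decreases.
    """

    fwhm_mm: float = 8.0
    percentile_window: tuple[float, float] = (5.0, 95.0)
    flair_target: float = 1000.0
    tissue_threshold: float = 0.5
    group_mask_threshold: float = 0.5
    alpha: float = 0.05
    npc_modalities: tuple[str, ...] = ("FLAIR", "FA", "MD", "NDI")
    flip_modalities: frozenset = frozenset({"FLAIR", "MD"})

    def __post_init__(self) -> None:
        lo, hi = self.percentile_window
        if not (0 <= lo < hi <= 100):
            raise ValueError(f"bad percentile window ({lo}, {hi})")
        if self.flair_target <= 0:
            raise ValueError("flair_target must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if "GMC" in self.npc_modalities:
            raise ValueError(
                "GMC has no consistent direction of change and is excluded "
                "from the multimodal (NPC) analysis")


def gaussian_smooth(vol: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Separable Gaussian smoothing with kernel width given as FWHM in mm.

    sigma per axis (in voxels) is ``fwhm_mm / (voxel_size * 2*sqrt(2*ln 2))``;
    ``fwhm_mm = 0`` is the identity.  Boundaries use constant-zero padding.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy()
    sigma = tuple(fwhm_mm * _SIGMA_PER_FWHM / v for v in vol.voxel_size_mm)
    out = ndimage.gaussian_filter(vol.data, sigma, mode="constant", cval=0.0)
    return vol.with_data(out)


def robust_mean(values: np.ndarray,
                window: tuple[float, float] = (5.0, 95.0)) -> float:
    """Mean of the values between two percentiles, inclusive at both ends.

    Percentiles are computed with linear interpolation.  If trimming leaves
    nothing (possible only with pathological windows), the plain mean is
    returned with a warning.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("robust_mean of an empty sample")
    lo, hi = np.percentile(values, window)
    kept = values[(values >= lo) & (values <= hi)]
    if kept.size == 0:  # degenerate window
        warnings.warn("percentile window retained no values; using plain mean",
                      stacklevel=2)
        return float(values.mean())
    return float(kept.mean())


def normalize_flair_intensity(
    flair: VolumeGrid,
    cerebellar_wm: BinaryMask,
    target: float = 1000.0,
    window: tuple[float, float] = (5.0, 95.0),
) -> VolumeGrid:
    """Scale FLAIR so the robust mean inside cerebellar WM equals ``target``.

    The cerebellum serves as reference region because it is rarely involved
    in focal pathology.  The operation is idempotent and invariant to any
    positive rescaling of the input.
    """
    if flair.shape != cerebellar_wm.shape:
        raise ValueError("FLAIR and cerebellar WM mask shapes differ")
    if not cerebellar_wm.data.any():
        raise ValueError("cerebellar WM mask is empty")
    ref = robust_mean(flair.data[cerebellar_wm.data], window)
    if ref <= 0:
        raise ValueError(
            f"nonpositive cerebellar WM robust mean ({ref:g}); input corrupt?")
    return flair.with_data(flair.data * (target / ref))


def make_subject_brain_mask(
    gmc: VolumeGrid, wmc: VolumeGrid, threshold: float = 0.5
) -> BinaryMask:
    """Brain mask from tissue concentrations: keep voxels with GMC+WMC >= threshold."""
    if gmc.shape != wmc.shape:
        raise ValueError("GMC and WMC shapes differ")
    return BinaryMask(gmc.data + wmc.data >= threshold)


def make_group_brain_mask(
    subject_masks: list[BinaryMask], group_threshold: float = 0.5
) -> BinaryMask:
    """Average subject masks and binarize at ``group_threshold`` (mean >= threshold)."""
    if not subject_masks:
        raise ValueError("no subject masks given")
    shape = subject_masks[0].shape
    for m in subject_masks:
        if m.shape != shape:
            raise ValueError("subject masks have differing shapes")
    mean = np.mean([m.data for m in subject_masks], axis=0)
    return BinaryMask(mean >= group_threshold)


def orient_for_decrease_test(
    vol: VolumeGrid, modality: str, flip_modalities=frozenset({"FLAIR", "MD"})
) -> VolumeGrid:
    """Negate modalities whose abnormalities are increases.

    After this step an abnormality is a decrease in every NPC modality, so a
    single one-tailed decrease test covers the concordant direction.
    """
    if modality in flip_modalities:
        return vol.with_data(-vol.data)
    return vol.copy()


def apply_mask(vol: VolumeGrid, mask: BinaryMask) -> VolumeGrid:
    """Zero voxels outside the mask; NaN inside the mask is an error."""
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    inside = vol.data[mask.data]
    if np.isnan(inside).any():
        raise ValueError("NaN voxels inside the brain mask")
    out = np.where(mask.data, vol.data, 0.0)
    return vol.with_data(out)
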