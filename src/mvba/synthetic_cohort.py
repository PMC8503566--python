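"""Synthetic multimodal cohorts with planted lesions.

Generates fully synthetic, already-normalized control cohorts plus one
patient on a common grid, so the whole statistical pipeline can be exercised
without real MRI.  Each volume is a stationary Gaussian random field
(Gaussian-smoothed white noise, restandardized to a target voxel-wise
standard deviation) around a modality-specific baseline.  Lesions are
spheres that raise FLAIR/MD, lower FA/NDI and may shift GMC in either
direction, mirroring the direction conventions of the analysis.

Under the null (no lesion) the patient is drawn from the same distribution
as the controls, which is exactly the exchangeability assumption the
permutation test relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import (
    BinaryMask,
    CohortManifest,
    SubjectEntry,
    VolumeGrid,
    save_manifest,
    save_mask,
    save_volume,
)

__all__ = [
    "MODALITIES",
    "NPC_MODALITIES",
    "SIGN_MAP",
    "SyntheticConfig",
    "LesionSpec",
    "CohortDataset",
    "generate_control_volume",
    "plant_lesion",
    "generate_cohort",
    "make_seeg_sphere_mask",
    "write_cohort",
]

#: Canonical modality order.
MODALITIES = ("FLAIR", "FA", "MD", "NDI", "GMC", "WMC")

#: Modalities entering the multimodal (NPC) analysis; GMC is excluded because
#: its direction of change is inconsistent across lesions, WMC is used only
#: for brain-mask construction.
NPC_MODALITIES = ("FLAIR", "FA", "MD", "NDI")

#: Required sign of a lesion effect per modality; 0 means either direction.
SIGN_MAP = {"FLAIR": +1, "MD": +1, "FA": -1, "NDI": -1, "GMC": 0, "WMC": 0}

_UNIT_MODALITIES = frozenset({"FA", "NDI", "GMC", "WMC"})

# Baselines / noise levels chosen as plausible values for normalized data:
# FLAIR in arbitrary units near the cerebellar-WM reference scale, FA/NDI
# mid-range fractions, MD in mm^2/s of healthy tissue, tissue concentrations
# summing to 0.8 so the 0.5 brain-mask rule keeps the synthetic head.
_DEFAULT_BASELINE = {
    "FLAIR": 250.0, "FA": 0.45, "MD": 8.0e-4, "NDI": 0.55,
    "GMC": 0.45, "WMC": 0.35,
}
_DEFAULT_NOISE_SD = {
    "FLAIR": 25.0, "FA": 0.04, "MD": 8.0e-5, "NDI": 0.05,
    "GMC": 0.04, "WMC": 0.04,
}

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_controls: int = 20
    modalities: tuple[str, ...] = MODALITIES
    baseline_mean: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINE))
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    noise_smoothness_fwhm_mm: float = 6.0
    #: axis-aligned box (start, stop) voxel slices per axis for cerebellar WM
    cerebellar_region: tuple[tuple[int, int], ...] = ((10, 18), (10, 18), (2, 10))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("n_controls must be >= 2")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        for m in self.modalities:
            if self.noise_sd[m] < 0:
                raise ValueError(f"noise_sd[{m}] must be >= 0")
            if m in _UNIT_MODALITIES and not 0 <= self.baseline_mean[m] <= 1:
                raise ValueError(f"baseline of unit-range modality {m} not in [0,1]")
        for (lo, hi), n in zip(self.cerebellar_region, self.shape):
            if not (0 <= lo < hi <= n):
                raise ValueError("cerebellar_region box empty or outside grid")

    def cerebellar_mask(self) -> BinaryMask:
        data = np.zeros(self.shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.cerebellar_region
        data[x0:x1, y0:y1, z0:z1] = True
        return BinaryMask(data)


@dataclass
class LesionSpec:
    """Spherical lesion definition.

    ``effect_size`` maps modality name to a signed effect in multiples of
    that modality's noise SD.  Signs must respect the pathology conventions
    (FLAIR/MD increase, FA/NDI decrease; GMC/WMC free).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    effect_size: dict[str, float]

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        for modality, eff in self.effect_size.items():
            _check_sign(modality, eff)


def _check_sign(modality: str, effect: float) -> None:
    sign = SIGN_MAP.get(modality)
    if sign is None:
        raise ValueError(f"unknown modality {modality!r}")
    if sign != 0 and effect != 0 and np.sign(effect) != sign:
        direction = "increase" if sign > 0 else "decrease"
        raise ValueError(
            f"lesions must {direction} {modality}; got effect {effect:+g}"
        )


@dataclass
class CohortDataset:
    """Controls x modalities stacks, one patient, and study masks."""

    controls: dict[str, np.ndarray]  # modality -> (n_subjects, nx, ny, nz)
    patient: dict[str, np.ndarray]   # modality -> (nx, ny, nz)
    voxel_size_mm: tuple[float, float, float]
    cerebellar_wm_mask: BinaryMask
    truth_mask: BinaryMask | None = None
    brain_mask: BinaryMask | None = None  # filled in by preprocessing

    @property
    def n_controls(self) -> int:
        return next(iter(self.controls.values())).shape[0]

    @property
    def modalities(self) -> tuple[str, ...]:
        return tuple(self.controls)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.controls.values())).shape[1:]


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------

def _smooth_sigma_vox(fwhm_mm: float, voxel_size_mm) -> tuple[float, ...]:
    return tuple(fwhm_mm * _SIGMA_PER_FWHM / v for v in voxel_size_mm)


def generate_control_volume(
    config: SyntheticConfig, modality: str, subject_index: int
) -> VolumeGrid:
    """One synthetic normalized volume for a given subject and modality.

    The field is white Gaussian noise smoothed to
    ``noise_smoothness_fwhm_mm``, restandardized so its sample SD equals
    ``noise_sd[modality]`` exactly, then shifted to the modality baseline.
    Unit-range modalities are clipped to [0, 1].  The result is a pure
    function of ``(config.seed, subject_index, modality)``.
    """
    if modality not in config.modalities:
        raise ValueError(f"modality {modality!r} not listed in config")
    mod_index = MODALITIES.index(modality)
    rng = np.random.default_rng([config.seed, subject_index, mod_index])
    field_ = rng.standard_normal(config.shape)
    if config.noise_smoothness_fwhm_mm > 0:
        field_ = ndimage.gaussian_filter(
            field_, _smooth_sigma_vox(config.noise_smoothness_fwhm_mm,
                                      config.voxel_size_mm))
    sd = config.noise_sd[modality]
    if sd > 0:
        field_ = (field_ - field_.mean()) / field_.std() * sd
    else:
        field_ = np.zeros(config.shape)
    data = config.baseline_mean[modality] + field_
    if modality in _UNIT_MODALITIES:
        data = np.clip(data, 0.0, 1.0)
    return VolumeGrid(data, config.voxel_size_mm)


def make_seeg_sphere_mask(
    contacts: list[tuple[float, float, float]],
    radius_mm: float,
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
) -> BinaryMask:
    """Union of spheres around electrode-contact coordinates.

    A voxel is included iff its physical center (voxel index times voxel
    size, measured from the grid origin corner) lies within ``radius_mm``
    (Euclidean, inclusive) of any contact.  Contacts outside the grid emit a
    warning and contribute only their in-grid portion.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    mask = np.zeros(shape, dtype=bool)
    vs = np.asarray(voxel_size_mm, dtype=float)
    extent = (np.asarray(shape) - 1) * vs
    for contact in contacts:
        c = np.asarray(contact, dtype=float)
        if np.any(c < 0) or np.any(c > extent):
            warnings.warn(
                f"contact {tuple(c)} lies outside the grid; "
                "only its in-grid portion is masked", stacklevel=2)
        # bounding box of candidate voxel indices
        lo = np.maximum(np.floor((c - radius_mm) / vs).astype(int), 0)
        hi = np.minimum(np.ceil((c + radius_mm) / vs).astype(int) + 1,
                        np.asarray(shape))
        if np.any(lo >= hi):
            continue
        idx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)),
                          indexing="ij")
        coords = np.stack([i * v for i, v in zip(idx, vs)], axis=-1)
        dist2 = np.sum((coords - c) ** 2, axis=-1)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= dist2 <= radius_mm ** 2 + 1e-12
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return BinaryMask(mask)


def plant_lesion(
    vol: VolumeGrid, spec: LesionSpec, modality: str, noise_sd: float
) -> tuple[VolumeGrid, BinaryMask]:
    """Add a spherical lesion effect to one volume.

    Inside the sphere the signed effect ``spec.effect_size[modality] *
    noise_sd`` is added; voxels outside are untouched.  Unit-range
    modalities are re-clipped to [0, 1] afterwards.  Returns the modified
    volume and the sphere voxel mask.
    """
    _check_sign(modality, spec.effect_size.get(modality, 0.0))
    mask = make_seeg_sphere_mask([spec.center_mm], spec.radius_mm,
                                 vol.shape, vol.voxel_size_mm)
    if not mask.data.any():
        raise ValueError("lesion sphere does not intersect the grid")
    effect = spec.effect_size.get(modality, 0.0) * noise_sd
    data = vol.data.copy()
    data[mask.data] += effect
    if modality in _UNIT_MODALITIES:
        data = np.clip(data, 0.0, 1.0)
    return vol.with_data(data), mask


def generate_cohort(
    config: SyntheticConfig, lesion: LesionSpec | None = None
) -> CohortDataset:
    """Full synthetic cohort: ``n_controls`` healthy subjects plus one patient.

    With ``lesion=None`` the patient is drawn from the control distribution
    (global null); otherwise the lesion is planted in the patient's volumes
    and the sphere becomes the ground-truth mask.  Deterministic given
    ``(config, lesion)`` including the seed.
    """
    controls: dict[str, np.ndarray] = {}
    patient: dict[str, np.ndarray] = {}
    truth: BinaryMask | None = None
    patient_index = config.n_controls  # subject indices: 0..n-1 controls
    for modality in config.modalities:
        controls[modality] = np.stack([
            generate_control_volume(config, modality, i).data
            for i in range(config.n_controls)
        ])
        pvol = generate_control_volume(config, modality, patient_index)
        if lesion is not None:
            pvol, sphere = plant_lesion(pvol, lesion, modality,
                                        config.noise_sd[modality])
            truth = sphere
        patient[modality] = pvol.data
    return CohortDataset(
        controls=controls, patient=patient,
        voxel_size_mm=config.voxel_size_mm,
        cerebellar_wm_mask=config.cerebellar_mask(),
        truth_mask=truth,
    )


# ---------------------------------------------------------------------------
# Disk export (fixture generator)
# ---------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, outdir: str | Path) -> Path:
    """Write a cohort as NIfTI volumes plus a YAML manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    subjects: list[SubjectEntry] = []
    vs = dataset.voxel_size_mm
    for i in range(dataset.n_controls):
        files = {}
        for modality in dataset.modalities:
            name = f"control{i:03d}_{modality}.nii.gz"
            save_volume(VolumeGrid(dataset.controls[modality][i], vs),
                        outdir / name)
            files[modality] = name
        subjects.append(SubjectEntry(f"control{i:03d}", "control", files))
    files = {}
    for modality in dataset.modalities:
        name = f"patient_{modality}.nii.gz"
        save_volume(VolumeGrid(dataset.patient[modality], vs), outdir / name)
        files[modality] = name
    subjects.append(SubjectEntry("patient", "patient", files))
    save_mask(dataset.cerebellar_wm_mask, vs, outdir / "cerebellar_wm_mask.nii.gz")
    if dataset.truth_mask is not None:
        save_mask(dataset.truth_mask, vs, outdir / "truth_mask.nii.gz")
    manifest = CohortManifest(subjects=subjects,
                              modalities=list(dataset.modalities))
    path = outdir / "manifest.yaml"
    save_manifest(manifest, path)
    return path
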