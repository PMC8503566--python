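"""NIfTI volume and cohort I/O.

All volumes in a study are assumed to live on one common, already
co-registered grid: headers are carried through unchanged but never used to
resample.  The in-memory unit of computation is :class:`VolumeGrid`, a plain
3-D scalar field with a physical voxel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "CohortManifest",
    "SubjectEntry",
    "CohortStacks",
    "load_volume",
    "save_volume",
    "load_manifest",
    "save_manifest",
    "load_cohort",
]


class VolumeIOError(RuntimeError):
    """Raised for unreadable, malformed or inconsistent volume files."""


@dataclass
class VolumeGrid:
    """One 3-D scalar field on a common grid.

    Parameters
    ----------
    data:
        3-D float array; units are modality specific (FLAIR arbitrary
        intensity, FA/NDI/GMC/WMC dimensionless in [0, 1], MD in mm^2/s).
    voxel_size_mm:
        Physical edge lengths of one voxel, millimetres.
    affine:
        Optional 4x4 voxel-to-world matrix, carried through unchanged.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeIOError(
                f"VolumeGrid requires 3-D data, got {self.data.ndim}-D"
            )
        if min(self.data.shape) < 1:
            raise VolumeIOError(f"empty volume shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise VolumeIOError(f"voxel_size_mm must be 3 positive values, got {vs}")
        self.voxel_size_mm = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size_mm,
                          None if self.affine is None else self.affine.copy())

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """New grid with the same geometry but different voxel values."""
        return VolumeGrid(data, self.voxel_size_mm,
                          None if self.affine is None else self.affine.copy())


@dataclass
class BinaryMask:
    """3-D boolean mask on the cohort grid."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeIOError(f"BinaryMask requires 3-D data, got {arr.ndim}-D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise VolumeIOError("mask values must be in {0, 1}")
        self.data = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class SubjectEntry:
    subject_id: str
    role: str  # "control" | "patient"
    files: dict[str, str]  # modality -> path


@dataclass
class CohortManifest:
    """Listing of subjects, roles and per-modality file paths."""

    subjects: list[SubjectEntry]
    modalities: list[str]

    def __post_init__(self) -> None:
        roles = {s.role for s in self.subjects}
        bad = roles - {"control", "patient"}
        if bad:
            raise VolumeIOError(f"unknown subject roles {sorted(bad)}")
        n_controls = sum(1 for s in self.subjects if s.role == "control")
        if n_controls < 2:
            raise VolumeIOError(
                f"at least 2 control subjects are required, got {n_controls}"
            )

    @property
    def controls(self) -> list[SubjectEntry]:
        return [s for s in self.subjects if s.role == "control"]

    @property
    def patients(self) -> list[SubjectEntry]:
        return [s for s in self.subjects if s.role == "patient"]


@dataclass
class CohortStacks:
    """In-memory cohort: control stacks and one patient, per modality.

    ``controls[modality]`` has shape (n_subjects, nx, ny, nz) with row order
    matching the manifest's control order.  ``patient[modality]`` is the
    patient's 3-D volume (present only if the manifest lists a patient).
    """

    controls: dict[str, np.ndarray]
    patient: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    control_ids: list[str] = field(default_factory=list)
    patient_id: str | None = None


# ---------------------------------------------------------------------------
# Volume round trip
# ---------------------------------------------------------------------------

def load_volume(path: str | Path) -> VolumeGrid:
    """Read one NIfTI volume (.nii or .nii.gz) into a :class:`VolumeGrid`.

    No resampling is performed; voxel size is taken from the header zooms.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"volume file does not exist: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error detail varies
        raise VolumeIOError(f"unreadable NIfTI header in {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(
            f"{path} contains {data.ndim}-D data; expected a 3-D scalar volume"
        )
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(np.asarray(data, dtype=np.float64), tuple(zooms),
                      affine=np.asarray(img.affine))


def save_volume(vol: VolumeGrid, path: str | Path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI; inverse of :func:`load_volume`."""
    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"directory does not exist: {path.parent}")
    if vol.affine is not None:
        affine = vol.affine
    else:
        affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, voxel_size_mm, path: str | Path) -> None:
    """Write a binary mask as a {0,1}-valued NIfTI volume."""
    save_volume(VolumeGrid(mask.data.astype(np.float64), voxel_size_mm), path)


def load_mask(path: str | Path) -> BinaryMask:
    vol = load_volume(path)
    return BinaryMask(vol.data > 0.5)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> CohortManifest:
    """Read a YAML or JSON cohort manifest.

    Expected keys: ``modalities`` (list) and ``subjects`` (list of
    ``{id, role, files: {modality: path}}``).  Relative file paths are
    resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"manifest does not exist: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    base = path.parent
    subjects = []
    for entry in doc["subjects"]:
        files = {m: str((base / p)) if not Path(p).is_absolute() else p
                 for m, p in entry["files"].items()}
        subjects.append(SubjectEntry(str(entry["id"]), entry["role"], files))
    return CohortManifest(subjects=subjects, modalities=list(doc["modalities"]))


def save_manifest(manifest: CohortManifest, path: str | Path) -> None:
    doc = {
        "modalities": list(manifest.modalities),
        "subjects": [
            {"id": s.subject_id, "role": s.role, "files": dict(s.files)}
            for s in manifest.subjects
        ],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def load_cohort(manifest: CohortManifest) -> CohortStacks:
    """Assemble per-modality control stacks (and the patient) from disk.

    Subject order is preserved exactly as listed in the manifest.  All
    volumes must share one shape; a mismatch names the offending subject
    and modality.
    """
    ref_shape: tuple[int, ...] | None = None
    ref_vs: tuple[float, float, float] | None = None

    def _load(subject: SubjectEntry, modality: str) -> np.ndarray:
        nonlocal ref_shape, ref_vs
        if modality not in subject.files:
            raise VolumeIOError(
                f"subject {subject.subject_id!r} is missing modality {modality!r}"
            )
        vol = load_volume(subject.files[modality])
        if ref_shape is None:
            ref_shape, ref_vs = vol.shape, vol.voxel_size_mm
        elif vol.shape != ref_shape:
            raise VolumeIOError(
                f"shape mismatch for subject {subject.subject_id!r} modality "
                f"{modality!r}: {vol.shape} != {ref_shape}"
            )
        return vol.data

    controls: dict[str, np.ndarray] = {}
    ctl = manifest.controls
    for modality in manifest.modalities:
        controls[modality] = np.stack([_load(s, modality) for s in ctl])

    patient: dict[str, np.ndarray] = {}
    patient_id = None
    pats = manifest.patients
    if len(pats) > 1:
        raise VolumeIOError("manifest lists more than one patient")
    if pats:
        patient_id = pats[0].subject_id
        for modality in manifest.modalities:
            patient[modality] = _load(pats[0], modality)

    assert ref_vs is not None
    return CohortStacks(controls=controls, patient=patient,
                        voxel_size_mm=ref_vs,
                        control_ids=[s.subject_id for s in ctl],
                        patient_id=patient_id)
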