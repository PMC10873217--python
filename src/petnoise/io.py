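"""Volume input/output and SUV conversion.

Reads PET volumes from NIfTI files or DICOM series directories, converts
activity concentration to body-weight SUV, and writes derived products
(masks, noise maps, machine-readable reports).

Conventions
-----------
* ``SuvVolume.voxels`` is indexed ``[slice, row, col]`` = ``[z, y, x]``; each
  2-D slice ``voxels[k]`` is one transversal (axial) plane.
* ``spacing`` is ``(dx, dy, dz)`` in mm, strictly positive.
* World coordinates are mm at voxel centers: ``x = origin[0] + ix * dx`` etc.

DICOM support requires the optional ``pydicom`` dependency
(``pip install petnoise[dicom]``).
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import nibabel as nib

from .errors import (
    AmbiguousInputError,
    InconsistentGeometryError,
    IOErrorPetNoise,
    MetadataError,
)

#: Physical half-life of fluorine-18 in minutes (standard value).
F18_HALF_LIFE_MIN = 109.77

_SLICE_SPACING_RTOL = 1e-3


@dataclass
class PatientMeta:
    """Acquisition metadata attached to a volume.

    ``weight_kg``, ``injected_activity_MBq`` and ``uptake_time_min`` are only
    validated when an SUV conversion is requested; label fields are free text.
    """

    weight_kg: float | None = None
    injected_activity_MBq: float | None = None
    uptake_time_min: float | None = None
    bed_time_s: float | None = None
    recon_label: str = ""
    study_id: str = ""


@dataclass
class SuvVolume:
    """A 3-D scalar grid in SUV units with geometry and patient metadata."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: PatientMeta = field(default_factory=PatientMeta)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D array [slice, row, col]")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must all be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along ``axis`` (0=x, 1=y, 2=z)."""
        n = self.voxels.shape[2 - axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


def suv_bw(
    concentration_kBq_per_ml: float | np.ndarray,
    weight_kg: float,
    injected_activity_MBq: float,
    uptake_time_min: float = 0.0,
) -> float | np.ndarray:
    """Convert activity concentration to body-weight SUV.

    SUV = concentration / (decayed activity per unit body mass), with the
    decayed activity equal to ``injected_activity * 2**(-t / T_half)`` for
    F-18 (T_half = 109.77 min) and a tissue density of 1 g/ml assumed, so a
    concentration numerically equal to decayed-dose-per-gram yields SUV 1.
    """
    if weight_kg <= 0 or injected_activity_MBq <= 0:
        raise MetadataError("invalid metadata: weight and activity must be positive")
    if uptake_time_min < 0:
        raise MetadataError("invalid metadata: uptake time must be non-negative")
    decayed_kBq = injected_activity_MBq * 1000.0 * 2.0 ** (-uptake_time_min / F18_HALF_LIFE_MIN)
    weight_g = weight_kg * 1000.0
    return np.multiply(concentration_kBq_per_ml, weight_g / decayed_kBq)


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def _read_nifti(path: Path) -> SuvVolume:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise AmbiguousInputError(f"ambiguous input: expected a 3-D volume, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    # nibabel stores (x, y, z); transpose so the slice axis comes first.
    return SuvVolume(
        voxels=np.ascontiguousarray(arr.T, dtype=np.float64),
        spacing=(float(zooms[0]), float(zooms[1]), float(zooms[2])),
        origin=origin,
    )


def write_volume(volume: SuvVolume, path: str | os.PathLike) -> Path:
    """Write a volume (or mask / noise map) as NIfTI.

    The affine is a scaled identity built from spacing and origin; voxel data
    are stored as float64 so a read→write→read round trip is bit-exact.
    """
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.ascontiguousarray(volume.voxels.T), affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise IOErrorPetNoise(f"io error: cannot write {path}") from exc
    return path


# ---------------------------------------------------------------------------
# DICOM (optional dependency)
# ---------------------------------------------------------------------------


def _require_pydicom():
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "DICOM support requires the optional 'pydicom' package "
            "(pip install petnoise[dicom])"
        ) from exc
    return pydicom


def _read_dicom_series(path: Path) -> SuvVolume:
    pydicom = _require_pydicom()
    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise AmbiguousInputError(f"ambiguous input: no DICOM images found in {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise AmbiguousInputError("ambiguous input: multiple DICOM series in directory")

    ref = datasets[0]
    orient = np.array(getattr(ref, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    normal = np.cross(orient[:3], orient[3:])
    datasets.sort(key=lambda ds: float(np.dot(np.array(ds.ImagePositionPatient, float), normal)))

    positions = np.array([np.dot(np.array(ds.ImagePositionPatient, float), normal) for ds in datasets])
    if len(positions) > 1:
        steps = np.diff(positions)
        if steps.min() <= 0:
            raise InconsistentGeometryError("inconsistent geometry: duplicate or unsorted slice positions")
        if (steps.max() - steps.min()) > _SLICE_SPACING_RTOL * abs(steps.mean()):
            raise InconsistentGeometryError("inconsistent geometry: non-uniform slice spacing")
        dz = float(steps.mean())
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0) or 1.0)

    dy, dx = (float(v) for v in ref.PixelSpacing)
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        slices.append(arr * slope + intercept)
    voxels = np.stack(slices, axis=0)

    meta = _dicom_patient_meta(ref)
    units = str(getattr(ref, "Units", "")).upper()
    if units in ("BQML", "KBQ/ML", "BQ/ML"):
        scale = 1e-3 if units == "BQML" else 1.0  # to kBq/ml
        if meta.weight_kg is None or meta.injected_activity_MBq is None:
            raise MetadataError("metadata incomplete: weight/activity needed for SUV conversion")
        voxels = suv_bw(
            voxels * scale,
            meta.weight_kg,
            meta.injected_activity_MBq,
            meta.uptake_time_min or 0.0,
        )
    origin = tuple(float(v) for v in datasets[0].ImagePositionPatient)
    return SuvVolume(voxels=voxels, spacing=(dx, dy, dz), origin=origin, meta=meta)


def _dicom_patient_meta(ds) -> PatientMeta:
    meta = PatientMeta(study_id=str(getattr(ds, "StudyInstanceUID", "")))
    weight = getattr(ds, "PatientWeight", None)
    if weight is not None:
        meta.weight_kg = float(weight)
    seq = getattr(ds, "RadiopharmaceuticalInformationSequence", None)
    if seq:
        item = seq[0]
        dose_bq = getattr(item, "RadionuclideTotalDose", None)
        if dose_bq is not None:
            meta.injected_activity_MBq = float(dose_bq) / 1e6
        start = getattr(item, "RadiopharmaceuticalStartTime", None)
        acq = getattr(ds, "AcquisitionTime", None)
        if start is not None and acq is not None:
            meta.uptake_time_min = max(0.0, (_dcm_time_s(str(acq)) - _dcm_time_s(str(start))) / 60.0)
    return meta


def _dcm_time_s(t: str) -> float:
    t = t.split("+")[0]
    h, m = int(t[0:2]), int(t[2:4])
    s = float(t[4:]) if len(t) > 4 else 0.0
    return h * 3600 + m * 60 + s


def read_volume(path: str | os.PathLike, format_hint: str | None = None) -> SuvVolume:
    """Read a PET volume from a NIfTI file or a DICOM series directory.

    ``format_hint`` may be ``"nifti"`` or ``"dicom_series"``; by default the
    format is inferred from the path (directory → DICOM, file → NIfTI).
    DICOM volumes stored as activity concentration are converted to SUV using
    header metadata.
    """
    path = Path(path)
    if not path.exists():
        raise AmbiguousInputError(f"ambiguous input: {path} does not exist")
    if format_hint is None:
        format_hint = "dicom_series" if path.is_dir() else "nifti"
    if format_hint == "nifti":
        return _read_nifti(path)
    if format_hint == "dicom_series":
        return _read_dicom_series(path)
    raise AmbiguousInputError(f"ambiguous input: unknown format hint {format_hint!r}")


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    """Convert results (dataclasses, arrays, numpy scalars) to JSON-safe data."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(results: Mapping[str, Any] | Sequence[Any], path: str | os.PathLike) -> Path:
    """Write results as a JSON report (plus a CSV for tabular entries).

    ``results`` is a non-empty mapping of name → result object (dataclass or
    plain data). Numeric fields survive a JSON round trip bit-exactly
    (written with ``repr`` precision).
    """
    if results is None or len(results) == 0:
        raise IOErrorPetNoise("io error: refusing to write an empty report")
    path = Path(path)
    payload = _jsonable(results)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise IOErrorPetNoise(f"io error: cannot write {path}") from exc
    return path


def read_report(path: str | os.PathLike) -> Any:
    with open(path) as fh:
        return json.load(fh)


def write_histogram_csv(hist, path: str | os.PathLike) -> Path:
    """Write a noise histogram as CSV with columns bin_left, bin_right, count."""
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["bin_left", "bin_right", "count"])
            for left, right, count in zip(hist.bin_edges[:-1], hist.bin_edges[1:], hist.counts):
                w.writerow([repr(float(left)), repr(float(right)), int(count)])
    except OSError as exc:
        raise IOErrorPetNoise(f"io error: cannot write {path}") from exc
    return path
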