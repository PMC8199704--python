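"""DICOM-RT input/output, contour rasterization, and dose resampling.

Grids follow DICOM patient-coordinate conventions: ``origin`` is the
centre of voxel (0, 0, 0) in mm, arrays are indexed ``[z, y, x]``
(frame, row, column) with 0-based indices and voxel-centre semantics.
Only axis-aligned (identity orientation) grids are supported, which
covers standard supine axial acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import shapely
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

from .errors import (
    DicomFormatError,
    DicomModalityError,
    GeometryMismatchError,
    InvalidInputError,
)

_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"


@dataclass(frozen=True)
class GridGeometry:
    """Axis-aligned voxel grid: origin (mm), spacing (mm), dimensions."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]  # (nx, ny, nz)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.dims):
            raise InvalidInputError(f"dimensions must be >= 1, got {self.dims}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape (nz, ny, nx)."""
        nx, ny, nz = self.dims
        return (nz, ny, nx)

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0

    def axis_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates along x, y, z."""
        return tuple(
            self.origin[i] + self.spacing[i] * np.arange(self.dims[i])
            for i in range(3)
        )

    def approx_equal(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on a grid; values indexed [z, y, x]."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise InvalidInputError(
                f"dose shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidInputError("dose values must be finite and nonnegative")


@dataclass
class CTVolume:
    """CT numbers (HU) on a grid; values indexed [z, y, x]."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise InvalidInputError(
                f"CT shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("CT values must be finite")


@dataclass(frozen=True)
class PlanarContour:
    """One closed planar contour: slice position z (mm) and (x, y) vertices."""

    z: float
    vertices: np.ndarray  # shape (n, 2), mm

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise InvalidInputError("contour needs >= 3 (x, y) vertices")
        if not (np.all(np.isfinite(v)) and np.isfinite(self.z)):
            raise InvalidInputError("contour coordinates must be finite")
        object.__setattr__(self, "vertices", v)


@dataclass
class StructureSet:
    """Organ name -> list of planar contours."""

    rois: dict[str, list[PlanarContour]] = field(default_factory=dict)

    def organ_names(self) -> list[str]:
        return list(self.rois)


@dataclass
class OrganMask:
    """Boolean voxel membership of one organ on a grid."""

    geometry: GridGeometry
    membership: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.geometry.shape:
            raise InvalidInputError("mask shape does not match geometry")

    @property
    def voxel_volume_cm3(self) -> float:
        return self.geometry.voxel_volume_cm3

    @property
    def volume_cm3(self) -> float:
        return float(self.membership.sum()) * self.voxel_volume_cm3


# ---------------------------------------------------------------------------
# DICOM helpers


def _new_file_meta(sop_class_uid: str, sop_instance_uid: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class_uid
    meta.MediaStorageSOPInstanceUID = sop_instance_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class_uid: str, modality: str) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class_uid
    ds.SOPInstanceUID = generate_uid()
    ds.file_meta = _new_file_meta(sop_class_uid, ds.SOPInstanceUID)
    ds.Modality = modality
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SECR-FIXTURE"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    return ds


def _require(ds: Dataset, attr: str, what: str):
    if not hasattr(ds, attr):
        raise DicomFormatError(f"{what}: missing required attribute {attr}")
    return getattr(ds, attr)


def _check_modality(ds: Dataset, expected: str, path) -> None:
    modality = getattr(ds, "Modality", None)
    if modality != expected:
        raise DicomModalityError(
            f"{path}: expected modality {expected}, got {modality!r}"
        )


# ---------------------------------------------------------------------------
# RTDOSE


def read_rtdose(path: str | Path) -> DoseGrid:
    """Read an RTDOSE object into a :class:`DoseGrid` in Gy."""
    ds = pydicom.dcmread(path)
    _check_modality(ds, "RTDOSE", path)
    scaling = float(_require(ds, "DoseGridScaling", "RTDOSE"))
    ipp = [float(v) for v in _require(ds, "ImagePositionPatient", "RTDOSE")]
    ps = [float(v) for v in _require(ds, "PixelSpacing", "RTDOSE")]
    offsets = np.asarray(
        _require(ds, "GridFrameOffsetVector", "RTDOSE"), dtype=float
    )
    if offsets.size > 1:
        dzs = np.diff(offsets)
        if not np.allclose(dzs, dzs[0], atol=1e-6):
            raise DicomFormatError("RTDOSE: non-uniform GridFrameOffsetVector")
        dz = float(dzs[0])
    else:
        dz = 1.0
    arr = ds.pixel_array.astype(np.float64) * scaling
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    nz, ny, nx = arr.shape
    geom = GridGeometry(
        origin=(ipp[0], ipp[1], ipp[2] + float(offsets[0])),
        spacing=(ps[1], ps[0], dz),
        dims=(nx, ny, nz),
    )
    return DoseGrid(geom, arr)


def write_rtdose(grid: DoseGrid, path: str | Path) -> None:
    """Write a :class:`DoseGrid` as a standard RTDOSE object.

    The dose-grid scaling factor is chosen so the maximum dose maps near
    the top of the 32-bit integer range, bounding quantization error by
    half a scaling quantum (~1e-8 of the maximum dose).
    """
    if np.any(grid.values < 0):
        raise InvalidInputError("RTDOSE cannot store negative dose")
    max_dose = float(grid.values.max())
    scaling = max_dose / 4_294_967_000.0 if max_dose > 0 else 1.0
    pixels = np.round(grid.values / scaling).astype(np.uint32)

    ds = _base_dataset(_RTDOSE_SOP, "RTDOSE")
    nz, ny, nx = grid.values.shape
    ox, oy, oz = grid.geometry.origin
    dx, dy, dz = grid.geometry.spacing
    ds.ImagePositionPatient = [ox, oy, oz]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [dy, dx]
    ds.GridFrameOffsetVector = [k * dz for k in range(nz)]
    ds.Rows, ds.Columns, ds.NumberOfFrames = ny, nx, nz
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.PixelData = pixels.tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# CT series


def read_ct_series(directory: str | Path) -> CTVolume:
    """Read one CT series from a directory of slices into HU.

    Slices are sorted by patient z; the rescale slope/intercept of each
    slice is applied.  Mixed series or non-uniform slice spacing (a
    missing slice) raise :class:`DicomFormatError`.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise DicomFormatError(f"no .dcm files in {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(f)
        _check_modality(ds, "CT", f)
        slices.append(ds)
    series_uids = {ds.SeriesInstanceUID for ds in slices}
    if len(series_uids) != 1:
        raise DicomFormatError(f"directory mixes {len(series_uids)} CT series")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dzs = np.diff(zs)
        if not np.allclose(dzs, dzs[0], atol=1e-3):
            raise DicomFormatError("non-uniform CT slice spacing (missing slice?)")
        dz = float(dzs[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    first = slices[0]
    ps = [float(v) for v in first.PixelSpacing]
    hu = np.stack(
        [
            ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope)
            + float(ds.RescaleIntercept)
            for ds in slices
        ]
    )
    nz, ny, nx = hu.shape
    ipp = [float(v) for v in first.ImagePositionPatient]
    geom = GridGeometry(
        origin=(ipp[0], ipp[1], zs[0]), spacing=(ps[1], ps[0], dz), dims=(nx, ny, nz)
    )
    return CTVolume(geom, hu)


def write_ct_series(volume: CTVolume, directory: str | Path) -> None:
    """Write a CT volume as one slice file per frame (slope 1, intercept -1024)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    ox, oy, oz = volume.geometry.origin
    dx, dy, dz = volume.geometry.spacing
    nz, ny, nx = volume.values.shape
    stored = np.round(volume.values + 1024.0)
    if stored.min() < 0 or stored.max() > 65535:
        raise InvalidInputError("HU outside storable range [-1024, 64511]")
    stored = stored.astype(np.uint16)
    for k in range(nz):
        ds = _base_dataset(_CT_SOP, "CT")
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [ox, oy, oz + k * dz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.Rows, ds.Columns = ny, nx
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = stored[k].tobytes()
        ds.save_as(directory / f"ct_{k:04d}.dcm", enforce_file_format=True)


# ---------------------------------------------------------------------------
# RTSTRUCT


def read_rtstruct(path: str | Path) -> StructureSet:
    """Read all ROIs with planar contour data; names preserved verbatim."""
    ds = pydicom.dcmread(path)
    _check_modality(ds, "RTSTRUCT", path)
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in _require(ds, "StructureSetROISequence", "RTSTRUCT")
    }
    out = StructureSet()
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(rc.ReferencedROINumber), f"ROI{rc.ReferencedROINumber}")
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] < 3:
                continue
            contours.append(PlanarContour(z=float(data[0, 2]), vertices=data[:, :2]))
        if not contours:
            warnings.warn(f"ROI {name!r} has no contour geometry; skipped", stacklevel=2)
            continue
        out.rois[name] = contours
    return out


def write_rtstruct(structures: StructureSet, path: str | Path) -> None:
    """Write a minimal RTSTRUCT holding the given planar contours."""
    ds = _base_dataset(_RTSTRUCT_SOP, "RTSTRUCT")
    ds.StructureSetLabel = "SECR"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, contours) in enumerate(structures.rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for contour in contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = contour.vertices.shape[0]
            xyz = np.column_stack(
                [contour.vertices, np.full(len(contour.vertices), contour.z)]
            )
            c.ContourData = [float(v) for v in xyz.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# Rasterization and resampling


def rasterize(
    contours: list[PlanarContour], geometry: GridGeometry, name: str = "organ"
) -> OrganMask:
    """Rasterize planar contours to a voxel mask on the given grid.

    A voxel belongs to the organ iff its centre lies inside the contour
    polygon(s) assigned to its slice under the even-odd rule: multiple
    polygons on one slice combine by parity, so holes subtract, and
    vertex orientation is irrelevant.  Points exactly on a polygon edge
    count as inside (deterministic tie-break).  Contours are assigned to
    the nearest grid slice; contours farther than dz/2 from any slice
    are dropped with a warning.
    """
    nz, ny, nx = geometry.shape
    mask = np.zeros((nz, ny, nx), dtype=bool)
    xs, ys, zs = geometry.axis_coords()
    X, Y = np.meshgrid(xs, ys)  # (ny, nx)
    pts = shapely.points(np.column_stack([X.ravel(), Y.ravel()]))
    oz, dz = geometry.origin[2], geometry.spacing[2]
    for contour in contours:
        k = int(round((contour.z - oz) / dz))
        if k < 0 or k >= nz or abs(contour.z - zs[k]) > dz / 2 + 1e-9:
            warnings.warn(
                f"contour at z={contour.z:g} outside grid z-range; ignored",
                stacklevel=2,
            )
            continue
        poly = Polygon(contour.vertices)
        inside = shapely.covers(poly, pts).reshape(ny, nx)
        mask[k] ^= inside
    return OrganMask(geometry=geometry, membership=mask, name=name)


def resample_to(dose: DoseGrid, target: GridGeometry) -> DoseGrid:
    """Trilinearly interpolate a dose grid onto another geometry.

    Target voxel centres outside the source extent are clamped to the
    nearest source voxel (never an error), so degenerate single-voxel
    axes are handled gracefully.
    """
    if dose.geometry.approx_equal(target):
        return DoseGrid(target, dose.values.copy())
    sx, sy, sz = dose.geometry.spacing
    ox, oy, oz = dose.geometry.origin
    txs, tys, tzs = target.axis_coords()
    iz, iy, ix = np.meshgrid(
        (tzs - oz) / sz, (tys - oy) / sy, (txs - ox) / sx, indexing="ij"
    )
    values = map_coordinates(
        dose.values, [iz, iy, ix], order=1, mode="nearest"
    )
    return DoseGrid(target, values)


def resample_dose(dose: DoseGrid, target_spacing: float | tuple = 2.0) -> DoseGrid:
    """Resample a dose grid to a new spacing over the same physical extent.

    The default 2 mm isotropic spacing is the reporting resolution used
    for dose-distribution display; the origin (first voxel centre) is
    preserved and the number of voxels per axis is the largest count
    whose centres stay within the source extent.
    """
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * 3
    if any(s <= 0 for s in target_spacing):
        raise InvalidInputError("target spacing must be positive")
    dims = tuple(
        int(np.floor((n - 1) * s_old / s_new + 1e-9)) + 1
        for n, s_old, s_new in zip(
            dose.geometry.dims, dose.geometry.spacing, target_spacing
        )
    )
    target = GridGeometry(dose.geometry.origin, tuple(target_spacing), dims)
    return resample_to(dose, target)
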