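"""CT volume / mask containers and DICOM / NIfTI input-output.

The canonical in-memory layout is ``(slice, row, column)`` with slice index 0
being the most cranial slice when ``cranial_first`` is true.  Loaders normalise
to this convention so the craniocaudal cutoff downstream always knows which end
of the stack is the head end.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom


@dataclasses.dataclass
class CTVolume:
    """A CT scan as a 3-D grid of Hounsfield units.

    Parameters
    ----------
    voxels
        ``(n_slices, height, width)`` float array of HU values.
    spacing
        ``(slice_thickness_mm, pixel_height_mm, pixel_width_mm)``, all > 0.
    cranial_first
        True iff slice index 0 is the most cranial (head-end) slice.
    scan_id
        Opaque identifier carried through reports.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    cranial_first: bool = True
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got shape {self.voxels.shape}")
        if min(self.voxels.shape) < 1:
            raise ValueError("every volume extent must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 finite positive values, got {self.spacing}")
        if not np.isfinite(self.voxels).all():
            raise ValueError("voxels contain NaN or Inf after load")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_thickness_mm(self) -> float:
        return self.spacing[0]

    def copy_with(self, voxels: np.ndarray, spacing=None) -> "CTVolume":
        return CTVolume(
            voxels=voxels,
            spacing=self.spacing if spacing is None else spacing,
            cranial_first=self.cranial_first,
            scan_id=self.scan_id,
        )


@dataclasses.dataclass
class MaskVolume:
    """Integer label grid aligned to a :class:`CTVolume`.

    Class index 0 is background, index 1 the IVC filter.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_names: tuple[str, ...] = ("background", "IVCF")
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            # accept float input only when it is exactly integral
            as_int = self.labels.astype(np.uint8)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("mask labels must be integers")
            self.labels = as_int
        self.labels = self.labels.astype(np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3-D, got shape {self.labels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        n_cls = len(self.class_names)
        if self.labels.size and int(self.labels.max()) >= n_cls:
            raise ValueError(
                f"label value {int(self.labels.max())} out of range for {n_cls} classes"
            )

    def copy_with(self, labels: np.ndarray, spacing=None) -> "MaskVolume":
        return MaskVolume(
            labels=labels,
            spacing=self.spacing if spacing is None else spacing,
            class_names=self.class_names,
            scan_id=self.scan_id,
        )


# --------------------------------------------------------------------------
# DICOM
# --------------------------------------------------------------------------

def _slice_position(ds: pydicom.Dataset, path: Path) -> float:
    """Coordinate of a slice along the stack normal, from position metadata."""
    try:
        pos = np.asarray([float(v) for v in ds.ImagePositionPatient])
        orient = np.asarray([float(v) for v in ds.ImageOrientationPatient])
    except AttributeError as exc:
        raise ValueError(f"missing position/orientation metadata in {path}") from exc
    normal = np.cross(orient[:3], orient[3:])
    return float(pos @ normal), float(normal[2])


def load_dicom_series(directory_path) -> CTVolume:
    """Load a single-frame CT series from a directory of DICOM files.

    Slices are sorted by their physical position along the slice normal (file
    names are ignored), rescale slope/intercept are applied so voxel values are
    HU, and the stack is flipped if needed so slice 0 is the most cranial.
    """
    directory = Path(directory_path)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            datasets.append((p, pydicom.dcmread(p)))
        except pydicom.errors.InvalidDicomError:
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")

    uids = {str(ds.get("SeriesInstanceUID", "")) for _, ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed series UIDs in {directory}: {sorted(uids)}")

    keyed = []
    for p, ds in datasets:
        z, normal_z = _slice_position(ds, p)
        keyed.append((z, normal_z, p, ds))
    keyed.sort(key=lambda t: t[0])

    slices = []
    for _, _, p, ds in keyed:
        slope = float(ds.get("RescaleSlope", 1.0))
        intercept = float(ds.get("RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    voxels = np.stack(slices, axis=0)

    zs = [t[0] for t in keyed]
    if len(zs) > 1:
        deltas = np.diff(zs)
        thickness = float(np.median(np.abs(deltas)))
        if thickness <= 0:
            raise ValueError(f"duplicate slice positions in {directory}")
    else:
        thickness = float(keyed[0][3].get("SliceThickness", 1.0))

    ps = keyed[0][3].get("PixelSpacing", [1.0, 1.0])
    spacing = (thickness, float(ps[0]), float(ps[1]))

    # DICOM patient +z points cranially: ascending sort along a normal with a
    # positive z-component puts the head end last, so flip to cranial-first.
    if keyed[0][1] >= 0:
        voxels = voxels[::-1].copy()

    return CTVolume(
        voxels=voxels,
        spacing=spacing,
        cranial_first=True,
        scan_id=str(datasets[0][1].get("SeriesInstanceUID", directory.name)),
    )


# --------------------------------------------------------------------------
# NIfTI
# --------------------------------------------------------------------------

_DESCRIP_RE = re.compile(rb"cranial_first=(\d)")


def save_nifti(volume_or_mask, path) -> None:
    """Write a :class:`CTVolume` (float32) or :class:`MaskVolume` (uint8) to NIfTI-1.

    Array axes are stored in the package's ``(slice, row, column)`` order with
    the matching zooms, so a save/load round trip is bit-exact on voxels.
    """
    obj = volume_or_mask
    if isinstance(obj, CTVolume):
        data = obj.voxels.astype(np.float32)
        descrip = f"cranial_first={int(obj.cranial_first)}".encode()
    elif isinstance(obj, MaskVolume):
        data = obj.labels.astype(np.uint8)
        descrip = b"mask"
    else:
        raise TypeError(f"expected CTVolume or MaskVolume, got {type(obj)}")
    affine = np.diag(list(obj.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing)
    img.header["descrip"] = descrip
    nib.save(img, str(path))


def load_nifti(path, as_mask: bool = False):
    """Load a NIfTI-1 file as a :class:`CTVolume` or (``as_mask=True``) :class:`MaskVolume`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI image, got {data.ndim}-D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    name = Path(path).name
    if as_mask:
        return MaskVolume(labels=data, spacing=spacing, scan_id=name)
    m = _DESCRIP_RE.search(bytes(img.header["descrip"].tobytes()))
    cranial_first = bool(int(m.group(1))) if m else True
    return CTVolume(
        voxels=data.astype(np.float32),
        spacing=spacing,
        cranial_first=cranial_first,
        scan_id=name,
    )
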