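"""CT volume container and readers/writers for NIfTI, DICOM series and VTK ImageData.

The central object is :class:`Volume`: a 3D scalar grid indexed ``(x, y, z)``
with ``z`` the slice (depth) axis, per-axis voxel spacing in millimetres and a
world-space origin. All depth-axis operations downstream (chunking, LOD,
ROI cropping) act on the last axis of ``Volume.data``.

NIfTI is handled through nibabel and DICOM through pydicom; the VTK XML
ImageData (``.vti``) dialect written here is a single self-contained file with
one inline base64-encoded little-endian scalar array named ``"intensity"``,
so a volume can round-trip without any VTK installation.
"""

from __future__ import annotations

import base64
import struct
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pydicom

from .errors import FormatError, ValidationError, VolumeIOError

__all__ = [
    "Volume",
    "read_nifti",
    "write_nifti",
    "read_dicom_series",
    "read_vti",
    "write_vti",
]


@dataclass
class Volume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    data
        Array of shape ``(width, height, depth)``; the last axis is the
        slice axis.
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm, each strictly positive.
    origin
        World-space position in mm of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_range: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume data must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        if self.data.size == 0:
            raise ValidationError("volume data must be non-empty")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValidationError(f"spacing must be three positive finite values, got {self.spacing}")
        if self.intensity_range is None:
            self.intensity_range = (float(self.data.min()), float(self.data.max()))
        else:
            self.intensity_range = (
                float(self.intensity_range[0]),
                float(self.intensity_range[1]),
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        """(width, height, depth) in voxels."""
        return tuple(int(n) for n in self.data.shape)  # type: ignore[return-value]

    @property
    def dtype_bits(self) -> int:
        return int(self.data.dtype.itemsize) * 8

    @property
    def nbytes(self) -> int:
        return int(self.data.nbytes)

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge lengths of the volume's bounding box in mm (dims × spacing)."""
        return tuple(d * s for d, s in zip(self.dims, self.spacing))  # type: ignore[return-value]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box (min corner, max corner) in mm.

        Voxel ``i`` is centred at ``origin + i * spacing``, so the box extends
        half a voxel beyond the first/last centres and spans exactly
        ``dims * spacing``.
        """
        o = np.asarray(self.origin, dtype=float)
        sp = np.asarray(self.spacing, dtype=float)
        d = np.asarray(self.dims, dtype=float)
        return o - 0.5 * sp, o + (d - 0.5) * sp

    def with_data(self, data: np.ndarray, **kwargs) -> "Volume":
        """New Volume sharing this one's metadata, with fresh voxel data."""
        meta = dict(spacing=self.spacing, origin=self.origin)
        meta.update(kwargs)
        return Volume(data=data, **meta)

    def copy(self) -> "Volume":
        return replace(self, data=self.data.copy())


# ---------------------------------------------------------------------------
# NIfTI


def read_nifti(path) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    Spacing comes from the header pixdim fields; the scl_slope/scl_inter
    scaling is applied (by nibabel) so stored values are physical intensities.
    A 4D image with a singleton trailing axis is squeezed to 3D.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise FormatError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    # squeeze trailing singleton axes (e.g. header-declared 4D with one frame)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(
            f"expected a 3D NIfTI image, got shape {data.shape} in {path}"
        )
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_nifti(vol: Volume, path) -> Path:
    """Write a volume as NIfTI-1 with a diagonal spacing affine."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# DICOM series


def _slice_position(ds) -> float:
    """Project ImagePositionPatient onto the slice normal; fall back to InstanceNumber."""
    try:
        iop = np.asarray([float(v) for v in ds.ImageOrientationPatient], dtype=float)
        normal = np.cross(iop[:3], iop[3:])
        ipp = np.asarray([float(v) for v in ds.ImagePositionPatient], dtype=float)
        return float(np.dot(ipp, normal))
    except Exception:
        try:
            return float(ds.InstanceNumber)
        except Exception:
            raise FormatError(
                "DICOM slice has neither usable ImagePositionPatient/"
                "ImageOrientationPatient nor InstanceNumber"
            ) from None


def read_dicom_series(directory) -> Volume:
    """Assemble a single-frame CT DICOM series into a :class:`Volume`.

    Slices are sorted into ascending spatial order by the projection of
    ImagePositionPatient onto the slice normal (fallback: InstanceNumber), so
    assembly is invariant to the filename listing order. RescaleSlope and
    RescaleIntercept are applied; the slice spacing ``sz`` is the median
    inter-slice spatial distance, falling back to the SliceThickness tag for
    a one-slice series.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise VolumeIOError(f"no such directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue  # skip non-DICOM files quietly
    if not datasets:
        raise VolumeIOError(f"no readable DICOM files in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise ValidationError(f"mixed SeriesInstanceUIDs in {directory}: {sorted(map(str, uids))}")

    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) > 1:
        raise ValidationError(f"non-uniform in-plane dimensions across slices: {sorted(shapes)}")

    datasets.sort(key=_slice_position)
    positions = np.asarray([_slice_position(ds) for ds in datasets], dtype=float)

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        slices.append(arr)
    stack = np.stack(slices, axis=-1)  # (rows, cols, z)
    if np.allclose(stack, np.round(stack)):
        stack = stack.astype(np.int32)
    # (rows, cols, z) -> (x, y, z): DICOM rows run along y, columns along x
    data = np.transpose(stack, (1, 0, 2))

    ds0 = datasets[0]
    try:
        # PixelSpacing is (row spacing = y, column spacing = x)
        sy, sx = (float(v) for v in ds0.PixelSpacing)
    except Exception:
        sx = sy = 1.0
    if len(datasets) > 1:
        sz = float(np.median(np.diff(positions)))
        if sz <= 0:
            raise ValidationError("non-increasing slice positions after sorting")
    else:
        sz = float(getattr(ds0, "SliceThickness", 1.0))
    try:
        ox, oy, oz = (float(v) for v in ds0.ImagePositionPatient)
    except Exception:
        ox = oy = oz = 0.0
    return Volume(data=data, spacing=(sx, sy, sz), origin=(ox, oy, oz))


# ---------------------------------------------------------------------------
# VTK XML ImageData (.vti)

_VTK_TYPES = {
    np.dtype("int8"): "Int8",
    np.dtype("uint8"): "UInt8",
    np.dtype("int16"): "Int16",
    np.dtype("uint16"): "UInt16",
    np.dtype("int32"): "Int32",
    np.dtype("uint32"): "UInt32",
    np.dtype("int64"): "Int64",
    np.dtype("uint64"): "UInt64",
    np.dtype("float32"): "Float32",
    np.dtype("float64"): "Float64",
}
_NP_TYPES = {v: k for k, v in _VTK_TYPES.items()}


def write_vti(vol: Volume, path) -> Path:
    """Write a volume as VTK XML ImageData with an inline base64 payload.

    One point-data scalar array named ``"intensity"`` is stored little-endian
    in VTK's x-fastest order, prefixed by a uint64 byte count and base64
    encoded as a single block. ``read_vti(write_vti(v))`` reproduces ``v``
    bit-exactly.
    """
    path = Path(path)
    dtype = vol.data.dtype
    if dtype not in _VTK_TYPES:
        raise ValidationError(f"unsupported dtype for .vti output: {dtype}")
    w, h, d = vol.dims
    # VTK stores x fastest, then y, then z: C-order over (z, y, x)
    payload = np.ascontiguousarray(
        np.transpose(vol.data, (2, 1, 0)), dtype=dtype.newbyteorder("<")
    ).tobytes()
    blob = base64.b64encode(struct.pack("<Q", len(payload)) + payload).decode("ascii")

    root = ET.Element(
        "VTKFile",
        type="ImageData",
        version="1.0",
        byte_order="LittleEndian",
        header_type="UInt64",
    )
    grid = ET.SubElement(
        root,
        "ImageData",
        WholeExtent=f"0 {w - 1} 0 {h - 1} 0 {d - 1}",
        Origin=" ".join(repr(v) for v in vol.origin),
        Spacing=" ".join(repr(v) for v in vol.spacing),
    )
    piece = ET.SubElement(grid, "Piece", Extent=f"0 {w - 1} 0 {h - 1} 0 {d - 1}")
    pdata = ET.SubElement(piece, "PointData", Scalars="intensity")
    arr = ET.SubElement(
        pdata,
        "DataArray",
        type=_VTK_TYPES[dtype],
        Name="intensity",
        NumberOfComponents="1",
        format="binary",
    )
    arr.text = blob
    try:
        ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8")
    except OSError as exc:
        raise VolumeIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_vti(path) -> Volume:
    """Read a ``.vti`` file written by :func:`write_vti` back into a Volume.

    A file lacking a Spacing attribute gets spacing ``(1, 1, 1)`` with a
    warning. Truncated or non-ImageData files raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"not a well-formed .vti file: {path}: {exc}") from exc
    if root.tag != "VTKFile" or root.get("type") != "ImageData":
        raise FormatError(f"{path} is not a VTK XML ImageData file")
    grid = root.find("ImageData")
    if grid is None:
        raise FormatError(f"{path} has no ImageData element")
    extent = grid.get("WholeExtent")
    if extent is None:
        raise FormatError(f"{path} lacks a WholeExtent attribute")
    x0, x1, y0, y1, z0, z1 = (int(v) for v in extent.split())
    dims = (x1 - x0 + 1, y1 - y0 + 1, z1 - z0 + 1)
    spacing_attr = grid.get("Spacing")
    if spacing_attr is None:
        warnings.warn(f"{path} has no Spacing attribute; defaulting to (1, 1, 1)")
        spacing = (1.0, 1.0, 1.0)
    else:
        spacing = tuple(float(v) for v in spacing_attr.split())
    origin = tuple(float(v) for v in (grid.get("Origin") or "0 0 0").split())

    arr_el = grid.find(".//DataArray[@Name='intensity']")
    if arr_el is None:
        arr_el = grid.find(".//DataArray")
    if arr_el is None or not (arr_el.text or "").strip():
        raise FormatError(f"{path} has no scalar DataArray payload")
    if arr_el.get("format") != "binary":
        raise FormatError(f"unsupported DataArray format {arr_el.get('format')!r} in {path}")
    vtk_type = arr_el.get("type")
    if vtk_type not in _NP_TYPES:
        raise FormatError(f"unsupported DataArray type {vtk_type!r} in {path}")
    dtype = _NP_TYPES[vtk_type]
    try:
        raw = base64.b64decode(arr_el.text.strip(), validate=True)
    except Exception as exc:
        raise FormatError(f"corrupt base64 payload in {path}: {exc}") from exc
    if len(raw) < 8:
        raise FormatError(f"truncated payload in {path}")
    (nbytes,) = struct.unpack("<Q", raw[:8])
    payload = raw[8 : 8 + nbytes]
    expected = dims[0] * dims[1] * dims[2] * dtype.itemsize
    if nbytes != expected or len(payload) != expected:
        raise FormatError(
            f"payload size mismatch in {path}: header {nbytes}, "
            f"got {len(payload)}, expected {expected}"
        )
    flat = np.frombuffer(payload, dtype=dtype.newbyteorder("<")).astype(dtype)
    data = np.transpose(flat.reshape(dims[2], dims[1], dims[0]), (2, 1, 0))
    return Volume(data=data, spacing=spacing, origin=origin)
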