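"""Level-of-detail (LOD) decision and trilinear downsampling.

When any dimension of a combined volume exceeds the target maximum dimension
(half the maximum 3D texture size), the volume is reduced by a single
isotropic factor

    maxFactor = max(dim_x, dim_y, dim_z) / targetMaxDimension

and each axis is resized to ``ceil(dim / maxFactor)`` voxels by trilinear
interpolation, with voxel spacing rescaled so the physical extent is
preserved. The output of a downsampling pass never needs downsampling again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .resources import ResourceProfile
from .volume_io import Volume

__all__ = [
    "LODResult",
    "target_max_dimension",
    "lod_factor",
    "lod_output_dims",
    "needs_downsampling",
    "trilinear_sample",
    "downsample_trilinear",
    "apply_lod",
]


@dataclass(frozen=True)
class LODResult:
    """Outcome of an LOD pass: the (possibly passthrough) volume and its factor."""

    volume: Volume
    max_factor: float
    target_max_dimension: int | None
    applied: bool


def target_max_dimension(profile: ResourceProfile) -> int:
    """Half the maximum 3D texture size, floored to an integer."""
    return profile.max_3d_texture_size // 2


def lod_factor(dims: tuple[int, int, int], target: int) -> float:
    """Isotropic reduction factor: max per-axis ratio to the target, at least 1."""
    if target < 1 or any(d < 1 for d in dims):
        raise ValidationError("dims and target must be >= 1")
    return max(1.0, max(d / target for d in dims))


def lod_output_dims(dims: tuple[int, int, int], max_factor: float) -> tuple[int, int, int]:
    """Resized grid dims: ceil(dim / maxFactor) per axis."""
    if max_factor < 1:
        raise ValidationError(f"max_factor must be >= 1, got {max_factor}")
    return tuple(math.ceil(d / max_factor) for d in dims)  # type: ignore[return-value]


def needs_downsampling(vol: Volume, profile: ResourceProfile) -> bool:
    """True iff any axis strictly exceeds the target maximum dimension."""
    return max(vol.dims) > target_max_dimension(profile)


def trilinear_sample(vol: Volume, x, y, z):
    """Trilinear interpolation of the volume at fractional voxel indices.

    Accepts scalars or broadcastable arrays. Coordinates are clamped to the
    valid index range, so integer in-range coordinates return stored voxel
    values exactly and border samples clamp rather than extrapolate.
    """
    coords = [np.asarray(c, dtype=float) for c in (x, y, z)]
    if any(np.any(np.isnan(c)) for c in coords):
        raise ValidationError("NaN sample coordinate")
    data = vol.data
    out_shape = np.broadcast(*coords).shape
    idx0 = []
    idx1 = []
    frac = []
    for c, n in zip(coords, data.shape):
        c = np.clip(c, 0.0, n - 1.0)
        i0 = np.floor(c).astype(np.intp)
        i0 = np.minimum(i0, n - 1 if n == 1 else n - 2)
        idx0.append(i0)
        idx1.append(np.minimum(i0 + 1, n - 1))
        frac.append(c - i0)
    x0, y0, z0 = idx0
    x1, y1, z1 = idx1
    fx, fy, fz = frac
    # weighted sum over the 8 surrounding voxels
    c000 = data[x0, y0, z0]
    c100 = data[x1, y0, z0]
    c010 = data[x0, y1, z0]
    c110 = data[x1, y1, z0]
    c001 = data[x0, y0, z1]
    c101 = data[x1, y0, z1]
    c011 = data[x0, y1, z1]
    c111 = data[x1, y1, z1]
    c00 = c000 * (1 - fx) + c100 * fx
    c10 = c010 * (1 - fx) + c110 * fx
    c01 = c001 * (1 - fx) + c101 * fx
    c11 = c011 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    out = c0 * (1 - fz) + c1 * fz
    if out_shape == ():
        return float(out)
    return out


def _axis_coords(n_in: int, n_out: int) -> np.ndarray:
    # endpoint-preserving mapping: out index i -> i * (n_in - 1) / (n_out - 1);
    # a single output sample lands on the axis centre
    if n_out == 1:
        return np.array([(n_in - 1) / 2.0])
    return np.arange(n_out, dtype=float) * ((n_in - 1) / (n_out - 1))


def downsample_trilinear(
    vol: Volume, max_factor: float, *, target: int | None = None
) -> LODResult:
    """Resize every axis to ``ceil(dim / max_factor)`` voxels by trilinear interpolation.

    The output grid preserves the first and last sample of each axis
    (endpoint-preserving mapping) and the spacing is rescaled by
    ``in_dim / out_dim`` so the physical extent is unchanged. Integer input
    volumes are rounded back to their input dtype.
    """
    if max_factor < 1:
        raise ValidationError(f"max_factor must be >= 1, got {max_factor}")
    if max_factor == 1.0:
        return LODResult(volume=vol, max_factor=1.0, target_max_dimension=target, applied=False)
    in_dims = vol.dims
    out_dims = lod_output_dims(in_dims, max_factor)
    xs = _axis_coords(in_dims[0], out_dims[0])
    ys = _axis_coords(in_dims[1], out_dims[1])
    zs = _axis_coords(in_dims[2], out_dims[2])
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    out = trilinear_sample(vol, gx, gy, gz)
    if np.issubdtype(vol.data.dtype, np.integer):
        out = np.rint(out).astype(vol.data.dtype)
    else:
        out = out.astype(vol.data.dtype)
    spacing = tuple(
        s * (di / do) for s, di, do in zip(vol.spacing, in_dims, out_dims)
    )
    down = Volume(data=out, spacing=spacing, origin=vol.origin)
    return LODResult(
        volume=down,
        max_factor=float(max_factor),
        target_max_dimension=target,
        applied=True,
    )


def apply_lod(vol: Volume, profile: ResourceProfile) -> LODResult:
    """Downsample a volume iff it exceeds the profile's target dimension."""
    target = target_max_dimension(profile)
    if not needs_downsampling(vol, profile):
        return LODResult(volume=vol, max_factor=1.0, target_max_dimension=target, applied=False)
    factor = lod_factor(vol.dims, target)
    return downsample_trilinear(vol, factor, target=target)
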