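"""Region-of-interest refinement: native-resolution re-rendering.

After an initial level-of-detail pass, a box selected on the downsampled
grid is mapped back to original voxel indices with outward (floor/ceil)
rounding — so the mapped box always physically contains the requested one —
cropped bit-exactly from the full-resolution volume, and re-rendered with
the viewer's camera pose preserved (re-targeted to the subvolume centre,
restored afterwards).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .lod import apply_lod
from .render import Camera, RenderSettings, render
from .resources import ResourceProfile
from .transfer import TransferFunction
from .volume_io import Volume

__all__ = ["ROIBox", "map_roi_to_original", "extract_subvolume", "rerender_roi"]


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned half-open voxel index box [a0, a1) per axis on a tagged grid."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]
    grid: str = "original"  # "original" | "downsampled"

    def __post_init__(self) -> None:
        if self.grid not in ("original", "downsampled"):
            raise ValidationError(f"unknown grid tag {self.grid!r}")
        for a0, a1 in (self.x, self.y, self.z):
            if a0 < 0 or a1 <= a0:
                raise ValidationError(f"invalid half-open range [{a0}, {a1})")

    @property
    def ranges(self) -> tuple[tuple[int, int], ...]:
        return (self.x, self.y, self.z)

    def dims(self) -> tuple[int, int, int]:
        return tuple(a1 - a0 for a0, a1 in self.ranges)  # type: ignore[return-value]


def map_roi_to_original(
    box: ROIBox, max_factor: float, original_dims: tuple[int, int, int]
) -> ROIBox:
    """Map a box on the downsampled grid back to original voxel indices.

    Start indices are floored, end indices ceiled (after scaling by
    ``max_factor``) and clamped to the original dims, so the mapped box's
    world-space extent contains the input box's extent.
    """
    if box.grid != "downsampled":
        raise ValidationError("map_roi_to_original expects a box on the downsampled grid")
    if max_factor < 1:
        raise ValidationError(f"max_factor must be >= 1, got {max_factor}")
    ranges = []
    for (a0, a1), dim in zip(box.ranges, original_dims):
        b0 = max(0, min(math.floor(a0 * max_factor), dim - 1))
        b1 = max(b0 + 1, min(math.ceil(a1 * max_factor), dim))
        if b1 <= b0:
            raise ValidationError(f"ROI box empty after clamping to dims {original_dims}")
        ranges.append((b0, b1))
    return ROIBox(x=ranges[0], y=ranges[1], z=ranges[2], grid="original")


def extract_subvolume(vol: Volume, box: ROIBox) -> Volume:
    """Crop a box from a volume without resampling.

    The subvolume's voxels are bit-equal to the parent slab; its origin is
    shifted by ``a0 × spacing`` per axis and the spacing is unchanged.
    """
    if box.grid != "original":
        # the box must be expressed on the grid it indexes into
        raise ValidationError("extract_subvolume expects a box tagged to this volume's grid")
    for (a0, a1), dim in zip(box.ranges, vol.dims):
        if a1 > dim:
            raise ValidationError(f"ROI box {box.ranges} exceeds volume dims {vol.dims}")
    (x0, x1), (y0, y1), (z0, z1) = box.ranges
    origin = tuple(
        o + a0 * s for o, (a0, _), s in zip(vol.origin, box.ranges, vol.spacing)
    )
    return Volume(data=vol.data[x0:x1, y0:y1, z0:z1], spacing=vol.spacing, origin=origin)


def _retarget(cam: Camera, subvol: Volume) -> Camera:
    """Same pose (direction, up, zoom, distance), aimed at the subvolume centre."""
    lo, hi = subvol.world_bounds()
    center = (lo + hi) / 2.0
    d = np.asarray(cam.view_dir)
    distance = 2.0 * float(np.max(hi - lo))
    return Camera(
        position=tuple(center - d * distance),
        view_dir=cam.view_dir,
        up=cam.up,
        projection=cam.projection,
        view_size=cam.view_size,
        image_size=cam.image_size,
    )


def rerender_roi(
    original: Volume,
    box: ROIBox,
    max_factor: float,
    tf: TransferFunction,
    cam: Camera,
    settings: RenderSettings | None = None,
    profile: ResourceProfile | None = None,
) -> np.ndarray:
    """Re-render an ROI chosen on the downsampled grid at native resolution.

    The caller's camera is never mutated (pose before equals pose after);
    rendering uses a copy re-targeted to the subvolume's world-space centre.
    No resampling is applied unless the cropped subvolume itself exceeds the
    profile's texture limit, in which case the LOD pass is re-applied to it.
    """
    mapped = map_roi_to_original(box, max_factor, original.dims)
    sub = extract_subvolume(original, mapped)
    if profile is not None:
        sub = apply_lod(sub, profile).volume
    roi_cam = _retarget(cam, sub)
    return render(sub, tf, roi_cam, settings)
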