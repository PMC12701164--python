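"""CPU ray caster for the emission–absorption volume rendering model.

Rays are marched front to back through the volume at a step of
``sampleDistance × min(spacing)`` mm; each sample's intensity is looked up
trilinearly, mapped through the transfer function, opacity-corrected for the
step length and composited as

    C = Σᵢ cᵢ · αᵢ · Πⱼ<ᵢ (1 − αⱼ)

with early termination once accumulated opacity reaches a threshold. For a
homogeneous medium this discrete sum converges, as the step shrinks, to the
closed-form ray integral c · (1 − exp(−τD)), which the tests use as the
convergence oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .errors import ValidationError
from .lod import trilinear_sample
from .transfer import TransferFunction, color_at, opacity_at
from .volume_io import Volume

__all__ = [
    "Camera",
    "RenderSettings",
    "ClippingPlane",
    "composite_ray",
    "analytic_homogeneous_intensity",
    "opacity_step_correction",
    "gradient_at",
    "gradient_field",
    "render",
    "default_camera",
    "write_png",
    "VIEW_DIRECTIONS",
]

# named anatomical viewing directions: (view direction, up vector)
VIEW_DIRECTIONS = {
    "anterior": ((0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
    "posterior": ((0.0, -1.0, 0.0), (0.0, 0.0, 1.0)),
    "left": ((-1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
    "right": ((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
    "superior": ((0.0, 0.0, -1.0), (0.0, 1.0, 0.0)),
    "inferior": ((0.0, 0.0, 1.0), (0.0, 1.0, 0.0)),
}


def _normalize(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0 or not np.isfinite(n):
        raise ValidationError(f"cannot normalise zero/non-finite vector {v}")
    return v / n


@dataclass
class Camera:
    """View parameters for the ray caster.

    ``view_size`` is the physical width (mm) of the image plane for an
    orthographic camera, or the vertical field of view in degrees for a
    perspective one. ``up`` is re-orthogonalised against ``view_dir``.
    """

    position: tuple[float, float, float]
    view_dir: tuple[float, float, float]
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    projection: str = "orthographic"
    view_size: float = 100.0
    image_size: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        if self.projection not in ("orthographic", "perspective"):
            raise ValidationError(f"unknown projection {self.projection!r}")
        if any(n < 1 for n in self.image_size):
            raise ValidationError("image_size must be positive")
        d = _normalize(self.view_dir)
        u = np.asarray(self.up, dtype=float)
        u = u - np.dot(u, d) * d
        if np.linalg.norm(u) < 1e-12:
            # up parallel to view direction: pick any perpendicular
            u = np.cross(d, [1.0, 0.0, 0.0])
            if np.linalg.norm(u) < 1e-12:
                u = np.cross(d, [0.0, 1.0, 0.0])
        self.view_dir = tuple(float(x) for x in d)
        self.up = tuple(float(x) for x in _normalize(u))
        self.position = tuple(float(x) for x in self.position)

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(right, up, forward) orthonormal triad."""
        fwd = np.asarray(self.view_dir)
        up = np.asarray(self.up)
        right = _normalize(np.cross(fwd, up))
        return right, up, fwd

    def rays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ray origins and unit directions, each shaped (H, W, 3)."""
        w_px, h_px = self.image_size
        right, up, fwd = self.basis()
        # pixel centres in normalised image coordinates
        us = (np.arange(w_px) + 0.5) / w_px - 0.5
        vs = 0.5 - (np.arange(h_px) + 0.5) / h_px
        uu, vv = np.meshgrid(us, vs)  # (H, W)
        if self.projection == "orthographic":
            width = self.view_size
            height = width * h_px / w_px
            origins = (
                np.asarray(self.position)
                + uu[..., None] * width * right
                + vv[..., None] * height * up
            )
            dirs = np.broadcast_to(fwd, origins.shape).copy()
        else:
            half_h = math.tan(math.radians(self.view_size) / 2.0)
            half_w = half_h * w_px / h_px
            dirs = (
                fwd + uu[..., None] * 2 * half_w * right + vv[..., None] * 2 * half_h * up
            )
            dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
            origins = np.broadcast_to(np.asarray(self.position), dirs.shape).copy()
        return origins, dirs


@dataclass(frozen=True)
class ClippingPlane:
    """Half-space clip: samples with (p − point)·normal < 0 are discarded."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]


@dataclass
class RenderSettings:
    """Sampling, shading and clipping controls for :func:`render`.

    sample_distance
        Step length as a fraction of the smallest voxel spacing, in [0.1, 1].
    gradient_opacity_scale
        0 disables gradient modulation; 1 scales opacity fully by the local
        normalised gradient magnitude.
    scalar_opacity_ref
        Reference level on the normalised [0, 255] intensity scale below
        which opacity is linearly attenuated toward zero; 0 disables it.
    """

    sample_distance: float = 0.5
    gradient_opacity_scale: float = 0.0
    scalar_opacity_ref: float = 0.0
    shading: bool = False
    blend_mode: str = "composite"
    clipping_planes: tuple[ClippingPlane, ...] = ()
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)
    early_termination_alpha: float = 0.99

    def __post_init__(self) -> None:
        if not (0.1 <= self.sample_distance <= 1.0):
            raise ValidationError(
                f"sample_distance must lie in [0.1, 1], got {self.sample_distance}"
            )
        if not (0.0 <= self.gradient_opacity_scale <= 1.0):
            raise ValidationError("gradient_opacity_scale must lie in [0, 1]")
        if not (0.0 <= self.scalar_opacity_ref <= 255.0):
            raise ValidationError("scalar_opacity_ref must lie in [0, 255]")
        if self.blend_mode not in ("composite", "max-intensity"):
            raise ValidationError(f"unknown blend_mode {self.blend_mode!r}")
        self.clipping_planes = tuple(self.clipping_planes)


def composite_ray(
    colors, alphas, background=(0.0, 0.0, 0.0), early_termination_alpha: float = 1.0
) -> tuple[np.ndarray, float]:
    """Front-to-back compositing of one ray's ordered samples.

    Returns (RGB, accumulated alpha); remaining transparency multiplies the
    background. Optional early termination stops once accumulated alpha
    reaches the threshold (the truncated tail is bounded by 1 − threshold).
    """
    colors = np.atleast_2d(np.asarray(colors, dtype=float))
    alphas = np.asarray(alphas, dtype=float).ravel()
    if np.any(~np.isfinite(alphas)) or np.any(~np.isfinite(colors)):
        raise ValidationError("non-finite sample in composite_ray")
    if np.any((alphas < 0) | (alphas > 1)):
        raise ValidationError("sample alphas must lie in [0, 1]")
    accum = np.zeros(3)
    acc_alpha = 0.0
    for c, a in zip(colors, alphas):
        accum += c * a * (1.0 - acc_alpha)
        acc_alpha += a * (1.0 - acc_alpha)
        if acc_alpha >= early_termination_alpha:
            break
    accum += (1.0 - acc_alpha) * np.asarray(background, dtype=float)
    return accum, acc_alpha


def analytic_homogeneous_intensity(tau: float, color, depth: float) -> np.ndarray:
    """Closed-form ray integral for a homogeneous medium: c · (1 − exp(−τD))."""
    if tau < 0 or depth < 0:
        raise ValidationError("tau and depth must be nonnegative")
    return np.asarray(color, dtype=float) * (1.0 - math.exp(-tau * depth))


def opacity_step_correction(alpha, step: float, ref_step: float):
    """Rescale per-sample opacity for a step length differing from the reference.

    1 − (1 − α)^(step/ref) keeps the accumulated transmittance of a
    homogeneous ray independent of the sampling step.
    """
    if step <= 0 or ref_step <= 0:
        raise ValidationError("step lengths must be positive")
    alpha = np.asarray(alpha, dtype=float)
    out = 1.0 - np.power(1.0 - np.clip(alpha, 0.0, 1.0), step / ref_step)
    return float(out) if out.shape == () else out


def gradient_field(vol: Volume) -> np.ndarray:
    """Per-voxel intensity gradient (mm⁻¹) as an (w, h, d, 3) array.

    Central differences divided by 2×spacing in the interior, one-sided at
    the borders (numpy.gradient's convention).
    """
    grads = np.gradient(vol.data.astype(float), *vol.spacing)
    return np.stack(grads, axis=-1)


def gradient_at(vol: Volume, idx: tuple[int, int, int]) -> np.ndarray:
    """Intensity gradient at one voxel, via local finite differences."""
    data = vol.data
    out = np.empty(3)
    for ax in range(3):
        n = data.shape[ax]
        i = idx[ax]
        if not (0 <= i < n):
            raise ValidationError(f"index {idx} outside grid {data.shape}")
        lo = list(idx)
        hi = list(idx)
        if 0 < i < n - 1:
            lo[ax] -= 1
            hi[ax] += 1
            h = 2.0 * vol.spacing[ax]
        elif i == 0 and n > 1:
            hi[ax] += 1
            h = vol.spacing[ax]
        elif i == n - 1 and n > 1:
            lo[ax] -= 1
            h = vol.spacing[ax]
        else:  # single-voxel axis
            out[ax] = 0.0
            continue
        out[ax] = (float(data[tuple(hi)]) - float(data[tuple(lo)])) / h
    return out


def _ray_box(origins, dirs, box_min, box_max):
    """Slab-method ray/AABB intersection; returns (t_near, t_far) per ray."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t0 = (box_min - origins) * inv
        t1 = (box_max - origins) * inv
    # rays parallel to an axis: inside -> (-inf, inf), outside -> miss
    parallel = dirs == 0
    inside = (origins >= box_min) & (origins <= box_max)
    t0 = np.where(parallel, np.where(inside, -np.inf, np.inf), t0)
    t1 = np.where(parallel, np.where(inside, np.inf, -np.inf), t1)
    tmin = np.minimum(t0, t1).max(axis=-1)
    tmax = np.maximum(t0, t1).min(axis=-1)
    tmin = np.maximum(tmin, 0.0)
    return tmin, tmax


def default_camera(
    vol: Volume, view: str = "anterior", image_size: tuple[int, int] = (128, 128)
) -> Camera:
    """Orthographic camera facing the volume from a named direction.

    The view size is the largest physical edge of the volume (padded 5%) so
    the whole dataset is in frame.
    """
    if view not in VIEW_DIRECTIONS:
        raise ValidationError(f"unknown view {view!r}; available: {sorted(VIEW_DIRECTIONS)}")
    direction, up = VIEW_DIRECTIONS[view]
    lo, hi = vol.world_bounds()
    center = (lo + hi) / 2.0
    extent = float(np.max(hi - lo))
    distance = 2.0 * extent
    position = center - np.asarray(direction) * distance
    return Camera(
        position=tuple(position),
        view_dir=direction,
        up=up,
        projection="orthographic",
        view_size=extent * 1.05,
        image_size=image_size,
    )


def render(
    vol: Volume,
    tf: TransferFunction,
    cam: Camera | None = None,
    settings: RenderSettings | None = None,
) -> np.ndarray:
    """Ray-cast a volume to an (H, W, 4) uint8 RGBA image.

    Deterministic for fixed inputs. A camera viewing away from the volume
    yields a background-only image.
    """
    if cam is None:
        cam = default_camera(vol)
    if settings is None:
        settings = RenderSettings()

    origins, dirs = cam.rays()
    h_px, w_px = origins.shape[:2]
    origins = origins.reshape(-1, 3)
    dirs = dirs.reshape(-1, 3)
    n_rays = origins.shape[0]

    box_min, box_max = vol.world_bounds()
    t_near, t_far = _ray_box(origins, dirs, box_min, box_max)
    hit = t_far > t_near

    step = settings.sample_distance * min(vol.spacing)
    ref_step = min(vol.spacing)
    origin = np.asarray(vol.origin)
    spacing = np.asarray(vol.spacing)

    lo, hi = vol.intensity_range
    norm_scale = 255.0 / (hi - lo) if hi > lo else 0.0

    use_gradient = settings.gradient_opacity_scale > 0.0 or settings.shading
    if use_gradient:
        gfield = gradient_field(vol)
        gmag = np.linalg.norm(gfield, axis=-1)
        g_max = float(np.percentile(gmag, 98.0))
        if g_max <= 0:
            g_max = 1.0

    accum_c = np.zeros((n_rays, 3))
    accum_a = np.zeros(n_rays)
    if settings.blend_mode == "max-intensity":
        max_val = np.full(n_rays, -np.inf)

    active = hit.copy()
    t = np.where(hit, t_near + 0.5 * step, np.inf)
    mip = settings.blend_mode == "max-intensity"
    fwd = None
    while np.any(active):
        ai = np.nonzero(active)[0]
        p = origins[ai] + t[ai, None] * dirs[ai]
        keep = np.ones(len(ai), dtype=bool)
        for plane in settings.clipping_planes:
            nrm = _normalize(plane.normal)
            keep &= (p - np.asarray(plane.point)) @ nrm >= 0.0
        if np.any(keep):
            aj = ai[keep]
            pj = p[keep]
            idx = (pj - origin) / spacing
            vals = trilinear_sample(vol, idx[:, 0], idx[:, 1], idx[:, 2])
            vals = np.atleast_1d(np.asarray(vals, dtype=float))
            if mip:
                np.maximum.at(max_val, aj, vals)
            else:
                alpha = np.atleast_1d(opacity_at(tf, vals))
                color = np.atleast_2d(color_at(tf, vals))
                # scalar-opacity reference: attenuate below the reference level
                if settings.scalar_opacity_ref > 0 and norm_scale > 0:
                    nv = (vals - lo) * norm_scale
                    alpha = alpha * np.clip(nv / settings.scalar_opacity_ref, 0.0, 1.0)
                if use_gradient:
                    ci = np.clip(np.round(idx), 0, np.array(vol.dims) - 1).astype(int)
                    g = gfield[ci[:, 0], ci[:, 1], ci[:, 2]]
                    if settings.gradient_opacity_scale > 0:
                        mod = np.clip(np.linalg.norm(g, axis=-1) / g_max, 0.0, 1.0)
                        s = settings.gradient_opacity_scale
                        alpha = alpha * ((1.0 - s) + s * mod)
                    if settings.shading:
                        gn = np.linalg.norm(g, axis=-1, keepdims=True)
                        normal = np.divide(g, gn, out=np.zeros_like(g), where=gn > 0)
                        # headlight: light travels along the view direction
                        lam = np.abs(normal @ np.asarray(cam.view_dir))
                        shade = 0.2 + 0.8 * lam
                        color = color * shade[:, None]
                alpha = opacity_step_correction(alpha, step, ref_step)
                trans = 1.0 - accum_a[aj]
                accum_c[aj] += color * (alpha * trans)[:, None]
                accum_a[aj] += alpha * trans
        t[ai] += step
        active[ai] = (t[ai] < t_far[ai]) & (
            accum_a[ai] < settings.early_termination_alpha
        )

    bg = np.asarray(settings.background, dtype=float)
    if mip:
        got = np.isfinite(max_val) & (max_val > -np.inf)
        alpha = np.zeros(n_rays)
        color = np.zeros((n_rays, 3))
        if np.any(got):
            alpha[got] = np.atleast_1d(opacity_at(tf, max_val[got]))
            color[got] = np.atleast_2d(color_at(tf, max_val[got]))
        final = color * alpha[:, None] + (1.0 - alpha)[:, None] * bg
    else:
        final = accum_c + (1.0 - accum_a)[:, None] * bg

    rgba = np.empty((h_px, w_px, 4), dtype=np.uint8)
    rgba[..., :3] = np.clip(final.reshape(h_px, w_px, 3) * 255.0, 0, 255).astype(np.uint8)
    rgba[..., 3] = 255
    return rgba


def write_png(image: np.ndarray, path) -> Path:
    """Write an (H, W, 4) uint8 array as a PNG file."""
    path = Path(path)
    Image.fromarray(image, mode="RGBA").save(str(path))
    return path
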