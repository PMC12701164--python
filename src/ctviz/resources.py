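"""Simulated rendering-resource limits.

A browser-based volume renderer is constrained by the graphics context's
``MAX_3D_TEXTURE_SIZE`` and by how much heap memory can be devoted to texture
uploads (typically 75% of the heap limit, with a fixed fallback when the heap
cannot be queried). A headless pipeline has no live context to probe, so
these limits arrive through configuration and are carried by
:class:`ResourceProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = ["ResourceProfile", "upload_budget", "MIB"]

MIB = 1024 * 1024


@dataclass(frozen=True)
class ResourceProfile:
    """Resource limits governing chunking and level-of-detail decisions.

    Parameters
    ----------
    max_3d_texture_size
        Largest allowed 3D texture edge in voxels per axis.
    heap_limit_bytes
        Total heap limit in bytes, or ``None`` when unknown.
    upload_fraction
        Fraction of the heap limit available for texture uploads.
    fallback_upload_bytes
        Upload budget used when the heap limit is unknown (default 2048 MiB).
    chunk_factor
        Fraction of the texture size that bounds each chunk's depth.
    """

    max_3d_texture_size: int = 2048
    heap_limit_bytes: float | None = None
    upload_fraction: float = 0.75
    fallback_upload_bytes: float = 2048 * MIB
    chunk_factor: float = 0.25

    def __post_init__(self) -> None:
        if int(self.max_3d_texture_size) < 1:
            raise ValidationError("max_3d_texture_size must be >= 1")
        if not (0 < self.upload_fraction <= 1):
            raise ValidationError("upload_fraction must lie in (0, 1]")
        if not (0 < self.chunk_factor <= 1):
            raise ValidationError("chunk_factor must lie in (0, 1]")
        if self.heap_limit_bytes is not None and self.heap_limit_bytes <= 0:
            raise ValidationError("heap_limit_bytes must be positive when given")
        if self.fallback_upload_bytes <= 0:
            raise ValidationError("fallback_upload_bytes must be positive")

    @classmethod
    def from_config(cls, cfg: dict) -> "ResourceProfile":
        """Build a profile from config keys (heap given in MiB)."""
        kwargs = {}
        if "max_texture_size" in cfg:
            kwargs["max_3d_texture_size"] = int(cfg["max_texture_size"])
        if cfg.get("heap_mb") is not None:
            kwargs["heap_limit_bytes"] = float(cfg["heap_mb"]) * MIB
        if "upload_fraction" in cfg:
            kwargs["upload_fraction"] = float(cfg["upload_fraction"])
        if "fallback_mb" in cfg:
            kwargs["fallback_upload_bytes"] = float(cfg["fallback_mb"]) * MIB
        if "chunk_factor" in cfg:
            kwargs["chunk_factor"] = float(cfg["chunk_factor"])
        return cls(**kwargs)


def upload_budget(profile: ResourceProfile) -> float:
    """Bytes available for uploading volume data.

    ``upload_fraction × heap_limit_bytes`` when the heap limit is known,
    otherwise the configured fallback. Monotone nondecreasing in both the
    heap limit and the fraction.
    """
    if profile.heap_limit_bytes is None:
        budget = float(profile.fallback_upload_bytes)
    else:
        budget = profile.upload_fraction * float(profile.heap_limit_bytes)
    if budget <= 0:
        raise ValidationError(f"non-positive upload budget {budget}")
    return budget
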