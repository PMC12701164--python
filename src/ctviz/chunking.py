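"""Depth-axis partitioning and streaming of CT volumes.

A volume too large to upload at once is split along the slice axis into
chunks whose depth is bounded both by a fraction of the maximum 3D texture
size and by half the upload-memory budget:

    chunkSize   = min(floor(maxTex × chunkFactor), floor(budget / 2))
    totalChunks = ceil(depth / chunkSize)

Chunks carry half-open depth ranges ``[z0, z1)`` that tile ``[0, depth)``
exactly, so recombination (summing the individual chunk depths) is a
bit-exact inverse of the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import BudgetError, ValidationError
from .resources import ResourceProfile, upload_budget
from .volume_io import Volume

__all__ = [
    "ChunkPlan",
    "Chunk",
    "compute_chunk_size",
    "compute_total_chunks",
    "make_chunk_plan",
    "split_volume",
    "stream_chunks",
    "combine_chunks",
]


@dataclass(frozen=True)
class ChunkPlan:
    """Partition of ``[0, depth)`` into consecutive half-open slabs."""

    chunk_size: int
    ranges: tuple[tuple[int, int], ...]

    @property
    def total_chunks(self) -> int:
        return len(self.ranges)

    @property
    def depth(self) -> int:
        return self.ranges[-1][1] if self.ranges else 0


@dataclass
class Chunk:
    """One slab of a parent volume: voxel (x, y, z) equals parent (x, y, z_start + z)."""

    volume: Volume
    z_start: int
    z_end: int
    index: int

    @property
    def depth(self) -> int:
        return self.z_end - self.z_start


def compute_chunk_size(
    profile: ResourceProfile,
    *,
    bytes_per_slice: int | None = None,
    budget_in_slices: bool = False,
) -> int:
    """Slices per chunk for a given resource profile.

    Default form takes the two operands exactly as written above. With
    ``budget_in_slices=True`` the byte budget is first converted to slices
    via ``bytes_per_slice`` so both min() operands share units.
    """
    texture_term = math.floor(profile.max_3d_texture_size * profile.chunk_factor)
    budget = upload_budget(profile)
    if budget_in_slices:
        if not bytes_per_slice or bytes_per_slice <= 0:
            raise ValidationError("budget_in_slices requires a positive bytes_per_slice")
        budget_term = math.floor(budget / 2 / bytes_per_slice)
    else:
        budget_term = math.floor(budget / 2)
    size = min(texture_term, budget_term)
    if size < 1:
        raise BudgetError(
            f"resource budget too small for even one slice per chunk "
            f"(texture term {texture_term}, budget term {budget_term})"
        )
    return int(size)


def compute_total_chunks(depth: int, chunk_size: int) -> int:
    """Number of chunks needed: ceil(depth / chunk_size)."""
    if depth < 1 or chunk_size < 1:
        raise ValidationError("depth and chunk_size must be >= 1")
    return -(-depth // chunk_size)


def make_chunk_plan(depth: int, chunk_size: int) -> ChunkPlan:
    """Tile ``[0, depth)`` with slabs of ``chunk_size`` slices (last may be shorter)."""
    n = compute_total_chunks(depth, chunk_size)
    ranges = tuple(
        (i * chunk_size, min((i + 1) * chunk_size, depth)) for i in range(n)
    )
    return ChunkPlan(chunk_size=chunk_size, ranges=ranges)


def _check_plan(vol: Volume, plan: ChunkPlan) -> None:
    depth = vol.dims[2]
    if not plan.ranges:
        raise ValidationError("empty chunk plan")
    expected = 0
    for z0, z1 in plan.ranges:
        if z0 != expected or z1 <= z0:
            raise ValidationError(f"chunk plan ranges do not tile [0, {depth}): {plan.ranges}")
        if z1 - z0 > plan.chunk_size:
            raise ValidationError("chunk range longer than plan chunk_size")
        expected = z1
    if expected != depth:
        raise ValidationError(
            f"chunk plan covers [0, {expected}) but volume depth is {depth}"
        )


def split_volume(vol: Volume, plan: ChunkPlan) -> list[Chunk]:
    """Cut a volume into depth-order chunks per the plan.

    Chunks inherit spacing; each chunk's origin is offset along z by
    ``z0 × sz`` so world coordinates are preserved.
    """
    _check_plan(vol, plan)
    ox, oy, oz = vol.origin
    sz = vol.spacing[2]
    chunks = []
    for i, (z0, z1) in enumerate(plan.ranges):
        sub = Volume(
            data=vol.data[:, :, z0:z1],
            spacing=vol.spacing,
            origin=(ox, oy, oz + z0 * sz),
        )
        chunks.append(Chunk(volume=sub, z_start=z0, z_end=z1, index=i))
    return chunks


def stream_chunks(
    vol: Volume, plan: ChunkPlan, budget: float
) -> Iterator[tuple[Chunk, int]]:
    """Yield ``(chunk, used_bytes)`` one chunk at a time.

    ``used_bytes`` is the cumulative payload byte count of all chunks
    materialised so far, mirroring per-chunk heap-usage reporting. A single
    chunk larger than ``budget`` aborts with :class:`BudgetError`.
    """
    if budget <= 0:
        raise ValidationError("budget must be positive")
    _check_plan(vol, plan)
    ox, oy, oz = vol.origin
    sz = vol.spacing[2]
    used = 0
    for i, (z0, z1) in enumerate(plan.ranges):
        sub = Volume(
            data=np.ascontiguousarray(vol.data[:, :, z0:z1]),
            spacing=vol.spacing,
            origin=(ox, oy, oz + z0 * sz),
        )
        if sub.nbytes > budget:
            raise BudgetError(
                f"chunk {i} needs {sub.nbytes} bytes, exceeding the {budget:.0f}-byte budget"
            )
        used += sub.nbytes
        yield Chunk(volume=sub, z_start=z0, z_end=z1, index=i), used


def combine_chunks(chunks: Sequence[Chunk]) -> Volume:
    """Concatenate contiguous chunks back into one volume.

    The combined depth is the sum of the individual chunk depths; width,
    height and spacing must agree across chunks and the depth ranges must be
    consecutive without gap or overlap. ``combine(split(v)) == v`` bit-exactly.
    """
    if not chunks:
        raise ValidationError("no chunks to combine")
    first = chunks[0].volume
    w, h = first.dims[0], first.dims[1]
    expected = chunks[0].z_start
    if expected != 0:
        raise ValidationError(f"first chunk starts at z={expected}, expected 0")
    for c in chunks:
        cw, ch, cd = c.volume.dims
        if (cw, ch) != (w, h):
            raise ValidationError(
                f"chunk {c.index} has in-plane dims {(cw, ch)}, expected {(w, h)}"
            )
        if c.volume.spacing != first.spacing:
            raise ValidationError(f"chunk {c.index} spacing {c.volume.spacing} != {first.spacing}")
        if c.z_start != expected:
            raise ValidationError(
                f"chunk ranges not contiguous: chunk {c.index} starts at "
                f"{c.z_start}, expected {expected}"
            )
        if cd != c.depth:
            raise ValidationError(f"chunk {c.index} data depth {cd} != range depth {c.depth}")
        expected = c.z_end
    data = np.concatenate([c.volume.data for c in chunks], axis=2)
    return Volume(data=data, spacing=first.spacing, origin=first.origin)
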