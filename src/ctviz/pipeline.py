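"""End-to-end preprocessing pipeline.

Orchestrates: read volume → compute chunk size and count → stream chunks
under the upload budget → recombine → level-of-detail decision (and
trilinear downsampling when needed) → optional conversion/rendering.
The report echoes the outputs of the individual stage functions verbatim;
nothing is re-derived.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import chunking, lod, volume_io
from .errors import VolumeIOError
from .resources import ResourceProfile, upload_budget
from .volume_io import Volume

__all__ = ["PipelineReport", "read_volume_auto", "run_pipeline"]

log = logging.getLogger("ctviz.pipeline")


@dataclass
class PipelineReport:
    input_path: str
    input_dims: tuple[int, int, int]
    input_spacing: tuple[float, float, float]
    profile: dict
    upload_budget_bytes: float
    chunk_size: int
    total_chunks: int
    chunk_ranges: list[tuple[int, int]]
    per_chunk_bytes: list[int]
    used_bytes: list[int]
    lod: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def read_volume_auto(path) -> Volume:
    """Dispatch on path type/suffix: DICOM directory, NIfTI or .vti file."""
    path = Path(path)
    if path.is_dir():
        return volume_io.read_dicom_series(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return volume_io.read_nifti(path)
    if name.endswith(".vti"):
        return volume_io.read_vti(path)
    raise VolumeIOError(f"unrecognised volume input: {path}")


def run_pipeline(
    input_path,
    profile: ResourceProfile,
    *,
    vti_out=None,
    nifti_out=None,
) -> tuple[Volume, PipelineReport]:
    """Run ingest → chunk stream → combine → LOD on one volume.

    Returns the render-ready volume (downsampled when the combined data
    exceeded the texture target, otherwise the combined original) and a
    report assembled from the stage outputs.
    """
    vol = read_volume_auto(input_path)
    log.info("read %s: dims=%s spacing=%s", input_path, vol.dims, vol.spacing)

    budget = upload_budget(profile)
    chunk_size = chunking.compute_chunk_size(profile)
    depth = vol.dims[2]
    total = chunking.compute_total_chunks(depth, chunk_size)
    plan = chunking.make_chunk_plan(depth, chunk_size)

    chunks = []
    per_chunk = []
    used = []
    for chunk, used_bytes in chunking.stream_chunks(vol, plan, budget):
        log.info(
            "Processed Chunks (%d/%d) — used bytes %d",
            chunk.index + 1,
            total,
            used_bytes,
        )
        chunks.append(chunk)
        per_chunk.append(chunk.volume.nbytes)
        used.append(used_bytes)
    combined = chunking.combine_chunks(chunks)

    result = lod.apply_lod(combined, profile)
    out_vol = result.volume
    log.info(
        "LOD applied=%s maxFactor=%.4f dims_out=%s",
        result.applied,
        result.max_factor,
        out_vol.dims,
    )

    outputs = []
    if vti_out is not None:
        outputs.append(str(volume_io.write_vti(out_vol, vti_out)))
    if nifti_out is not None:
        outputs.append(str(volume_io.write_nifti(out_vol, nifti_out)))

    report = PipelineReport(
        input_path=str(input_path),
        input_dims=vol.dims,
        input_spacing=vol.spacing,
        profile={
            "max_3d_texture_size": profile.max_3d_texture_size,
            "heap_limit_bytes": profile.heap_limit_bytes,
            "upload_fraction": profile.upload_fraction,
            "fallback_upload_bytes": profile.fallback_upload_bytes,
            "chunk_factor": profile.chunk_factor,
        },
        upload_budget_bytes=budget,
        chunk_size=chunk_size,
        total_chunks=total,
        chunk_ranges=[tuple(r) for r in plan.ranges],
        per_chunk_bytes=per_chunk,
        used_bytes=used,
        lod={
            "applied": result.applied,
            "max_factor": result.max_factor,
            "target_max_dimension": result.target_max_dimension,
            "dims_in": combined.dims,
            "dims_out": out_vol.dims,
            "spacing_out": out_vol.spacing,
        },
        outputs=outputs,
    )
    return out_vol, report
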