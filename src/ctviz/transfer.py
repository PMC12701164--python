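"""Intensity histograms and transfer functions.

The transfer function maps voxel intensity υ to an opacity and a colour:

    α(υ) = Σᵢ wᵢ · exp(−(υ − υᵢ)² / (2σᵢ²))       (clamped to [0, 1])
    c(υ) = piecewise-linear interpolation between sorted colour nodes

The Gaussian opacity kernel carries no normalisation constant, so each
node's peak height equals its weight — weights read directly as maximum
opacities. The colour map is mathematically the hat-kernel sum
Σᵢ cᵢ L(υ − υᵢ) over the node positions, evaluated as ordinary linear
interpolation with end-clamping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .volume_io import Volume

__all__ = [
    "GaussianNode",
    "ColorNode",
    "TransferFunction",
    "Histogram",
    "histogram",
    "opacity_at",
    "color_at",
    "preset_tf",
    "PRESETS",
]


@dataclass(frozen=True)
class GaussianNode:
    """One opacity bump: peak ``weight`` at ``center``, Gaussian width ``sigma``."""

    center: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if not (0 <= self.weight <= 1):
            raise ValidationError(f"weight must lie in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class ColorNode:
    """An RGB anchor at one intensity position; channels in [0, 1]."""

    position: float
    rgb: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.rgb) != 3 or any(not (0 <= c <= 1) for c in self.rgb):
            raise ValidationError(f"rgb channels must lie in [0, 1], got {self.rgb}")


@dataclass(frozen=True)
class TransferFunction:
    """Gaussian-mixture opacity plus piecewise-linear colour over an intensity domain."""

    opacity_nodes: tuple[GaussianNode, ...]
    color_nodes: tuple[ColorNode, ...]
    domain: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "opacity_nodes", tuple(self.opacity_nodes))
        object.__setattr__(self, "color_nodes", tuple(self.color_nodes))
        if len(self.color_nodes) < 2:
            raise ValidationError("at least 2 colour nodes are required")
        positions = [n.position for n in self.color_nodes]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValidationError(f"colour node positions must strictly increase: {positions}")

    def to_dict(self) -> dict:
        return {
            "opacity": [
                {"center": n.center, "width": n.sigma, "weight": n.weight}
                for n in self.opacity_nodes
            ],
            "color": [
                {"position": n.position, "rgb": list(n.rgb)} for n in self.color_nodes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunction":
        return cls(
            opacity_nodes=tuple(
                GaussianNode(float(n["center"]), float(n["width"]), float(n["weight"]))
                for n in d.get("opacity", [])
            ),
            color_nodes=tuple(
                ColorNode(float(n["position"]), tuple(float(c) for c in n["rgb"]))
                for n in d.get("color", [])
            ),
        )

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "TransferFunction":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Histogram:
    """Equal-width intensity histogram; Σ counts equals the source voxel count."""

    bin_edges: np.ndarray
    counts: np.ndarray


def histogram(vol: Volume, n_bins: int) -> Histogram:
    """Histogram of voxel intensities over the volume's intensity range.

    A degenerate range (min == max) yields a single bin holding every voxel.
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    lo, hi = vol.intensity_range
    if lo == hi:
        edges = np.array([lo - 0.5, hi + 0.5])
        counts = np.array([vol.data.size], dtype=np.int64)
        return Histogram(bin_edges=edges, counts=counts)
    counts, edges = np.histogram(vol.data, bins=n_bins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts.astype(np.int64))


def opacity_at(tf: TransferFunction, v):
    """Gaussian-mixture opacity α(υ), clamped to [0, 1]. Vectorised over υ."""
    v = np.asarray(v, dtype=float)
    total = np.zeros(v.shape)
    for n in tf.opacity_nodes:
        total += n.weight * np.exp(-((v - n.center) ** 2) / (2.0 * n.sigma**2))
    out = np.clip(total, 0.0, 1.0)
    return float(out) if out.shape == () else out


def color_at(tf: TransferFunction, v):
    """Piecewise-linear colour c(υ); end colours clamp outside the node range.

    Vectorised: scalar υ returns an RGB tuple, an array returns shape (..., 3).
    """
    v = np.asarray(v, dtype=float)
    positions = np.array([n.position for n in tf.color_nodes])
    channels = np.array([n.rgb for n in tf.color_nodes])  # (n, 3)
    out = np.stack(
        [np.interp(v, positions, channels[:, k]) for k in range(3)], axis=-1
    )
    if v.shape == ():
        return tuple(float(c) for c in out)
    return out


# Preset node tables: artifact-defined anchor points on the Hounsfield scale
# (air ≈ −1000 HU, soft tissue ≈ 40 HU, contrast-filled arteries ≈ 300–500 HU,
# cortical bone ≳ 1000 HU).
PRESETS: dict[str, dict] = {
    # contrast-enhanced vasculature: arteries bright red, bone white, air/soft transparent
    "ct-vascular": {
        "opacity": [
            {"center": 400.0, "width": 140.0, "weight": 0.75},
            {"center": 1200.0, "width": 300.0, "weight": 0.9},
        ],
        "color": [
            {"position": -1000.0, "rgb": [0.0, 0.0, 0.0]},
            {"position": 0.0, "rgb": [0.3, 0.1, 0.1]},
            {"position": 400.0, "rgb": [0.9, 0.15, 0.1]},
            {"position": 1000.0, "rgb": [0.95, 0.9, 0.85]},
            {"position": 2000.0, "rgb": [1.0, 1.0, 1.0]},
        ],
    },
    # skeletal structures: only dense bone opaque
    "ct-bone": {
        "opacity": [
            {"center": 1300.0, "width": 450.0, "weight": 0.95},
        ],
        "color": [
            {"position": -1000.0, "rgb": [0.0, 0.0, 0.0]},
            {"position": 300.0, "rgb": [0.6, 0.5, 0.35]},
            {"position": 1200.0, "rgb": [0.95, 0.95, 0.9]},
            {"position": 2500.0, "rgb": [1.0, 1.0, 1.0]},
        ],
    },
    # soft tissue window: faint muscle/fat, semi-opaque organs
    "ct-soft": {
        "opacity": [
            {"center": 40.0, "width": 120.0, "weight": 0.35},
            {"center": 1300.0, "width": 350.0, "weight": 0.6},
        ],
        "color": [
            {"position": -1000.0, "rgb": [0.0, 0.0, 0.0]},
            {"position": -100.0, "rgb": [0.8, 0.7, 0.45]},
            {"position": 80.0, "rgb": [0.8, 0.4, 0.35]},
            {"position": 1500.0, "rgb": [1.0, 1.0, 1.0]},
        ],
    },
}


def preset_tf(name: str) -> TransferFunction:
    """Named transfer-function preset on the Hounsfield scale.

    Available: ``ct-vascular``, ``ct-bone``, ``ct-soft``. Each keeps air
    (−1000 HU) essentially transparent and makes contrast/bone opaque.
    """
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return TransferFunction.from_dict(PRESETS[name])
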