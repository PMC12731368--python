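"""Per-material path integrals and Beer-Lambert transmissions.

The production tracer computes exact per-voxel intersection lengths with an
incremental (Siddon-type) traversal; :func:`trace_dense` is a deliberately
simple fixed-step midpoint sampler retained as an independent reference for
testing the exact tracer.  Transmissions follow T = exp(-sum_m (mu/rho)_m *
(integral rho dx)_m) with areal densities in g/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import siddon_areal
from .physics_tables import AttenuationTable, Material, default_attenuation_table
from .voxel_model import MaterialVolume

__all__ = ["Ray", "PathIntegral", "trace", "trace_dense", "transmission"]


@dataclass(frozen=True)
class Ray:
    """A finite line segment in world coordinates (mm)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]

    def __post_init__(self):
        s = np.asarray(self.start, dtype=float)
        e = np.asarray(self.end, dtype=float)
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(e))):
            raise ValueError("ray endpoints must be finite")
        if np.allclose(s, e):
            raise ValueError("degenerate zero-length ray")
        object.__setattr__(self, "start", tuple(map(float, s)))
        object.__setattr__(self, "end", tuple(map(float, e)))


@dataclass
class PathIntegral:
    """Per-material areal densities (g/cm^2) and lengths (cm) along a segment."""

    materials: tuple[Material, ...]
    areal_density: np.ndarray   # g/cm^2 per material class
    lengths: np.ndarray         # cm per material class
    total_length: float         # cm of in-grid chord

    def __post_init__(self):
        if np.any(self.areal_density < 0):
            raise ValueError("areal densities must be non-negative")

    def split_consistent(self) -> bool:
        return abs(self.lengths.sum() - self.total_length) <= 1e-9 * max(self.total_length, 1.0)


def trace(volume: MaterialVolume, ray: Ray) -> PathIntegral:
    """Exact per-material path integral of a ray through a material volume."""
    p0 = np.asarray(ray.start, dtype=float)
    p1 = np.asarray(ray.end, dtype=float)
    areal = np.zeros(volume.n_materials)
    lengths = np.zeros(volume.n_materials)
    total = siddon_areal(volume.labels, volume.density,
                         *volume.spacing, *volume.origin, p0, p1, areal, lengths)
    return PathIntegral(volume.materials, areal, lengths, float(total))


def trace_dense(volume: MaterialVolume, ray: Ray, step_mm: float | None = None) -> PathIntegral:
    """Reference midpoint-rule sampler (independent oracle for :func:`trace`).

    Samples the segment at ``step_mm`` intervals (default min(spacing)/100) and
    attributes each sample's step length to the material of the containing
    voxel.  Accurate to O(step) at material boundaries; never used in
    production paths.
    """
    if step_mm is None:
        step_mm = min(volume.spacing) / 100.0
    p0 = np.asarray(ray.start, dtype=float)
    p1 = np.asarray(ray.end, dtype=float)
    length_mm = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length_mm / step_mm)), 1)
    t = (np.arange(n) + 0.5) / n
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    sp = np.array(volume.spacing)
    b0 = np.array(volume.origin) - sp / 2
    idx = np.floor((pts - b0) / sp).astype(np.int64)
    inside = np.all((idx >= 0) & (idx < np.array(volume.shape)), axis=1)
    idx = idx[inside]
    seg_cm = (length_mm / n) * 0.1
    areal = np.zeros(volume.n_materials)
    lengths = np.zeros(volume.n_materials)
    if len(idx):
        labels = volume.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        rho = volume.density[idx[:, 0], idx[:, 1], idx[:, 2]]
        areal = np.bincount(labels, weights=rho * seg_cm, minlength=volume.n_materials)
        lengths = np.bincount(labels, minlength=volume.n_materials).astype(float) * seg_cm
    return PathIntegral(volume.materials, areal, lengths, float(lengths.sum()))


def transmission(path: PathIntegral, energy: float,
                 table: AttenuationTable | None = None) -> float:
    """Beer-Lambert transmission of a path integral at one photon energy (keV)."""
    table = table or default_attenuation_table()
    tau = 0.0
    for mat, ad in zip(path.materials, path.areal_density):
        if ad > 0:
            tau += table.material_mu_rho(mat, energy) * ad
    return float(np.exp(-tau))
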