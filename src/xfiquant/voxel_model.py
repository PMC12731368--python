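"""HU-based material segmentation of CT volumes.

A CT volume (Hounsfield Units on a regular grid) is classified voxel-wise into
material classes using ordered half-open HU intervals [low, high); values
outside the configured domain clamp to the nearest class so classification is
total and deterministic.  The result is a :class:`MaterialVolume` carrying a
per-voxel material label and mass density - the substrate for all path
integrals.

Coordinate convention: 0-based voxel indices; the world position of voxel
(i, j, k) center is ``origin + (i*dx, j*dy, k*dz)`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .physics_tables import Material, get_material, default_hu_ranges

__all__ = [
    "CTVolume",
    "HURangeTable",
    "MaterialVolume",
    "default_hu_table",
    "classify_hu",
    "build_material_map",
    "isolate_bone",
]


@dataclass
class CTVolume:
    """3-D Hounsfield-Unit grid with physical geometry (spacing/origin in mm)."""

    hu: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3 or self.hu.size == 0:
            raise ValueError("CT volume must be a non-empty 3-D array")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("CT volume contains non-finite HU values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the voxel-box hull in world mm."""
        sp = np.array(self.spacing)
        org = np.array(self.origin)
        return org - sp / 2, org + (np.array(self.shape) - 0.5) * sp


class HURangeTable:
    """Ordered, non-overlapping half-open HU intervals mapping to materials."""

    def __init__(self, ranges: Sequence[tuple[float, float, str | Material]]):
        if not ranges:
            raise ValueError("HU range table is empty")
        entries = sorted(((float(lo), float(hi), get_material(m)) for lo, hi, m in ranges),
                         key=lambda r: r[0])
        for (lo, hi, _) in entries:
            if hi <= lo:
                raise ValueError(f"invalid HU interval [{lo}, {hi})")
        for (_, hi_prev, _), (lo, _, _) in zip(entries, entries[1:]):
            if lo < hi_prev:
                raise ValueError("HU intervals overlap")
            if lo > hi_prev:
                raise ValueError("HU intervals leave a gap in the configured domain")
        self.entries = entries
        self.materials: tuple[Material, ...] = tuple(m for _, _, m in entries)
        self._edges = np.array([lo for lo, _, _ in entries[1:]])

    def classify_index(self, hu) -> np.ndarray:
        """Index of the material class for each HU value (clamped outside domain)."""
        return np.searchsorted(self._edges, np.asarray(hu, dtype=float), side="right")

    def midpoints(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi, _ in self.entries])

    def interval(self, material_name: str) -> tuple[float, float]:
        for lo, hi, m in self.entries:
            if m.name == material_name:
                return lo, hi
        raise KeyError(material_name)


def default_hu_table() -> HURangeTable:
    """The five-class air/paraffin/adipose/soft-tissue/bone default table."""
    return HURangeTable(default_hu_ranges())


def classify_hu(hu, table: HURangeTable | None = None):
    """Material for an HU value (or array of values): total under clamping."""
    table = table or default_hu_table()
    idx = table.classify_index(hu)
    if np.ndim(hu) == 0:
        return table.materials[int(idx)]
    return np.array([m.name for m in table.materials], dtype=object)[idx]


@dataclass
class MaterialVolume:
    """Per-voxel material label + density volume sharing the CT geometry."""

    labels: np.ndarray               # int8 indices into `materials`
    density: np.ndarray              # g/cm^3
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    materials: tuple[Material, ...]  # index order

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        if self.labels.shape != self.density.shape or self.labels.ndim != 3:
            raise ValueError("labels and density must be equal-shape 3-D arrays")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_materials(self) -> int:
        return len(self.materials)

    def label_index(self, name: str) -> int:
        for i, m in enumerate(self.materials):
            if m.name == name:
                return i
        raise KeyError(f"material {name!r} not present in this volume")

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        sp = np.array(self.spacing)
        org = np.array(self.origin)
        return org - sp / 2, org + (np.array(self.shape) - 0.5) * sp

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]


def _hu_linear_density(hu: np.ndarray) -> np.ndarray:
    # piecewise-linear HU->density through (-1000, 0.0012), (0, 1.0), (2000, 1.85)
    rho = np.where(hu < 0, 1.0 + hu * (1.0 - 0.0012) / 1000.0,
                   1.0 + hu * 0.85 / 2000.0)
    return np.clip(rho, 0.0012, None)


def build_material_map(ct: CTVolume, table: HURangeTable | None = None,
                       density_mode: str = "nominal") -> MaterialVolume:
    """Classify every voxel of a CT volume into a material + density volume.

    density_mode "nominal" assigns each class its nominal density (the
    material-class correction used throughout); "hu_linear" instead maps HU to
    density with a piecewise-linear calibration, for sensitivity studies.
    """
    table = table or default_hu_table()
    idx = table.classify_index(ct.hu).astype(np.int8)
    if density_mode == "nominal":
        nominal = np.array([m.nominal_density for m in table.materials])
        density = nominal[idx]
    elif density_mode == "hu_linear":
        density = _hu_linear_density(np.asarray(ct.hu, dtype=float))
    else:
        raise ValueError(f"unknown density_mode {density_mode!r}")
    return MaterialVolume(idx, density, ct.spacing, ct.origin, table.materials)


def isolate_bone(ct: CTVolume, table: HURangeTable | None = None,
                 largest_component: bool = False) -> np.ndarray:
    """Binary mask of cortical-bone voxels (optionally the largest 26-connected blob)."""
    table = table or default_hu_table()
    idx = table.classify_index(ct.hu)
    bone = next((i for i, m in enumerate(table.materials) if m.name == "cortical_bone"), None)
    if bone is None:
        raise KeyError("HU table has no 'cortical_bone' class")
    mask = idx == bone
    if largest_component and mask.any():
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask
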