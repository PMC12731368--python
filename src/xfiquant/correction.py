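"""Per-scan-point attenuation correction factors (kappa).

For every raster position the excitation beam (treated as its central axis,
entering the volume along +z) defines a set of candidate fluorescence origins:
the sample voxels it intersects.  Each origin is weighted by the excitation
transmission to it times its intersected length (fluorescence production is
proportional to the photons surviving to that depth, uniform per unit length).
The correction factor per detector is the inverse of the origin-averaged
combined (excitation x emission) transmission,

    kappa_d = 1 / sum_o w_o T_exc(o) T_emis(o, d),        sum_o w_o = 1,

and the detector-combined kappa averages over detectors with weights
proportional to solid angle x intrinsic efficiency.  Detector efficiency only
enters the inter-detector weights and the separately reported geometric
acceptance G, never kappa itself, so kappa = 1 holds exactly in vacuum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import emission_tau_batch
from .physics_tables import (AttenuationTable, default_attenuation_table,
                             get_material, line_energy)
from .voxel_model import MaterialVolume

__all__ = [
    "DetectorGeometry",
    "ScanGeometry",
    "CorrectionMap",
    "candidate_origins",
    "combined_transmission",
    "correction_factor",
    "correction_map",
    "beamline_detectors",
    "compact_detectors",
]

SAMPLE_MATERIALS = ("soft_tissue", "adipose", "cortical_bone")

# candidate-origin material classes per analyte: the averaging over potential
# fluorescence origins should only cover voxels that can actually carry the
# element (nanoparticles distribute in tissue, strontium sits in bone)
ELEMENT_ORIGINS = {
    "Au": ("soft_tissue", "adipose"),
    "Sr": ("cortical_bone",),
}


@dataclass(frozen=True)
class DetectorGeometry:
    """An energy-dispersive detector: position, aperture and stack thicknesses."""

    label: str
    position: tuple[float, float, float]      # world mm
    active_area_mm2: float = 50.0
    be_window_um: float = 12.5
    si_chip_mm: float = 1.0

    def __post_init__(self):
        if self.active_area_mm2 <= 0:
            raise ValueError("active area must be positive")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))

    @classmethod
    def at_angle(cls, label: str, angle_deg: float, distance_cm: float,
                 center=(0.0, 0.0, 0.0), plane: str = "xz", **kw) -> "DetectorGeometry":
        """Place a detector at `angle_deg` from the +z beam axis.

        ``plane`` selects the plane containing the beam axis: "xz" (horizontal,
        default) or "yz" (vertical).
        """
        if distance_cm <= 0:
            raise ValueError("detector distance must be positive")
        a = math.radians(angle_deg)
        if plane == "xz":
            u = np.array([math.sin(a), 0.0, math.cos(a)])
        elif plane == "yz":
            u = np.array([0.0, math.sin(a), math.cos(a)])
        else:
            raise ValueError("plane must be 'xz' or 'yz'")
        pos = np.asarray(center, dtype=float) + 10.0 * distance_cm * u
        return cls(label, tuple(pos), **kw)

    def intrinsic_efficiency(self, energy_kev: float,
                             table: AttenuationTable | None = None) -> float:
        """Be-window transmission times Si-chip absorption probability."""
        table = table or default_attenuation_table()
        be = get_material("beryllium")
        si = get_material("silicon")
        t_be = math.exp(-table.material_mu_rho(be, energy_kev)
                        * be.nominal_density * self.be_window_um * 1e-4)
        t_si = math.exp(-table.material_mu_rho(si, energy_kev)
                        * si.nominal_density * self.si_chip_mm * 0.1)
        return t_be * (1.0 - t_si)


def compact_detectors(center=(0.0, 0.0, 0.0), distance_cm: float = 4.0):
    """Four detectors on a perpendicular ring around the beam (compact layout).

    All four sit at 90 degrees to the beam axis (+/-x and +/-y), the
    scatter-minimum placement; emission paths to them do not depend on the
    fluorescence depth along the beam, which keeps the candidate-origin
    averaged correction well-conditioned.
    """
    return [DetectorGeometry.at_angle("det+x", 90, distance_cm, center, "xz"),
            DetectorGeometry.at_angle("det-x", -90, distance_cm, center, "xz"),
            DetectorGeometry.at_angle("det+y", 90, distance_cm, center, "yz"),
            DetectorGeometry.at_angle("det-y", -90, distance_cm, center, "yz")]


def beamline_detectors(center=(0.0, 0.0, 0.0), distance_cm: float = 6.0):
    """Ten detectors on a nominal +/-70..150 degree ring (beamline layout)."""
    return [DetectorGeometry.at_angle(f"det{a:+d}", a, distance_cm, center)
            for a in (70, -70, 90, -90, 110, -110, 130, -130, 150, -150)]


@dataclass
class ScanGeometry:
    """Raster-scan description: beam positions, energy, flux and aperture.

    The beam axis is +z; the beam enters from the low-z side.  ``x_mm`` and
    ``y_mm`` are the raster grid center coordinates (world frame, mm).
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    beam_energy_kev: float
    beam_area_mm2: float
    flux_ph_s: float
    dwell_s: float
    beam_profile: str = "square"
    step_mm: tuple[float, float] | None = None

    def __post_init__(self):
        self.x_mm = np.atleast_1d(np.asarray(self.x_mm, dtype=float))
        self.y_mm = np.atleast_1d(np.asarray(self.y_mm, dtype=float))
        if self.beam_energy_kev <= 0 or self.beam_area_mm2 <= 0:
            raise ValueError("beam energy and area must be positive")
        if self.flux_ph_s < 0 or self.dwell_s <= 0:
            raise ValueError("flux must be >= 0 and dwell > 0")
        if self.step_mm is None:
            sx = float(np.diff(self.x_mm).mean()) if len(self.x_mm) > 1 else math.sqrt(self.beam_area_mm2)
            sy = float(np.diff(self.y_mm).mean()) if len(self.y_mm) > 1 else math.sqrt(self.beam_area_mm2)
            self.step_mm = (sx, sy)

    @property
    def n0(self) -> float:
        """Incident photons per scan point (flux x dwell)."""
        return self.flux_ph_s * self.dwell_s

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.y_mm), len(self.x_mm)

    @property
    def beam_area_cm2(self) -> float:
        return self.beam_area_mm2 * 0.01

    @classmethod
    def raster(cls, extent_x_mm, extent_y_mm, nx, ny, **kw):
        """Centered nx x ny raster covering the given extents."""
        x = (np.arange(nx) - (nx - 1) / 2) * (extent_x_mm / nx)
        y = (np.arange(ny) - (ny - 1) / 2) * (extent_y_mm / ny)
        return cls(x, y, step_mm=(extent_x_mm / nx, extent_y_mm / ny), **kw)


def beamline_scan(extent_x_mm, extent_y_mm, **overrides) -> ScanGeometry:
    """Synchrotron-side defaults: 53 keV, 1x1 mm square beam, 1 mm step, 30 s."""
    step = overrides.pop("step_mm", 1.0)
    nx = max(int(round(extent_x_mm / step)), 1)
    ny = max(int(round(extent_y_mm / step)), 1)
    kw = dict(beam_energy_kev=53.0, beam_area_mm2=1.0, flux_ph_s=4.79e8,
              dwell_s=30.0, beam_profile="square")
    kw.update(overrides)
    return ScanGeometry.raster(extent_x_mm, extent_y_mm, nx, ny, **kw)


def compact_scan(extent_x_mm, extent_y_mm, **overrides) -> ScanGeometry:
    """Compact-system defaults: 59 keV, 0.65x0.6 mm beam, 0.6 mm step, 40 s."""
    step = overrides.pop("step_mm", 0.6)
    nx = max(int(round(extent_x_mm / step)), 1)
    ny = max(int(round(extent_y_mm / step)), 1)
    kw = dict(beam_energy_kev=59.0, beam_area_mm2=0.65 * 0.6, flux_ph_s=3.84e8,
              dwell_s=40.0, beam_profile="gaussian")
    kw.update(overrides)
    return ScanGeometry.raster(extent_x_mm, extent_y_mm, nx, ny, **kw)


@dataclass
class CorrectionMap:
    """kappa and companion maps on the raster grid (row = y, column = x)."""

    kappa: np.ndarray                 # (ny, nx) detector-combined
    kappa_det: np.ndarray             # (ndet, ny, nx)
    mean_transmission: np.ndarray     # (ny, nx) combined-weighted mean T
    geom: np.ndarray                  # (ny, nx) total geometric acceptance G
    geom_det: np.ndarray              # (ndet, ny, nx)
    emission_energy: float
    detector_labels: tuple[str, ...]
    n_origins: np.ndarray = None      # (ny, nx) candidate origins per column

    def to_tsv(self, path, which: str = "kappa"):
        arr = getattr(self, which)
        header = (f"# {which} map, emission energy {self.emission_energy} keV\n"
                  f"# rows = raster y, columns = raster x\n")
        with open(path, "w") as f:
            f.write(header)
            np.savetxt(f, np.atleast_2d(arr), delimiter="\t", fmt="%.8g")


def _beam_column_tau(volume: MaterialVolume, x: float, y: float,
                     mu_rho_mat: np.ndarray):
    """Segments and mid-voxel excitation optical depth of the +z beam column.

    Returns (k indices, segment lengths cm, tau at segment midpoints, (i, j))
    or None when the column misses the grid laterally.  Exact for the
    axis-aligned beam used throughout.
    """
    b0, b1 = volume.world_bounds()
    if not (b0[0] <= x < b1[0] and b0[1] <= y < b1[1]):
        return None
    i = min(int((x - b0[0]) / volume.spacing[0]), volume.shape[0] - 1)
    j = min(int((y - b0[1]) / volume.spacing[1]), volume.shape[1] - 1)
    labels = volume.labels[i, j, :]
    rho = volume.density[i, j, :]
    seg_cm = volume.spacing[2] * 0.1
    dtau = mu_rho_mat[labels] * rho * seg_cm
    tau_mid = np.cumsum(dtau) - 0.5 * dtau
    ks = np.arange(volume.shape[2])
    return ks, np.full(volume.shape[2], seg_cm), tau_mid, (i, j)


def candidate_origins(volume: MaterialVolume, scan_point, beam_energy_kev: float,
                      include=SAMPLE_MATERIALS, stride: int = 1,
                      table: AttenuationTable | None = None):
    """Candidate fluorescence origins along the beam line through a scan point.

    Returns (points (n,3) world mm, normalized weights (n,), T_exc (n,)).
    Origins are the non-air (by default tissue/bone) voxels the beam
    intersects; weights are proportional to excitation transmission times
    intersected length.  A beam that misses the sample yields empty arrays.
    """
    table = table or default_attenuation_table()
    mu = np.array([table.material_mu_rho(m, beam_energy_kev) for m in volume.materials])
    x, y = float(scan_point[0]), float(scan_point[1])
    col = _beam_column_tau(volume, x, y, mu)
    empty = (np.zeros((0, 3)), np.zeros(0), np.zeros(0))
    if col is None:
        return empty
    ks, segs, tau_mid, (i, j) = col
    names = {m.name for m in volume.materials}
    keep_idx = [volume.label_index(n) for n in include if n in names]
    sel = np.isin(volume.labels[i, j, :], keep_idx)
    if not sel.any():
        return empty
    ks, segs, tau_mid = ks[sel], segs[sel], tau_mid[sel]
    if stride > 1:
        ks, segs, tau_mid = ks[::stride], segs[::stride], tau_mid[::stride]
    t_exc = np.exp(-tau_mid)
    w = t_exc * segs
    w = w / w.sum()
    z = volume.origin[2] + ks * volume.spacing[2]
    pts = np.column_stack([np.full(len(ks), x), np.full(len(ks), y), z])
    return pts, w, t_exc


def combined_transmission(origin, scan_point, detector: DetectorGeometry,
                          volume: MaterialVolume, e_beam: float, e_line: float,
                          table: AttenuationTable | None = None) -> float:
    """Excitation (entry -> origin at E_beam) x emission (origin -> detector
    center at E_line) transmission for a single candidate origin."""
    from .raytracer import Ray, trace, transmission as _T
    table = table or default_attenuation_table()
    origin = np.asarray(origin, dtype=float)
    b0, _ = volume.world_bounds()
    entry = np.array([origin[0], origin[1], b0[2] - 1.0])
    t_exc = 1.0
    if not np.allclose(entry, origin):
        t_exc = _T(trace(volume, Ray(tuple(entry), tuple(origin))), e_beam, table)
    t_emis = _T(trace(volume, Ray(tuple(origin), detector.position)), e_line, table)
    return t_exc * t_emis


def correction_factor(scan_point, detectors, volume: MaterialVolume,
                      e_beam: float, e_line: float, include=SAMPLE_MATERIALS,
                      stride: int = 1, table: AttenuationTable | None = None,
                      subaperture: int = 1, beam_step_mm=None):
    """kappa at one scan point: per-detector and detector-combined.

    ``subaperture`` > 1 averages candidate origins over an NxN grid of pencil
    beams across the beam footprint (``beam_step_mm``) instead of the central
    axis only, which removes the second-order convexity error of the
    center-ray approximation.  Returns a dict with kappa, kappa_det, mean_T,
    geom (total geometric acceptance G = sum_d <Omega_d/4pi> eps_d), geom_det.
    """
    if not detectors:
        raise ValueError("at least one detector is required")
    table = table or default_attenuation_table()
    if subaperture > 1:
        if beam_step_mm is None:
            raise ValueError("subaperture averaging needs beam_step_mm")
        sx, sy = beam_step_mm
        offs = (np.arange(subaperture) + 0.5) / subaperture - 0.5
        all_pts, all_w, all_t = [], [], []
        for ox in offs:
            for oy in offs:
                p, w_, t_ = candidate_origins(
                    volume, (scan_point[0] + ox * sx, scan_point[1] + oy * sy),
                    e_beam, include, stride, table)
                if len(p):
                    all_pts.append(p)
                    all_w.append(w_)
                    all_t.append(t_)
        if all_pts:
            pts = np.concatenate(all_pts)
            w = np.concatenate([wi / len(all_w) for wi in all_w])
            w = w / w.sum()
            t_exc = np.concatenate(all_t)
        else:
            pts = np.zeros((0, 3)); w = np.zeros(0); t_exc = np.zeros(0)
    else:
        pts, w, t_exc = candidate_origins(volume, scan_point, e_beam, include, stride, table)
    mu_line = np.array([table.material_mu_rho(m, e_line) for m in volume.materials])
    ndet = len(detectors)
    kappa_det = np.ones(ndet)
    s_det = np.ones(ndet)
    g_det = np.zeros(ndet)
    if len(pts) == 0:
        # vacuum / miss: kappa = 1; geometric acceptance at the beam mid-grid point
        b0, b1 = volume.world_bounds()
        ref = np.array([scan_point[0], scan_point[1], (b0[2] + b1[2]) / 2])
        for d, det in enumerate(detectors):
            r2 = np.sum((np.asarray(det.position) - ref) ** 2)
            g_det[d] = det.active_area_mm2 / (4 * np.pi * r2) * det.intrinsic_efficiency(e_line, table)
    else:
        for d, det in enumerate(detectors):
            tau = emission_tau_batch(volume.labels, volume.density,
                                     *volume.spacing, *volume.origin,
                                     pts, np.asarray(det.position, dtype=float), mu_line)
            t_comb = t_exc * np.exp(-tau)
            s = float(np.sum(w * t_comb))
            s_det[d] = s
            kappa_det[d] = 1.0 / s
            r2 = np.sum((pts - np.asarray(det.position)) ** 2, axis=1)
            omega = det.active_area_mm2 / (4 * np.pi * r2)
            g_det[d] = float(np.sum(w * omega)) * det.intrinsic_efficiency(e_line, table)
    if g_det.sum() <= 0:
        raise ValueError("all detectors subtend zero solid angle")
    omega_d = g_det / g_det.sum()
    mean_t = float(np.sum(omega_d * s_det))
    return {
        "kappa": 1.0 / mean_t,
        "kappa_det": kappa_det,
        "mean_T": mean_t,
        "geom": float(g_det.sum()),
        "geom_det": g_det,
        "n_origins": len(pts),
    }


def _resolve_emission_energy(emission) -> float:
    if isinstance(emission, (int, float)):
        return float(emission)
    element, line = emission
    return line_energy(element, line)


def correction_map(scan: ScanGeometry, detectors, volume: MaterialVolume,
                   emission, include=SAMPLE_MATERIALS, stride: int = 1,
                   table: AttenuationTable | None = None,
                   subaperture: int = 1) -> CorrectionMap:
    """Evaluate :func:`correction_factor` at every raster point.

    ``emission`` is either an energy in keV or an (element, line) pair.
    Raises a validation error when the raster grid does not overlap the
    volume's world frame laterally (unit/axes mismatch guard).
    """
    e_line = _resolve_emission_energy(emission)
    b0, b1 = volume.world_bounds()
    if (scan.x_mm.max() < b0[0] or scan.x_mm.min() > b1[0]
            or scan.y_mm.max() < b0[1] or scan.y_mm.min() > b1[1]):
        raise ValueError(
            "scan raster does not overlap the volume laterally; check that scan "
            "geometry and CT share the same world frame and units (mm)"
        )
    table = table or default_attenuation_table()
    ny, nx = scan.shape
    ndet = len(detectors)
    out = CorrectionMap(
        kappa=np.ones((ny, nx)),
        kappa_det=np.ones((ndet, ny, nx)),
        mean_transmission=np.ones((ny, nx)),
        geom=np.zeros((ny, nx)),
        geom_det=np.zeros((ndet, ny, nx)),
        emission_energy=e_line,
        detector_labels=tuple(d.label for d in detectors),
        n_origins=np.zeros((ny, nx), dtype=np.int64),
    )
    for iy, y in enumerate(scan.y_mm):
        for ix, x in enumerate(scan.x_mm):
            res = correction_factor((x, y), detectors, volume,
                                    scan.beam_energy_kev, e_line, include, stride,
                                    table, subaperture, scan.step_mm)
            out.kappa[iy, ix] = res["kappa"]
            out.kappa_det[:, iy, ix] = res["kappa_det"]
            out.mean_transmission[iy, ix] = res["mean_T"]
            out.geom[iy, ix] = res["geom"]
            out.geom_det[:, iy, ix] = res["geom_det"]
            out.n_origins[iy, ix] = res["n_origins"]
    return out
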