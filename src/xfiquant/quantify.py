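"""Conversion of fitted counts + kappa into elemental mass maps and
biodistribution coefficients, with significance/display thresholding and
composite CT overlays.

The per-pixel mass follows m = N_corr * A_beam / (N0 * sigma_f) with
N_corr = N * kappa, where N is the detected count normalized by the geometric
acceptance G (solid angle x intrinsic efficiency, reported by the correction
module) so that kappa remains a pure attenuation inverse.  Statistical errors
propagate linearly from the fit; kappa and sigma_f uncertainties are
systematic and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .correction import CorrectionMap, ScanGeometry
from .physics_tables import fluorescence_cross_section
from .spectral_fit import FitResult, SpectralModel, build_model, fit_spectrum

__all__ = [
    "MassMap",
    "BiodistributionResult",
    "mass_from_counts",
    "significance_filter",
    "total_mass",
    "percent_injected_dose",
    "fit_scan",
    "quantify_scan",
    "composite_overlay",
]

# display/transparency thresholds (g/pixel) used for rendering AND totals
DISPLAY_THRESHOLDS = {"Au": 6e-9, "Sr": 5e-9}


def mass_from_counts(n, kappa, n0, a_beam_cm2, sigma_f):
    """Elemental mass (g) in the beam at one scan point.

    m = (N * kappa) * A_beam / (N0 * sigma_f); linear in N and kappa.
    """
    if n0 <= 0 or sigma_f <= 0 or a_beam_cm2 <= 0:
        raise ValueError("N0, sigma_f and A_beam must all be positive")
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 1.0 - 1e-12):
        raise ValueError("kappa must be >= 1")
    out = np.asarray(n, dtype=float) * kappa * a_beam_cm2 / (n0 * sigma_f)
    return float(out) if np.ndim(n) == 0 and np.ndim(kappa) == 0 else out


def significance_filter(area, area_error, k: float = 3.0):
    """Currie-style decision: pass iff area > k * error (default k = 3)."""
    area = np.asarray(area, dtype=float)
    err = np.asarray(area_error, dtype=float)
    out = area > k * err
    return bool(out) if out.ndim == 0 else out


@dataclass
class MassMap:
    """Grid of elemental mass per raster pixel (g) with standard errors."""

    mass: np.ndarray
    stderr: np.ndarray
    element: str
    group: str
    scan: ScanGeometry = field(repr=False, default=None)
    significant: np.ndarray = None
    uncorrected: np.ndarray = None   # same map with kappa = 1, for comparison

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if self.mass.shape != self.stderr.shape:
            raise ValueError("mass and stderr shapes differ")
        if np.any(self.mass < 0):
            raise ValueError("thresholded masses must be non-negative")
        if self.significant is None:
            self.significant = np.ones(self.mass.shape, dtype=bool)

    def to_tsv(self, path):
        with open(path, "w") as f:
            f.write(f"# {self.element} ({self.group}) mass map, g per raster pixel\n")
            np.savetxt(f, np.atleast_2d(self.mass), delimiter="\t", fmt="%.8g")


def total_mass(mass_map, display_threshold: float | None = None) -> float:
    """Sum of per-pixel masses at or above the display threshold (g).

    The threshold applies to totals as well as rendering, so reported totals
    share the semantics of the displayed maps; pass 0 for unthresholded sums.
    """
    if isinstance(mass_map, MassMap):
        arr = mass_map.mass
        if display_threshold is None:
            display_threshold = DISPLAY_THRESHOLDS.get(mass_map.element, 0.0)
    else:
        arr = np.asarray(mass_map, dtype=float)
        display_threshold = display_threshold or 0.0
    return float(arr[arr >= display_threshold].sum())


@dataclass(frozen=True)
class BiodistributionResult:
    """%ID (and %ID/g when a tissue mass is given) for one sample."""

    m_element_total: float
    injected_dose: float
    tissue_mass: float | None
    percent_id: float
    percent_id_per_g: float | None


def percent_injected_dose(m_total: float, injected: float,
                          tissue_mass: float | None = None) -> BiodistributionResult:
    """Percent of injected dose (and per gram of tissue when mass is known)."""
    if injected <= 0:
        raise ValueError("injected dose must be positive")
    if tissue_mass is not None and tissue_mass <= 0:
        raise ValueError("tissue mass must be positive")
    pid = 100.0 * m_total / injected
    pidg = pid / tissue_mass if tissue_mass is not None else None
    return BiodistributionResult(m_total, injected, tissue_mass, pid, pidg)


def fit_scan(sim_or_spectra, model: SpectralModel | None = None,
             elements=None, window=None, detector="sum"):
    """Fit every raster point's (detector-summed) spectrum.

    Accepts a :class:`~xfiquant.synthetic.SimulatedScan` or a 2-D object array
    of :class:`~xfiquant.spectral_fit.Spectrum`.  Returns an (ny, nx) object
    array of FitResult.
    """
    if model is None:
        kw = {}
        if elements is not None:
            kw["elements"] = elements
        if window is not None:
            kw["fit_window"] = window
        model = build_model(**kw)
    if hasattr(sim_or_spectra, "spectrum"):
        ny, nx = sim_or_spectra.scan.shape
        get = lambda iy, ix: sim_or_spectra.spectrum(iy, ix, detector)
    else:
        arr = np.asarray(sim_or_spectra, dtype=object)
        ny, nx = arr.shape
        get = lambda iy, ix: arr[iy, ix]
    out = np.empty((ny, nx), dtype=object)
    null = FitResult(areas={k: 0.0 for k in model.group_keys},
                     errors={k: 0.0 for k in model.group_keys},
                     background={}, redchi=0.0, window=model.window,
                     converged=False, n_free=model.n_free)
    for iy in range(ny):
        for ix in range(nx):
            try:
                out[iy, ix] = fit_spectrum(get(iy, ix), model)
            except ValueError:
                # empty spectrum (e.g. beam misses everything): null result
                out[iy, ix] = null
    return out


def quantify_scan(fits: np.ndarray, cmaps, scan: ScanGeometry,
                  element: str = "Au", groups=("La", "Lb"),
                  significance_k: float = 3.0, apply_correction: bool = True,
                  combine: str = "inverse_variance") -> MassMap:
    """Turn fitted areas + correction maps into a mass map (g per pixel).

    ``cmaps`` maps line-group label to its :class:`CorrectionMap` (a single
    map is accepted for single-group quantification).  Per pixel, each group's
    detected area is divided by the geometric acceptance G, multiplied by its
    group's kappa (unless ``apply_correction=False``), and converted to an
    independent mass estimate with that group's beam-energy fluorescence
    cross-section.  Group estimates are combined by inverse variance (default;
    a heavily attenuated, interference-ridden group like Au La contributes in
    proportion to its information) or simply pooled (``combine="pooled"``).
    Pixels failing the significance filter (pooled area vs pooled error;
    disabled with ``significance_k=0``) are zeroed and flagged, not removed.
    """
    if isinstance(cmaps, CorrectionMap):
        cmaps = {groups[0]: cmaps} if not isinstance(groups, str) else {groups: cmaps}
    if isinstance(groups, str):
        groups = (groups,)
    missing = [g for g in groups if g not in cmaps]
    if missing:
        raise ValueError(f"no correction map for group(s) {missing}")
    if combine not in ("inverse_variance", "pooled"):
        raise ValueError(f"unknown combine mode {combine!r}")
    ny, nx = fits.shape
    sigma_f = {g: fluorescence_cross_section(element, g, scan.beam_energy_kev)
               for g in groups}
    scale = scan.beam_area_cm2 / scan.n0
    mass = np.zeros((ny, nx))
    err = np.zeros((ny, nx))
    sig = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            fr: FitResult = fits[iy, ix]
            # a column with no candidate origins cannot carry the analyte
            # under the correction model; its mass is structurally zero
            first = cmaps[groups[0]]
            if first.n_origins is not None and first.n_origins[iy, ix] == 0:
                continue
            m_g, s_g = [], []
            pooled_area = 0.0
            pooled_var = 0.0
            geom_ok = True
            for g in groups:
                area, aerr = fr.area(element, g)
                cm = cmaps[g]
                gg = cm.geom[iy, ix]
                if gg <= 0:
                    geom_ok = False
                    break
                kappa = cm.kappa[iy, ix] if apply_correction else 1.0
                m_g.append(mass_from_counts(area / gg, kappa, scan.n0,
                                            scan.beam_area_cm2, sigma_f[g]))
                s_g.append(max(aerr, 1e-3) * kappa / gg * scale / sigma_f[g])
                pooled_area += area
                pooled_var += aerr ** 2
            if not geom_ok:
                continue
            m_g, s_g = np.array(m_g), np.array(s_g)
            if combine == "inverse_variance":
                w = 1.0 / s_g ** 2
                m = float(np.sum(w * m_g) / w.sum())
                e = float(np.sqrt(1.0 / w.sum()))
            else:
                w = np.array([sigma_f[g] for g in groups])
                m = float(np.sum(w * m_g) / w.sum())
                e = float(np.sqrt(np.sum((w * s_g) ** 2)) / w.sum())
            ok = significance_filter(pooled_area, max(np.sqrt(pooled_var), 1e-300),
                                     significance_k)
            sig[iy, ix] = ok
            mass[iy, ix] = max(m, 0.0) if ok else 0.0
            err[iy, ix] = e
    return MassMap(mass, err, element, "+".join(groups), scan, significant=sig)


def composite_overlay(mass_map: MassMap, ct, axis=2,
                      transparency_threshold: float | None = None,
                      smoothing: str = "gaussian", cmap_name: str = "inferno"):
    """Composite mass-map / CT projection image.

    The CT volume is summed along ``axis`` into a radiograph-like grayscale;
    the raster mass map is resampled onto the CT pixel grid using the shared
    world frame and Gaussian-smoothed; pixels below the transparency threshold
    are fully transparent.  Returns (rgba array, extent in mm) suitable for
    ``matplotlib.pyplot.imshow``.
    """
    import matplotlib

    if transparency_threshold is None:
        transparency_threshold = DISPLAY_THRESHOLDS.get(mass_map.element, 0.0)
    axes2d = [a for a in range(3) if a != axis]
    proj = ct.hu.sum(axis=axis) - ct.hu.min() * ct.shape[axis]
    proj = proj / max(proj.max(), 1e-12)
    # CT pixel grid in world coords; proj axes = (axes2d[0], axes2d[1])
    n0_, n1_ = proj.shape
    sp0, sp1 = ct.spacing[axes2d[0]], ct.spacing[axes2d[1]]
    o0, o1 = ct.origin[axes2d[0]], ct.origin[axes2d[1]]
    scan = mass_map.scan
    if scan is None:
        raise ValueError("mass map carries no scan geometry")
    lo0 = o0 - sp0 / 2
    lo1 = o1 - sp1 / 2
    if not (scan.x_mm.min() >= lo0 - 50 and scan.x_mm.max() <= lo0 + n0_ * sp0 + 50):
        raise ValueError("mass map and CT do not share a consistent world frame")
    canvas = np.zeros_like(proj)
    hits = np.zeros_like(proj)
    for iy, y in enumerate(scan.y_mm):
        for ix, x in enumerate(scan.x_mm):
            i = int((x - lo0) / sp0)
            j = int((y - lo1) / sp1)
            if 0 <= i < n0_ and 0 <= j < n1_:
                canvas[i, j] += mass_map.mass[iy, ix]
                hits[i, j] = 1.0
    if smoothing == "gaussian":
        sigma = (scan.step_mm[0] / sp0 / 2.0, scan.step_mm[1] / sp1 / 2.0)
        smooth = ndimage.gaussian_filter(canvas, sigma)
        norm = ndimage.gaussian_filter(hits, sigma)
        canvas = np.where(norm > 1e-9, smooth / np.maximum(norm, 1e-9), 0.0)
    vmax = max(canvas.max(), 1e-300)
    colors = matplotlib.colormaps[cmap_name](canvas / vmax)
    colors[..., 3] = np.where(canvas >= transparency_threshold, 0.85, 0.0)
    gray = np.repeat(proj[..., None], 4, axis=2)
    gray[..., 3] = 1.0
    alpha = colors[..., 3:4]
    rgba = gray * (1 - alpha) + colors * alpha
    rgba[..., 3] = 1.0
    extent = (lo1, lo1 + n1_ * sp1, lo0, lo0 + n0_ * sp0)
    return rgba, extent
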