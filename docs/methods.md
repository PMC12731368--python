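# Methods

`xfiquant` quantifies element distributions from raster-scanned L-shell X-ray
fluorescence imaging (XFI) measurements, correcting the strong attenuation of
low-energy fluorescence photons in tissue with anatomical information from a
co-registered CT scan. This note describes the model, its assumptions, the
numerical choices, and what the validation on synthetic data does and does not
establish.

## Physical model

A monochromatic pencil beam of energy `E0` (53–59 keV) enters the sample along
`+z` at raster position `(x, y)` with `N0 = flux x dwell` photons. An element
of mass `m` inside the beam produces fluorescence photons in proportion to its
shell-summed production cross-section `sigma_f(E0)` (cm²/g). A photon emitted
at energy `E_line` reaches a detector with probability

    T_exc(E0) x T_emis(E_line) x Omega/4pi x eps(E_line),

where the transmissions follow the Beer–Lambert law `T = exp(-sum_m (mu/rho)_m
∫rho dx_m)` with per-material areal densities integrated along the photon
path, `Omega` is the detector solid angle and `eps` the intrinsic efficiency
(Be-window transmission x Si-chip absorption). Detected counts per line are
extracted by spectral deconvolution, corrected with the attenuation factor
`kappa`, and converted to mass via

    m = N_corr * A_beam / (N0 * sigma_f),        N_corr = N * kappa,

where `N` is first normalized by the geometric acceptance `G = sum_d
<Omega_d/4pi> eps_d` so that `kappa` remains a pure attenuation inverse
(`kappa = 1` in vacuum).

## CT segmentation

Hounsfield Units are classified into five NIST material classes (air, paraffin
wax, adipose, soft tissue, cortical bone) by ordered half-open intervals
[low, high); values outside the configured domain clamp to the nearest class,
making classification total and idempotent. Each class carries its nominal
density (`density_mode="nominal"`); a piecewise-linear HU-to-density mapping is
available for sensitivity studies. Tumor tissue is represented by the
soft-tissue/adipose classes; there is no dedicated tumor compound.

## Attenuation tables

Elemental mass attenuation coefficients are bundled as a plain-text snapshot
on a 5–100 keV grid and interpolated log-log (standard for photon
cross-sections; sub-percent error away from edges, exact at grid nodes).
Composites use the weight-fraction mixture rule. The snapshot is built from a
photoelectric power law (`E^-3.07`) anchored to tabulated 10 keV totals plus a
Klein–Nishina-shaped incoherent term; against the standard liquid-water
tabulation it agrees to ~1% over 5–100 keV and exactly at 10 keV
(5.329 cm²/g). Users can substitute their own tables in the same TSV layout.
Fluorescence production cross-sections are bundled per element shell as a
power law above the shell edge with branching fractions distributing the shell
total over lines; below-edge queries raise (strict mode) or return zero.

## Ray tracing

Path integrals use an exact incremental (Siddon-type) voxel traversal with
half-open voxel boxes (a point on a face belongs to the larger-index voxel);
space outside the grid is vacuum, appropriate for ex vivo samples in air. A
fixed-step midpoint sampler is retained purely as an independent test oracle.
The excitation beam is axis-aligned, so its column integrals reduce to exact
cumulative sums.

## Correction factor kappa

For each scan position, the candidate fluorescence origins are the voxels of
the analyte's carrier materials intersected by the beam line (Au:
soft tissue + adipose; Sr: cortical bone; configurable). Each origin is
weighted by its excitation transmission times intersected length, normalized
to 1. Per detector,

    kappa_d = 1 / sum_o w_o T_exc(o) T_emis(o, d),

and the detector-combined kappa averages `sum_o w_o T_comb` over detectors
with weights proportional to solid angle x intrinsic efficiency. Efficiency
never enters `kappa_d` itself, only the inter-detector weights and the
separately reported acceptance `G`, so the vacuum identity `kappa = 1` holds
exactly. The beam is treated as its central axis; optional NxN sub-aperture
averaging (off by default) removes the second-order convexity error for beams
comparable to the raster step.

Two properties of this estimator matter in practice:

- It is unbiased only insofar as the analyte's depth distribution along the
  beam resembles the candidate-origin distribution. Detectors perpendicular to
  the beam are robust (their emission paths are depth-independent); backward
  detectors are not, which is why the compact-system preset places its four
  detectors on a perpendicular ring (±x, ±y). The positions of the real
  compact system's detectors are not published; the ring is a nominal,
  physically motivated choice (90° is also the scatter minimum).
- Restricting origins to the analyte's carrier materials avoids systematic
  over-correction in beam columns that cross dense non-carrier structures
  (e.g. bone in an Au scan).

Scan positions whose beam column contains no carrier voxels have no candidate
origins; the correction model cannot support analyte mass there and the mass
map is structurally zero at such pixels.

## Spectral deconvolution

The spectrum model is one Gaussian per tabulated emission line inside the fit
window (default 8–15 keV), centers fixed at tabulated energies and widths
fixed by the resolution model `FWHM(E) = 2.355 sqrt(sigma_noise^2 + F eps E)`
calibrated to 123 eV FWHM at 5.9 keV (Fano factor 0.115, pair energy
3.65 eV), on a composite continuum (constant + exponential + quadratic +
sigmoid). Line areas are tied with tabulated branching ratios within
fine-structure subgroups (Lα1+Lα2+Ll, Lβ1+Lβ2, Kα1+Kα2, ...) for the analyte
elements, because attenuation distorts the detected ratio *between* subgroups
(Au Lα at 9.7 keV vs Lβ at 11.4 keV differ by ~2x through 5 mm of tissue) but
not meaningfully within one. Elements whose fluorescence originates in the
setup rather than the sample (W, Ta, Ni) and the trace elements not being
quantified (Rb, Zn) are tied across their whole shell, which anchors their
overlap with the gold lines (notably W Lβ1 at 9.672 keV under Au Lα1 at
9.713 keV). Au Lγ1 (13.382 keV) is spectrally inseparable from Rb Kα1
(13.395 keV) at SDD resolution; it stays in the model but is excluded from
quantification by default.

Fitting is bounded least squares (areas ≥ 0) with Poisson-motivated weights.
The first pass weights by observed counts; two deterministic reweighting
passes then use model-predicted variances, because observed-count weighting
(Neyman χ²) biases areas low by roughly one count per bin — a 10–15% effect at
realistic per-pixel statistics. The reduced χ² and parameter covariance are
evaluated at the final model's variances. Initialization is deterministic
(window sums and decile ratios; no random starts), so identical inputs give
bit-identical results. Non-convergence flags the result instead of raising.

## Quantification

Each fitted line group yields an independent mass estimate (its own kappa map
at its emission energy, its own cross-section); groups are combined per pixel
by inverse variance, so a noisy, heavily attenuated group contributes in
proportion to its information. Per-pixel statistical errors propagate the fit
errors linearly; kappa and sigma_f uncertainties are systematic and reported
separately. The display threshold (6 ng Au, 5 ng Sr per pixel) applies to both
rendering and reported totals; the Currie-style significance filter
(area > k·sigma, default k = 3) is intended for detect/non-detect decisions
and can be disabled for totals (k = 0). Biodistribution coefficients follow
%ID = 100 m/dose and %ID/g = %ID/m_tissue (tissue mass is user input).

## Synthetic data

The default phantom emulates a paraffin-embedded murine hindleg/tumor
specimen: a 19 x 16 x 12 mm block (0.1 mm default voxels, 0.2 mm in the
routine validation studies to keep runtimes in minutes) consisting of a
~1 mm paraffin shell around a soft-tissue block with an adipose pocket, a
femur-like bone rod plus a pelvis-like bone block carrying 2.5 ug Sr, and
14.9 ug Au distributed through most of the tissue (66% broad) with two
hotspots (24% + 10%) — mirroring a broadly spread, inhomogeneous intratumoral
injection. HU values are drawn uniformly from each class's interval (seeded)
so classification robustness is exercised; classification recovers the truth
labels exactly by construction.

The forward simulator runs the full physics chain per scan point (exact
column excitation transmissions, per-voxel emission traces to each detector,
solid angle, intrinsic efficiency, Gaussian line placement, Poisson noise),
with the beam footprint subdivided 3 x 3 laterally for the emission geometry.
Scan parameters default to the compact-system values (59 keV, 3.84e8 ph/s,
40 s/point); the beam is square and step-matched so the raster tiles the
sample. The continuum background is phenomenological
(constant + exponential, scaled by a beam-path density proxy); its amplitude
is set so the whole-scan 3-sigma Au detection limit is of order 1 ug,
consistent with the sub-microgram theoretical sensitivity of the instrument
class being emulated. Interference lines (W, Ta from the beam path, Ni from
the detector housing, Rb/Zn from tissue) are placed with source branching and
fixed effective scales.

What the synthetic validation shows: the pipeline recovers known totals to
about five percent or better per orientation with realistic counting
statistics (worst where a bone column, its scatter-associated interference
and an Au hotspot coincide), the
correction removes a ~10-20x attenuation bias, and the fit separates Au from
W/Ta interference. What it does not show: performance under real detector
artifacts (pile-up, escape peaks, tailing), real Compton continua, CT
miscalibration or registration error, or tissue compositions outside the five
NIST classes — all listed as non-goals.

## Numerical choices and edge cases

- Energies in keV, lengths in mm (converted to cm for areal densities),
  masses in g. World coordinates are voxel-center based, 0-based indices.
- Ray endpoints exactly on voxel faces resolve toward the larger index.
- Zero-length rays, empty fit windows, non-overlapping scan/CT frames, and
  below-edge excitation raise validation errors; a beam missing the sample
  yields kappa = 1 and an empty origin list, not an error.
- Determinism: every stochastic step derives from one integer seed; repeated
  runs are bit-identical. The validation studies use 15 x 15 rasters, 0.2 mm
  voxels and 4 orientations (~4 minutes end to end on one CPU); these sizes
  are the package's routine test configuration, with the 0.1 mm default
  reserved for full-fidelity runs.

## Known limitations

- The candidate-origin average is a first-order correction: a strongly
  localized source viewed by a depth-sensitive detector geometry is
  under-corrected; orientation consistency of totals is the practical check.
- kappa and sigma_f systematics are not folded into the per-pixel error bars.
- The bundled cross-section snapshot is a compact parameterization (~1%
  vs reference tabulations for the five materials in 8-60 keV); heavy-element
  attenuation around L-edges is not tabulated (only production cross-sections
  above-edge are needed for the analytes).
- Non-negative per-pixel estimates bias map totals slightly upward at very low
  signal-to-noise; totals are therefore reported with the display-threshold
  semantics and support masking described above.
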