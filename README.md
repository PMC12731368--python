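# xfiquant

CT-guided attenuation correction and quantification for L-shell X-ray
fluorescence imaging (XFI) of high-Z element distributions — e.g. gold
nanoparticles in resected tumor specimens.

## The problem

L-shell XFI raster-scans a sample with a hard X-ray pencil beam (50–60 keV)
and counts element-characteristic fluorescence photons. For gold the L lines
lie at 9.7–13.4 keV, where a centimetre of soft tissue transmits only a few
percent — so raw count maps underestimate the element mass severely and
anisotropically. `xfiquant` corrects this using a co-registered CT scan:

1. **Segment** — classify CT Hounsfield Units into material classes
   (air / paraffin / adipose / soft tissue / cortical bone) with nominal
   densities: a sample-specific 3-D attenuation map.
2. **Correct** — for every scan position and detector, ray-trace excitation
   and emission paths (exact Siddon voxel traversal) and average the combined
   Beer–Lambert transmission `T_exc(E0) · T_emis(E_line)` over candidate
   fluorescence origins along the beam. The inverse of the detector-weighted
   mean transmission is the correction factor **κ** (κ = 1 in vacuum, ≥ 1
   everywhere).
3. **Fit** — deconvolve each detector spectrum into per-line areas: Gaussians
   at tabulated line energies with detector-resolution widths
   (123 eV FWHM at 5.9 keV) on a composite continuum, fitted over 8–15 keV
   with branching-tied areas; goodness of fit via reduced χ².
4. **Quantify** — convert corrected counts to mass per raster pixel,

       m = N·κ · A_beam / (N0 · σ_f),

   with `N0` incident photons, `A_beam` the beam cross-section and `σ_f` the
   fluorescence production cross-section; then totals, significance/display
   thresholds, composite XFI/CT overlays, and biodistribution coefficients
   (%ID, %ID/g).

A first-class synthetic module generates voxel phantoms with known material
and element content and forward-simulates complete raster scans (attenuation,
solid angle, detector efficiency, spectral response, Poisson noise,
interference lines) — every claim the package makes is validated against this
hermetic oracle. See `docs/methods.md` for the model details and limitations.

## Worked example

Simulate a murine-hindleg-like phantom (14.9 μg Au in the tumor region,
2.5 μg Sr in bone), then run the pipeline stages on the bundle:

```bash
xfiquant simulate --seed 4 --nx 6 --ny 6 --spacing 0.5 --out run/
xfiquant segment  --ct run/ct.nii.gz --out run/seg
xfiquant correct  --ct run/ct.nii.gz --geometry run/geometry.yaml --out run/corr
xfiquant fit      --spectra run/spectra.h5 --out run/fits.tsv
xfiquant quantify --fits run/fits.tsv --kappa run/corr/kappa.tsv \
                  --geom run/corr/geom.tsv --geometry run/geometry.yaml \
                  --injected-dose-ug 34.7 --significance-k 0 --out run/quant
```

which prints (the phantom truly contains 14.9 μg of gold):

```json
{
  "display_threshold_g": 6e-09,
  "element": "Au",
  "group": "La",
  "percent_id": 42.93818726112518,
  "total_mass_g": 1.489955097961044e-05,
  "unthresholded_total_g": 1.4905360242160547e-05
}
```

or in Python, end to end:

```python
>>> from xfiquant.pipeline import end_to_end_study
>>> for r in end_to_end_study(seed=1, spacing=0.2):
...     print(f"orientation {r.orientation}: corrected "
...           f"{r.corrected_total*1e6:.2f} ug, uncorrected "
...           f"{r.uncorrected_total*1e6:.2f} ug, true {r.true_total*1e6:.2f} ug")
orientation 0: corrected 14.78 ug, uncorrected 1.33 ug, true 14.90 ug
orientation 1: corrected 14.82 ug, uncorrected 1.72 ug, true 14.90 ug
orientation 2: corrected 15.10 ug, uncorrected 1.38 ug, true 14.90 ug
orientation 3: corrected 15.65 ug, uncorrected 1.78 ug, true 14.90 ug
```

The uncorrected totals sit at the mean combined transmission (≈7–10% here —
an order-of-magnitude underestimate); the corrected totals recover the true
14.9 μg to within about five percent from every orientation (the worst
orientation aligns a bone column with an Au hotspot — the hardest geometry
for the correction, discussed in `docs/methods.md`). Biodistribution
coefficients from a quantified total:

```python
>>> from xfiquant.quantify import percent_injected_dose
>>> percent_injected_dose(14.9e-6, 34.7e-6).percent_id
42.93948126801153
```

i.e. 42.9 %ID retained of a 34.7 μg injected dose.

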