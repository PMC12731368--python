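"""File formats: CT volumes (NIfTI / MetaImage / raw+sidecar), scan spectra
(HDF5 / long CSV), geometry configs (YAML) and tabular/TIFF map outputs.

World-frame convention for CT files: the affine is diagonal voxel spacing (mm)
plus the origin translation; axis order is (x, y, z) with the beam along +z.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .correction import DetectorGeometry, ScanGeometry
from .spectral_fit import Spectrum
from .voxel_model import CTVolume

__all__ = [
    "save_ct", "load_ct", "write_labels_tiff", "write_float_tiff",
    "write_scan_spectra", "read_scan_spectra", "spectra_to_csv",
    "save_geometry", "load_geometry", "write_manifest",
]


def save_ct(ct: CTVolume, path) -> None:
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib
        affine = np.diag(list(ct.spacing) + [1.0])
        affine[:3, 3] = ct.origin
        nib.save(nib.Nifti1Image(np.asarray(ct.hu, dtype=np.float32), affine), str(path))
    elif path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk
        img = sitk.GetImageFromArray(np.asarray(ct.hu, dtype=np.float32).transpose(2, 1, 0))
        img.SetSpacing(ct.spacing)
        img.SetOrigin(ct.origin)
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported CT format: {path.name}")


def load_ct(path, sidecar=None) -> CTVolume:
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(abs(aff[i, i])) for i in range(3))
        origin = tuple(float(aff[i, 3]) for i in range(3))
        return CTVolume(np.asarray(img.dataobj, dtype=np.float32), spacing, origin)
    if path.suffix in (".mha", ".mhd"):
        import SimpleITK as sitk
        img = sitk.ReadImage(str(path))
        hu = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return CTVolume(hu.astype(np.float32), tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    if path.suffix == ".raw":
        side = Path(sidecar) if sidecar else path.with_suffix(".yaml")
        meta = yaml.safe_load(side.read_text())
        hu = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "int16")))
        hu = hu.reshape(tuple(meta["shape"])).astype(np.float32)
        return CTVolume(hu, tuple(meta["spacing"]), tuple(meta.get("origin", (0, 0, 0))))
    raise ValueError(f"unsupported CT format: {path.name}")


def write_labels_tiff(labels: np.ndarray, path) -> None:
    """Label volume as a multi-page (z-paged) TIFF."""
    tifffile.imwrite(str(path), np.moveaxis(np.asarray(labels, dtype=np.uint8), 2, 0))


def write_float_tiff(arr: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32))


def write_scan_spectra(path, bin_edges, spectra, x_mm, y_mm,
                       detector_labels, live_time: float) -> None:
    """HDF5 layout: /bin_edges, /spectra (ny,nx,ndet,nbins), /x_mm, /y_mm,
    /detector_labels, live_time attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("bin_edges", data=np.asarray(bin_edges))
        f.create_dataset("spectra", data=np.asarray(spectra), compression="gzip")
        f.create_dataset("x_mm", data=np.asarray(x_mm))
        f.create_dataset("y_mm", data=np.asarray(y_mm))
        f.create_dataset("detector_labels",
                         data=np.array([str(l) for l in detector_labels], dtype="S"))
        f.attrs["live_time_s"] = float(live_time)


def read_scan_spectra(path):
    """Returns (bin_edges, spectra array, x_mm, y_mm, labels, live_time)."""
    with h5py.File(path, "r") as f:
        return (f["bin_edges"][:], f["spectra"][:], f["x_mm"][:], f["y_mm"][:],
                [s.decode() for s in f["detector_labels"][:]],
                float(f.attrs["live_time_s"]))


def spectra_to_csv(path, bin_edges, spectra, x_mm, y_mm, detector_labels) -> None:
    """Long-format CSV: ix, iy, detector, bin_low_keV, bin_high_keV, counts."""
    rows = []
    edges = np.asarray(bin_edges)
    for iy in range(len(y_mm)):
        for ix in range(len(x_mm)):
            for d, lab in enumerate(detector_labels):
                c = spectra[iy, ix, d]
                rows.append(pd.DataFrame({
                    "ix": ix, "iy": iy, "detector": lab,
                    "bin_low_keV": edges[:-1], "bin_high_keV": edges[1:],
                    "counts": c}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def save_geometry(path, scan: ScanGeometry, detectors) -> None:
    doc = {
        "scan": {
            "x_mm": [float(v) for v in scan.x_mm],
            "y_mm": [float(v) for v in scan.y_mm],
            "beam_energy_kev": float(scan.beam_energy_kev),
            "beam_area_mm2": float(scan.beam_area_mm2),
            "beam_profile": scan.beam_profile,
            "flux_ph_s": float(scan.flux_ph_s),
            "dwell_s": float(scan.dwell_s),
            "step_mm": [float(v) for v in scan.step_mm],
            "units": {"length": "mm", "energy": "keV"},
        },
        "detectors": [
            {"label": d.label, "position_mm": [float(v) for v in d.position],
             "active_area_mm2": float(d.active_area_mm2),
             "be_window_um": float(d.be_window_um),
             "si_chip_mm": float(d.si_chip_mm)}
            for d in detectors
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_geometry(path):
    doc = yaml.safe_load(Path(path).read_text())
    s = doc["scan"]
    scan = ScanGeometry(np.array(s["x_mm"]), np.array(s["y_mm"]),
                        s["beam_energy_kev"], s["beam_area_mm2"],
                        s["flux_ph_s"], s["dwell_s"], s.get("beam_profile", "square"),
                        tuple(s["step_mm"]))
    dets = [DetectorGeometry(d["label"], tuple(d["position_mm"]),
                             d.get("active_area_mm2", 50.0),
                             d.get("be_window_um", 12.5), d.get("si_chip_mm", 1.0))
            for d in doc["detectors"]]
    return scan, dets


def write_manifest(outdir, config: dict, seed: int | None = None) -> Path:
    """Run manifest: canonical config hash, seed and package version."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "xfiquant_version": __version__,
        "config": config,
    }
    p = Path(outdir) / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return p
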