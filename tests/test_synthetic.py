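"""Phantom construction and forward-simulator physics checks."""

import numpy as np
import pytest

from xfiquant.correction import DetectorGeometry, ScanGeometry, compact_detectors
from xfiquant.physics_tables import (default_attenuation_table, emission_lines,
                                     fluorescence_cross_section, mass_attenuation)
from xfiquant.synthetic import (
    Box, ElementInclusion, Ellipsoid, PhantomSpec, forward_simulate,
    ground_truth_kappa, hindleg_phantom, make_phantom, rotate_phantom,
)
from xfiquant.voxel_model import build_material_map


def _tiny_phantom(au_ug=2.0, spacing=0.5, hu_mode="uniform", seed=0):
    """6 mm tissue cube with a small central Au blob in a 10 mm air box."""
    n = int(round(10.0 / spacing))
    return make_phantom(PhantomSpec(
        shape=(n, n, n), spacing=spacing,
        primitives=[(Box((0, 0, 0), (6.0, 6.0, 6.0)), "soft_tissue")],
        inclusions=[ElementInclusion("Au", Ellipsoid((0, 0, 0), (1.5, 1.5, 1.5)),
                                     total_mass_g=au_ug * 1e-6)],
        hu_mode=hu_mode, seed=seed))


def _scan(**kw):
    args = dict(beam_energy_kev=59.0, beam_area_mm2=1.0,
                flux_ph_s=1e9, dwell_s=1.0)
    args.update(kw)
    return ScanGeometry.raster(8.0, 8.0, 4, 4, **args)


class TestMakePhantom:
    def test_empty_spec_gives_all_air(self):
        ph = make_phantom(PhantomSpec(shape=(5, 5, 5), spacing=0.5))
        assert all(ph.materials.materials[i].name == "air"
                   for i in np.unique(ph.materials.labels))

    def test_classification_round_trip_recovers_truth_labels(self):
        ph = hindleg_phantom(seed=3, spacing=0.4)
        seg = build_material_map(ph.ct)
        np.testing.assert_array_equal(seg.labels, ph.materials.labels)

    def test_deterministic_given_seed(self):
        a = _tiny_phantom(seed=9)
        b = _tiny_phantom(seed=9)
        np.testing.assert_array_equal(a.ct.hu, b.ct.hu)
        np.testing.assert_array_equal(a.elements["Au"], b.elements["Au"])

    def test_inclusion_mass_is_exact(self):
        ph = _tiny_phantom(au_ug=2.0)
        assert ph.elements["Au"].sum() == pytest.approx(2.0e-6, rel=1e-12)

    def test_hindleg_preset_dimensions_and_contents(self):
        ph = hindleg_phantom(seed=0, spacing=0.4)
        names = {ph.materials.materials[i].name for i in np.unique(ph.materials.labels)}
        assert {"air", "paraffin", "soft_tissue", "adipose", "cortical_bone"} <= names
        assert ph.elements["Au"].sum() == pytest.approx(14.9e-6, rel=1e-9)
        assert ph.elements["Sr"].sum() == pytest.approx(2.5e-6, rel=1e-9)
        # ~19 x 16 x 12 mm sample inside a 21 x 18 x 14 mm grid
        assert ph.ct.shape == (52, 45, 35)

    def test_rotation_preserves_mass_and_labels(self):
        ph = hindleg_phantom(seed=1, spacing=0.4)
        rot = rotate_phantom(ph, 1)
        assert rot.ct.shape == (ph.ct.shape[2], ph.ct.shape[1], ph.ct.shape[0])
        assert rot.elements["Au"].sum() == pytest.approx(ph.elements["Au"].sum())
        assert np.bincount(rot.materials.labels.ravel(), minlength=5).tolist() == \
            np.bincount(ph.materials.labels.ravel(), minlength=5).tolist()


class TestForwardSimulate:
    def test_zero_flux_gives_empty_spectra(self):
        ph = _tiny_phantom()
        sim = forward_simulate(ph, _scan(flux_ph_s=0.0), compact_detectors(),
                               seed=1, background=None, interference=None)
        assert sim.spectra.sum() == 0

    def test_identical_seeds_bit_identical(self):
        ph = _tiny_phantom()
        s1 = forward_simulate(ph, _scan(), compact_detectors(), seed=5)
        s2 = forward_simulate(ph, _scan(), compact_detectors(), seed=5)
        np.testing.assert_array_equal(s1.spectra, s2.spectra)

    def test_single_voxel_closed_form_mean_counts(self):
        """One Au voxel in near-vacuum: expected La1 counts match the analytic
        N0 (m/A) sigma_f Omega/4pi eps formula."""
        spacing = 0.5
        ph = make_phantom(PhantomSpec(
            shape=(9, 9, 9), spacing=spacing,
            inclusions=[ElementInclusion("Au", Box((0, 0, 0), (0.4, 0.4, 0.4)),
                                         total_mass_g=1e-6, restrict_to=None)],
            seed=0))
        det = DetectorGeometry.at_angle("d", 90.0, 4.0)
        scan = ScanGeometry(np.array([0.0]), np.array([0.0]), 59.0, 1.0, 1e9, 1.0,
                            step_mm=(0.5, 0.5))
        sim = forward_simulate(ph, scan, [det], seed=2, background=None,
                               interference=None, subsample=1)
        lam = sum(sim.expected_counts[("Au", g)][0, 0, 0] for g in ("La", "Lb", "Lg"))
        sf = fluorescence_cross_section("Au", "L", 59.0)
        table = default_attenuation_table()
        eps_omega = sum(
            det.intrinsic_efficiency(l.energy, table) * l.rel_intensity
            for l in emission_lines("Au", shell="L"))
        eps_omega /= sum(l.rel_intensity for l in emission_lines("Au", shell="L"))
        omega = 50.0 / (4 * np.pi * 40.0 ** 2)
        expect = 1e9 * (1e-6 / 0.01) * sf * omega * eps_omega
        # residual air attenuation in the grid is < 1%
        assert lam == pytest.approx(expect, rel=0.02)

    def test_adding_tissue_scales_counts_by_transmission(self):
        """Burying the same Au blob in tissue reduces the expected counts by
        the analytic combined transmission factor."""
        spacing = 0.5
        blob = ElementInclusion("Au", Box((0, 0, 0), (0.4, 0.4, 0.4)),
                                total_mass_g=1e-6, restrict_to=None)
        empty = make_phantom(PhantomSpec(shape=(17, 17, 17), spacing=spacing,
                                         inclusions=[blob], seed=0))
        tissue = make_phantom(PhantomSpec(
            shape=(17, 17, 17), spacing=spacing,
            primitives=[(Box((0, 0, 0), (8.0, 8.0, 8.0)), "soft_tissue")],
            inclusions=[blob], hu_mode="midpoint", seed=0))
        det = DetectorGeometry.at_angle("d", 90.0, 4.0)
        scan = ScanGeometry(np.array([0.0]), np.array([0.0]), 59.0, 1.0, 1e9, 1.0,
                            step_mm=(0.5, 0.5))
        kw = dict(seed=2, background=None, interference=None, subsample=1)
        s0 = forward_simulate(empty, scan, [det], **kw)
        s1 = forward_simulate(tissue, scan, [det], **kw)
        # the voxelized 8 mm cube spans 8.5 mm (voxel centers inside the box
        # claim their whole 0.5 mm voxels), so both paths are 4.25 mm
        path_cm = 0.425
        for line_label, group in (("La1", "La"), ("Lb1", "Lb")):
            lam0 = s0.expected_counts[("Au", group)][0, 0, 0]
            lam1 = s1.expected_counts[("Au", group)][0, 0, 0]
            lines = emission_lines("Au", group=group)
            tot = sum(l.rel_intensity for l in lines)
            t_emis = sum(l.rel_intensity / tot
                         * np.exp(-mass_attenuation("soft_tissue", l.energy) * path_cm)
                         for l in lines)
            t_exc = np.exp(-mass_attenuation("soft_tissue", 59.0) * path_cm)
            # air contribution differs slightly between the two phantoms
            assert lam1 / lam0 == pytest.approx(t_exc * t_emis, rel=0.02)

    def test_flux_linearity_of_expected_counts(self):
        ph = _tiny_phantom()
        dets = compact_detectors()
        kw = dict(seed=3, background=None, interference=None)
        s1 = forward_simulate(ph, _scan(flux_ph_s=1e9), dets, **kw)
        s2 = forward_simulate(ph, _scan(flux_ph_s=2e9), dets, **kw)
        a = s1.expected_counts[("Au", "La")]
        b = s2.expected_counts[("Au", "La")]
        np.testing.assert_allclose(b, 2 * a, rtol=1e-9)

    def test_beam_below_edge_rejected(self):
        ph = _tiny_phantom()
        with pytest.raises(Exception, match="edge"):
            forward_simulate(ph, _scan(beam_energy_kev=10.0), compact_detectors())


class TestGroundTruthKappa:
    def test_vacuum_phantom_all_ones(self):
        ph = make_phantom(PhantomSpec(shape=(8, 8, 8), spacing=0.5))
        cmap = ground_truth_kappa(ph, _scan(), compact_detectors(), 9.713)
        np.testing.assert_array_equal(cmap.kappa, np.ones((4, 4)))

    def test_matches_pipeline_correction_map_under_shared_config(self):
        from xfiquant.correction import correction_map
        ph = _tiny_phantom(hu_mode="uniform", seed=4)
        scan = _scan()
        dets = compact_detectors()
        truth = ground_truth_kappa(ph, scan, dets, ("Au", "La1"))
        seg = build_material_map(ph.ct)
        pipe = correction_map(scan, dets, seg, ("Au", "La1"))
        np.testing.assert_allclose(pipe.kappa, truth.kappa, rtol=1e-6)
        np.testing.assert_allclose(pipe.kappa_det, truth.kappa_det, rtol=1e-6)

    def test_mismatched_weighting_config_differs(self):
        from xfiquant.correction import correction_map
        ph = _tiny_phantom(seed=4)
        scan = _scan()
        dets = compact_detectors()
        truth = ground_truth_kappa(ph, scan, dets, ("Au", "La1"))
        seg = build_material_map(ph.ct)
        other = correction_map(scan, dets, seg, ("Au", "La1"), stride=4)
        assert np.abs(other.kappa - truth.kappa).max() > 0
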