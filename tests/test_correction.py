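"""kappa identities, closed forms and frame behaviour."""

import math

import numpy as np
import pytest

from xfiquant.correction import (
    DetectorGeometry, ScanGeometry, candidate_origins, combined_transmission,
    compact_detectors, correction_factor, correction_map,
)
from xfiquant.physics_tables import mass_attenuation
from xfiquant.voxel_model import CTVolume, MaterialVolume, build_material_map, default_hu_table


def _volume(hu_value, shape=(20, 20, 20), spacing=0.5):
    hu = np.full(shape, float(hu_value), dtype=np.float32)
    origin = tuple(-(n - 1) / 2 * spacing for n in shape)
    return build_material_map(CTVolume(hu, (spacing,) * 3, origin))


@pytest.fixture()
def air_volume():
    return _volume(-1000.0)


@pytest.fixture()
def tissue_volume():
    return _volume(0.0)


@pytest.fixture()
def detectors():
    return compact_detectors()


class TestCandidateOrigins:
    def test_beam_missing_sample_gives_empty_list(self, tissue_volume):
        pts, w, t = candidate_origins(tissue_volume, (100.0, 0.0), 59.0)
        assert len(pts) == 0 and len(w) == 0

    def test_air_only_column_gives_empty_list(self, air_volume):
        pts, w, _ = candidate_origins(air_volume, (0.0, 0.0), 59.0)
        assert len(pts) == 0

    def test_weights_normalized_and_decay_with_depth(self, tissue_volume):
        pts, w, t = candidate_origins(tissue_volume, (0.0, 0.0), 59.0)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.diff(w) < 0)            # front (entry) voxel heaviest
        assert np.all(np.diff(pts[:, 2]) > 0)    # ordered along the beam

    def test_near_vacuum_density_gives_uniform_weights(self, tissue_volume):
        vol = MaterialVolume(tissue_volume.labels,
                             np.full(tissue_volume.shape, 1e-9),
                             tissue_volume.spacing, tissue_volume.origin,
                             tissue_volume.materials)
        _, w, _ = candidate_origins(vol, (0.0, 0.0), 59.0)
        assert np.allclose(w, 1.0 / len(w), rtol=1e-6)


class TestCombinedTransmission:
    def test_origin_on_surface_facing_detector_in_vacuum(self, air_volume):
        det = DetectorGeometry.at_angle("d", 90.0, 4.0)
        t = combined_transmission((0.0, 0.0, -4.9), (0.0, 0.0), det,
                                  air_volume, 59.0, 9.713)
        # the ~10 mm of in-grid air itself absorbs a few tenths of a percent
        assert t == pytest.approx(1.0, abs=7e-3)

    def test_slab_closed_form_at_depth(self, tissue_volume):
        # origin at cube center; the exit ray to the +x detector is exactly
        # perpendicular, so both path lengths have closed forms
        det = DetectorGeometry.at_angle("d", 90.0, 4.0)
        origin = (0.0, 0.0, 0.0)   # 5 mm into the 10 mm cube entered at z=-5
        t = combined_transmission(origin, (0.0, 0.0), det, tissue_volume, 59.0, 10.0)
        mu_b = mass_attenuation("soft_tissue", 59.0)
        mu_l = mass_attenuation("soft_tissue", 10.0)
        expect = math.exp(-mu_b * 0.5) * math.exp(-mu_l * 0.5)  # 5 mm in, 5 mm out
        assert t == pytest.approx(expect, rel=1e-6)

    def test_asymmetric_in_beam_and_line_energy(self, tissue_volume):
        det = DetectorGeometry.at_angle("d", 90.0, 4.0)
        origin = (0.0, 0.0, -3.0)
        t1 = combined_transmission(origin, (0.0, 0.0), det, tissue_volume, 59.0, 10.0)
        t2 = combined_transmission(origin, (0.0, 0.0), det, tissue_volume, 10.0, 59.0)
        assert t1 != pytest.approx(t2, rel=1e-3)


class TestCorrectionFactor:
    def test_vacuum_kappa_exactly_one(self, air_volume, detectors):
        res = correction_factor((0.0, 0.0), detectors, air_volume, 59.0, 9.713)
        assert res["kappa"] == 1.0
        assert np.all(res["kappa_det"] == 1.0)

    def test_kappa_at_least_one_everywhere(self, tissue_volume, detectors):
        res = correction_factor((1.0, -2.0), detectors, tissue_volume, 59.0, 9.713)
        assert res["kappa"] >= 1.0
        assert np.all(res["kappa_det"] >= 1.0)

    def test_kappa_increases_when_density_doubles(self, tissue_volume, detectors):
        res1 = correction_factor((0.0, 0.0), detectors, tissue_volume, 59.0, 9.713)
        dense = MaterialVolume(tissue_volume.labels, tissue_volume.density * 2,
                               tissue_volume.spacing, tissue_volume.origin,
                               tissue_volume.materials)
        res2 = correction_factor((0.0, 0.0), detectors, dense, 59.0, 9.713)
        assert res2["kappa"] > res1["kappa"]
        assert np.all(res2["kappa_det"] >= res1["kappa_det"])

    def test_requires_detectors(self, tissue_volume):
        with pytest.raises(ValueError, match="detector"):
            correction_factor((0.0, 0.0), [], tissue_volume, 59.0, 9.713)


class TestCorrectionMap:
    def _scan(self, n=5, extent=12.0):
        return ScanGeometry.raster(extent, extent, n, n, beam_energy_kev=59.0,
                                   beam_area_mm2=1.0, flux_ph_s=1e8, dwell_s=1.0)

    def test_half_tissue_half_air_footprint(self, detectors):
        hu = np.full((24, 24, 20), -1000.0, dtype=np.float32)
        hu[:12] = 0.0   # tissue on the low-x half
        origin = tuple(-(n - 1) / 2 * 0.5 for n in (24, 24, 20))
        vol = build_material_map(CTVolume(hu, (0.5,) * 3, origin))
        cmap = correction_map(self._scan(6, 11.0), detectors, vol, 9.713)
        left = cmap.kappa[:, :3]
        right = cmap.kappa[:, 3:]
        assert np.all(left > 1.0)
        assert np.allclose(right, 1.0)

    def test_mirror_symmetric_phantom_gives_mirror_kappa(self, tissue_volume):
        # detectors placed symmetrically about x=0; phantom symmetric in x
        dets = [DetectorGeometry.at_angle("p", 90.0, 4.0),
                DetectorGeometry.at_angle("m", -90.0, 4.0)]
        cmap = correction_map(self._scan(5, 8.0), dets, tissue_volume, 9.713)
        np.testing.assert_allclose(cmap.kappa, cmap.kappa[:, ::-1], rtol=1e-9)
        np.testing.assert_allclose(cmap.kappa_det[0], cmap.kappa_det[1][:, ::-1],
                                   rtol=1e-9)

    def test_bone_rod_casts_kappa_shadow_toward_side_detector(self):
        hu = np.full((40, 20, 20), 0.0, dtype=np.float32)
        # bone rod along y at x ~ +3.5 mm, between sample center and +x detector
        hu[26:30, :, 8:12] = 800.0
        origin = tuple(-(n - 1) / 2 * 0.5 for n in (40, 20, 20))
        vol = build_material_map(CTVolume(hu, (0.5,) * 3, origin))
        det = [DetectorGeometry.at_angle("px", 90.0, 4.0)]
        cmap = correction_map(self._scan(7, 14.0), det, vol, 9.713)
        # scan columns on the -x side of the rod see the rod in their exit path
        shadowed = cmap.kappa[3, 1]   # x ~ -4 mm, behind the rod
        clear = cmap.kappa[3, 5]      # x ~ +4 mm, in front of the rod
        assert shadowed > clear * 1.5

    def test_frame_mismatch_raises_before_compute(self, tissue_volume, detectors):
        scan = ScanGeometry.raster(5.0, 5.0, 3, 3, beam_energy_kev=59.0,
                                   beam_area_mm2=1.0, flux_ph_s=1e8, dwell_s=1.0)
        scan.x_mm = scan.x_mm + 500.0   # e.g. meters-vs-mm confusion
        with pytest.raises(ValueError, match="world frame"):
            correction_map(scan, detectors, tissue_volume, 9.713)
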