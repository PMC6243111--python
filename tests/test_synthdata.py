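"""Phantom generator: tensor fields, DWI, lesions, longitudinal subjects."""

import numpy as np
import pytest

from peritract import diffusion as dif
from peritract import synthdata as sd


class TestScheme:
    def test_default_is_single_shell_64_directions(self):
        scheme = sd.make_scheme()
        assert scheme.n_directions == 64
        assert set(np.unique(scheme.bvals)) == {0.0, 1000.0}
        norms = np.linalg.norm(scheme.bvecs[1:], axis=1)
        assert np.allclose(norms, 1.0, atol=1e-12)


class TestTensorPhantom:
    def test_straight_bundle_principal_axis(self):
        spec = sd.PhantomSpec(shape=(24, 12, 12), voxel_size=2.0,
                              bundles=[sd.BundleDescriptor(
                                  origin=(4, 12, 12), extent_mm=40,
                                  radius_mm=6.0)])
        field, mask, _ = sd.make_tensor_phantom(spec)
        evals, evecs = field.eigensystem()
        e1 = evecs[..., :, 0][mask]
        assert np.allclose(np.abs(e1 @ [1, 0, 0]), 1.0, atol=1e-9)

    def test_helix_tangent_alignment(self):
        spec = sd.PhantomSpec(shape=(30, 30, 30), voxel_size=2.0,
                              bundles=[sd.BundleDescriptor(
                                  kind="helix", origin=(30, 20, 5),
                                  arc_radius=15.0, helix_pitch=6.0,
                                  extent_mm=80.0, radius_mm=4.0)])
        field, mask, cls = sd.make_tensor_phantom(spec)
        cl = cls[0].points
        tangents = np.gradient(cl, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        from scipy.spatial import cKDTree
        tree = cKDTree(cl)
        _, evecs = field.eigensystem()
        idx = np.argwhere(mask)
        world = idx * 2.0
        _, nearest = tree.query(world)
        e1 = evecs[tuple(idx.T)][..., :, 0]
        cosang = np.abs(np.einsum("ij,ij->i", e1, tangents[nearest]))
        assert np.all(cosang >= np.cos(np.deg2rad(5.0)))

    def test_background_below_tracking_stop(self):
        spec = sd.PhantomSpec(shape=(16, 16, 16))
        field, mask, _ = sd.make_tensor_phantom(spec)
        fa = dif.tensor_scalars(field).fa
        assert np.all(fa[~mask] < 0.17)


@pytest.fixture(scope="module")
def small_field():
    spec = sd.PhantomSpec(shape=(12, 8, 8), voxel_size=2.0,
                          bundles=[sd.BundleDescriptor(
                              origin=(2, 8, 8), extent_mm=20,
                              radius_mm=4.0)])
    return sd.make_tensor_phantom(spec)[0]


class TestMakeDwi:
    def test_noiseless_roundtrip(self, small_field):
        scheme = sd.make_scheme()
        dwi = sd.make_dwi(small_field, scheme, snr=None)
        fit = dif.fit_tensor(dwi, scheme, np.ones(small_field.shape, bool))
        assert np.max(np.abs(fit.tensor - small_field.tensor)) < 1e-8

    def test_b0_near_s0(self, small_field):
        scheme = sd.make_scheme()
        dwi = sd.make_dwi(small_field, scheme, s0=1000.0, snr=50.0, seed=1)
        b0 = dwi[..., 0]
        assert abs(b0.mean() - 1000.0) < 3 * 1000 / 50

    def test_seed_determinism(self, small_field):
        scheme = sd.make_scheme()
        a = sd.make_dwi(small_field, scheme, snr=20.0, seed=9)
        b = sd.make_dwi(small_field, scheme, snr=20.0, seed=9)
        c = sd.make_dwi(small_field, scheme, snr=20.0, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestPlantDeltaFa:
    def test_exact_fa_shift(self):
        spec = sd.PhantomSpec(shape=(16, 12, 12), voxel_size=2.0,
                              bundles=[sd.BundleDescriptor(
                                  origin=(2, 12, 12), extent_mm=28,
                                  radius_mm=6.0)])
        field, mask, _ = sd.make_tensor_phantom(spec)
        region = mask.copy()
        planted = sd.plant_delta_fa(field, region, -0.10)
        fa0 = dif.tensor_scalars(field).fa
        fa1 = dif.tensor_scalars(planted).fa
        diff = fa1[mask] - fa0[mask]
        assert np.allclose(diff, -0.10, atol=1e-9)
        # mean diffusivity preserved
        md0 = dif.tensor_scalars(field).md
        md1 = dif.tensor_scalars(planted).md
        assert np.allclose(md0[mask], md1[mask], rtol=1e-9)

    def test_outside_region_untouched(self):
        spec = sd.PhantomSpec(shape=(16, 12, 12), voxel_size=2.0,
                              bundles=[sd.BundleDescriptor(
                                  origin=(2, 12, 12), extent_mm=28,
                                  radius_mm=5.0)])
        field, mask, _ = sd.make_tensor_phantom(spec)
        planted = sd.plant_delta_fa(field, np.zeros(spec.shape, bool), -0.1)
        assert np.allclose(planted.tensor, field.tensor, atol=1e-15)


class TestLesionVolumes:
    def test_truth_labels_by_construction(self):
        scene = [sd.LesionSpec(centre_mm=(20, 30, 30), acute_ring=True,
                               chronic_ring=False),
                 sd.LesionSpec(centre_mm=(40, 30, 30), acute_ring=True,
                               chronic_ring=True),
                 sd.LesionSpec(centre_mm=(30, 40, 30), acute_ring=False)]
        *_, truth = sd.make_lesion_volumes(scene, (60, 60, 60), np.eye(4), 0)
        assert list(truth.etiology_truth) == \
            ["traumatic", "non_traumatic", "indeterminate"]

    def test_detector_recovers_planted_centroid(self):
        from peritract import cmbdetect as cmb
        scene = [sd.LesionSpec(centre_mm=(30, 28, 32), radius_mm=2.5)]
        swi, _, _, mask, _ = sd.make_lesion_volumes(scene, (60, 60, 60),
                                                    np.eye(4), seed=4)
        kept = [r for r in cmb.detect_cmbs(swi, mask, np.eye(4))
                if r.mars_label != "rejected"]
        assert len(kept) == 1
        assert np.all(np.abs(kept[0].centroid_world - [30, 28, 32]) <= 1.0)


class TestLongitudinalSubject:
    def test_noise_off_sessions_identical(self):
        phantom = sd.PhantomSpec(shape=(16, 12, 12), voxel_size=2.0, snr=None,
                                 bundles=[sd.BundleDescriptor(
                                     origin=(2, 12, 12), extent_mm=24,
                                     radius_mm=4.0)])
        spec = sd.LongitudinalSpec(rotation_deg=0.0,
                                   translation_mm=(0, 0, 0), delta_fa=0.0,
                                   lesion_noise_sd=0.0, seed=0)
        sessions, _ = sd.make_longitudinal_subject(spec, phantom)
        assert np.array_equal(sessions[0].dwi, sessions[1].dwi)
        assert np.array_equal(sessions[0].swi, sessions[1].swi)

    def test_planted_delta_on_truth_fa_maps(self):
        phantom = sd.PhantomSpec(shape=(24, 16, 16), voxel_size=2.0, snr=None,
                                 bundles=[sd.BundleDescriptor(
                                     origin=(4, 16, 16), extent_mm=40,
                                     radius_mm=6.0)])
        lesion = sd.LesionSpec(centre_mm=(24, 16, 16), affected=True)
        spec = sd.LongitudinalSpec(rotation_deg=0.0, translation_mm=(0, 0, 0),
                                   delta_fa=-0.1, region_radius_mm=10.0,
                                   lesions=[lesion], seed=0)
        sessions, truth = sd.make_longitudinal_subject(spec, phantom)
        fa1, fa2 = sessions[0].fa, sessions[1].fa
        world = np.argwhere(sessions[0].bundle_mask) * 2.0
        in_region = np.linalg.norm(world - [24, 16, 16], axis=1) <= 10.0
        vox = np.argwhere(sessions[0].bundle_mask)[in_region]
        diff = fa2[tuple(vox.T)] - fa1[tuple(vox.T)]
        assert np.mean(diff) == pytest.approx(-0.10, abs=0.01)

    def test_motion_recovered_by_matching(self):
        # varying-curvature bundle: arcs/helices are self-similar under
        # rotation about their own axis, so the transform would be
        # unidentifiable; the sine course pins the correspondence
        phantom = sd.PhantomSpec(shape=(40, 40, 10), voxel_size=2.0, snr=30.0,
                                 bundles=[sd.BundleDescriptor(
                                     kind="sine", origin=(8, 20, 10),
                                     extent_mm=64.0, radius_mm=5.0,
                                     sine_amplitude=8.0, sine_period=45.0)])
        spec = sd.LongitudinalSpec(rotation_deg=2.0, rotation_axis=(0, 0, 1),
                                   translation_mm=(1.0, 0.5, 0.0), seed=3)
        sessions, truth = sd.make_longitudinal_subject(spec, phantom)
        from peritract import pipeline as pl
        cfg = pl.PipelineConfig(compute_uncertainty=False, min_mean_fa=0.8)
        pkg = pl.analyze_subject(sessions, config=cfg)
        assert pkg.match_results, "no bundles matched"
        res = pkg.match_results[0][0]
        rot_err = np.linalg.norm(res.global_rotation - truth.rotation)
        t_err = np.linalg.norm(res.global_translation - truth.translation)
        assert rot_err < 1e-2
        # translation error is floored by between-session reconstruction
        # differences (the confound the uncertainty radius measures)
        assert t_err < 0.75

    def test_motion_bounds_enforced(self):
        with pytest.raises(ValueError):
            sd.LongitudinalSpec(rotation_deg=45.0)


class TestCohortManifest:
    def test_deterministic_for_same_master_seed(self):
        phantom = sd.PhantomSpec()
        a = sd.make_cohort({"mtbi": 3, "old_hc": 2}, phantom, None, 7)
        b = sd.make_cohort({"mtbi": 3, "old_hc": 2}, phantom, None, 7)
        assert a.equals(b)

    def test_arm_sizes_and_affected_counts(self):
        phantom = sd.PhantomSpec()
        m = sd.make_cohort({"mtbi": 4, "old_hc": 3, "young_hc": 2}, phantom,
                           None, 1, affected_fraction=0.5, n_lesions=4)
        assert (m.arm == "mtbi").sum() == 4
        assert (m.arm == "old_hc").sum() == 3
        assert m.loc[m.arm == "mtbi", "n_affected"].eq(2).all()
        assert m.loc[m.arm != "mtbi", "n_lesions"].eq(0).all()
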