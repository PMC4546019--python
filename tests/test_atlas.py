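"""Atlas construction, registration, fill policy and the inpainting pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from muinpaint.atlas import (
    Atlas,
    FillPolicy,
    build_atlas,
    fill_masked_voids,
    inpaint,
    register_to_atlas,
    warp_mask_to_patient,
)
from muinpaint.detect import AIR_THRESHOLD, detect_voids
from muinpaint.grids import SOFT_TISSUE_MU, MuMap, VoxelGrid3D
from muinpaint.phantom import ArtifactSpec, PhantomSpec, inject_artifact, make_phantom


def dice(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return 2 * (a & b).sum() / (a.sum() + b.sum())


class TestBuildAtlas:
    def test_single_subject_mean_is_that_subject(self, phantom0):
        atlas = build_atlas([phantom0.water_image])
        np.testing.assert_array_equal(atlas.mean_water.values, phantom0.water_image.values)

    def test_duplicated_subject_leaves_mean_unchanged(self, population30):
        waters = [p.water_image for p in population30[:5]]
        a = build_atlas(waters)
        b = build_atlas(waters + [waters[0], waters[0]])
        manual = (np.sum([w.values for w in waters], axis=0) + 2 * waters[0].values) / 7
        np.testing.assert_allclose(b.mean_water.values, manual, rtol=1e-12)
        np.testing.assert_allclose(
            a.mean_water.values,
            np.mean([w.values for w in waters], axis=0),
            rtol=1e-12,
        )

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            build_atlas([])

    def test_air_core_matches_true_oral_cavity(self, atlas30, default_spec):
        # population air core vs the jitter-free phantom's cavity label
        ph = make_phantom(default_spec.with_(jitter_std_mm=0.0, water_noise_sigma=0.0))
        lab, n = ndimage.label(ph.air_cavity_mask.values)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, n + 1))
        cavity = lab == (np.argmax(sizes) + 1)
        assert dice(atlas30.oral_cavity_mask.values, cavity) >= 0.8

    def test_fill_template_excludes_anatomical_air(self, atlas30, population30):
        for subject in population30[:5]:
            cav = subject.air_cavity_mask.values.astype(bool)
            frac = (cav & atlas30.fill_mask.values.astype(bool)).sum() / cav.sum()
            assert frac < 0.10


class TestRegistration:
    def test_self_registration_is_identity(self, atlas30):
        patient = atlas30.mean_water
        t = register_to_atlas(patient, atlas30)
        matrix = np.array(t.GetParameters()[:9]).reshape(3, 3)
        translation = np.array(t.GetParameters()[9:])
        # account for the center: evaluate displacement of a few points
        pts = [(120.0, 120.0, 70.0), (60.0, 160.0, 40.0), (160.0, 80.0, 100.0)]
        for p in pts:
            q = np.array(t.TransformPoint(p))
            assert np.linalg.norm(q - np.array(p)) < 0.5
        assert np.allclose(matrix, np.eye(3), atol=0.01)

    def test_known_translation_recovered(self, atlas30):
        shift = np.array([5.0, -3.0, 2.0])
        moved = VoxelGrid3D(
            atlas30.mean_water.values,
            atlas30.mean_water.spacing,
            tuple(np.array(atlas30.mean_water.origin) + shift),
        )
        t = register_to_atlas(moved, atlas30)
        # the same anatomy sits at world x + shift: mapping patient -> atlas
        # must subtract the shift
        p = np.array((125.0, 160.0, 55.0))
        q = np.array(t.TransformPoint(tuple(p + shift)))
        assert np.linalg.norm(q - p) < 0.5

    def test_converges_with_large_outer_artifact(self, phantom0, atlas30):
        ph = inject_artifact(
            phantom0, ArtifactSpec(artifact_class="outer", target_volume_ml=300.0, seed=3)
        )
        t = register_to_atlas(ph.water_image, atlas30)
        for p in [(120.0, 120.0, 70.0), (80.0, 150.0, 40.0)]:
            q = np.array(t.TransformPoint(p))
            assert np.linalg.norm(q - np.array(p)) < 3.0

    def test_identity_warp_roundtrip(self, atlas30, phantom0):
        warped = warp_mask_to_patient(atlas30.fill_mask, None, phantom0.water_image)
        np.testing.assert_array_equal(
            warped.values.astype(bool), atlas30.fill_mask.values.astype(bool)
        )


def _toy_case(n_comp_voxels=20, n_overlap=10):
    """A single-component mu-map and an atlas whose template overlaps it."""
    vals = np.full((12, 12, 6), 0.1)
    vals[1:6, 1:5, 2:3] = 0.0  # 20-voxel void
    grid = VoxelGrid3D(vals, (2.6, 2.6, 3.1))
    mu = MuMap(grid, grid.with_values(np.ones(grid.shape, dtype=bool)), "dixon")
    voids = detect_voids(mu)
    assert voids.components[0].voxel_count == n_comp_voxels
    template = np.zeros(grid.shape, dtype=bool)
    flat = np.argwhere(voids.labels.values > 0)[:n_overlap]
    template[tuple(flat.T)] = True
    water = grid.with_values(np.where(vals > 0, 100.0, 0.0))
    atlas = Atlas(
        mean_water=water,
        oral_cavity_mask=grid.with_values(template | True),  # non-empty
        fill_mask=grid.with_values(template),
        n_subjects=1,
    )
    return mu, voids, atlas


class TestFillPolicy:
    @pytest.mark.parametrize(
        "n_overlap,action",
        [(17, "completed"), (10, "kept_partial"), (1, "reversed")],
    )
    def test_overlap_fraction_drives_action(self, n_overlap, action):
        # 20-voxel component: 85% / 50% / 5% overlap
        mu, voids, atlas = _toy_case(n_overlap=n_overlap)
        out, report = fill_masked_voids(mu, voids, atlas, None)
        fill = report.fills[0]
        assert fill.action == action
        if action == "completed":
            assert (out.values[voids.mask(1)] == SOFT_TISSUE_MU).all()
            assert fill.voxels_changed == 20
        elif action == "kept_partial":
            assert fill.voxels_changed == n_overlap
            changed = out.values != mu.values
            assert changed.sum() == n_overlap
        else:
            np.testing.assert_array_equal(out.values, mu.values)

    def test_exact_threshold_boundaries_are_strict(self):
        # fractions exactly 0.80 and 0.10 stay in the kept_partial band
        for n_overlap, action in [(16, "kept_partial"), (17, "completed"),
                                  (2, "kept_partial"), (1, "reversed")]:
            mu, voids, atlas = _toy_case(n_overlap=n_overlap)
            _, report = fill_masked_voids(mu, voids, atlas, None)
            assert report.fills[0].action == action, (n_overlap, report.fills[0])

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            FillPolicy(complete_threshold=0.1, reverse_threshold=0.5)


class TestInpaint:
    def test_artifact_free_is_bitwise_identity(self, phantom0, atlas30):
        res = inpaint(
            phantom0.mu_dixon, phantom0.activity_truth, phantom0.water_image, atlas30
        )
        np.testing.assert_array_equal(res.mu_inpainted.values, phantom0.mu_dixon.values)
        assert res.n_changed == 0

    def test_inner_void_filled_sinuses_untouched(self, phantom0, atlas30):
        ph = inject_artifact(
            phantom0, ArtifactSpec(artifact_class="inner", target_volume_ml=6.0, seed=2)
        )
        res = inpaint(ph.mu_dixon, ph.activity_truth, ph.water_image, atlas30)
        void = ph.void_truth_mask.values.astype(bool)
        assert np.isclose(res.mu_inpainted.values[void], SOFT_TISSUE_MU).mean() >= 0.9
        # anatomical air (cavity + sinuses) stays air
        anat_air = ph.air_cavity_mask.values.astype(bool)
        assert (res.mu_inpainted.values[anat_air] < AIR_THRESHOLD).all()

    def test_sinus_connected_to_void_is_preserved(self, phantom0, atlas30):
        # void grown into the sinus region: the sinus air itself must survive
        spec = phantom0.spec
        cx = (spec.shape[0] - 1) / 2 * spec.spacing[0]
        cy = (spec.shape[1] - 1) / 2 * spec.spacing[1]
        ph = inject_artifact(
            phantom0,
            ArtifactSpec(
                artifact_class="inner",
                target_volume_ml=12.0,
                centroid=(cx - 17.0, cy + 38.0, 74.0),
                connect_to_air=True,
                seed=6,
            ),
        )
        res = inpaint(ph.mu_dixon, ph.activity_truth, ph.water_image, atlas30)
        sinus_like = ph.air_cavity_mask.values.astype(bool)
        assert (res.mu_inpainted.values[sinus_like] < AIR_THRESHOLD).all()

    def test_monotone_and_confined_to_voids(self, phantom0, atlas30):
        ph = inject_artifact(
            phantom0, ArtifactSpec(artifact_class="inner", target_volume_ml=10.0, seed=3)
        )
        res = inpaint(ph.mu_dixon, ph.activity_truth, ph.water_image, atlas30)
        assert (res.mu_inpainted.values >= ph.mu_dixon.values).all()
        initial_voids = detect_voids(ph.mu_dixon).union_mask()
        assert (res.changed_mask.values.astype(bool) & ~initial_voids).sum() == 0

    def test_idempotent(self, phantom0, atlas30):
        ph = inject_artifact(
            phantom0, ArtifactSpec(artifact_class="inner", target_volume_ml=6.0, seed=2)
        )
        r1 = inpaint(ph.mu_dixon, ph.activity_truth, ph.water_image, atlas30)
        r2 = inpaint(r1.mu_inpainted, ph.activity_truth, ph.water_image, atlas30)
        np.testing.assert_array_equal(r2.mu_inpainted.values, r1.mu_inpainted.values)

    def test_provenance_marked_inpainted(self, phantom0, atlas30):
        ph = inject_artifact(
            phantom0, ArtifactSpec(artifact_class="inner", target_volume_ml=6.0, seed=2)
        )
        res = inpaint(ph.mu_dixon, ph.activity_truth, ph.water_image, atlas30)
        assert res.mu_inpainted.provenance == "inpainted"
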