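"""Tests for vessel extraction, candidate masking and FOV handling."""

import numpy as np
import pytest

import eigenfundus as ef
from eigenfundus.masking import (
    CandidateMask,
    estimate_fov_mask,
    fill_fov_border,
    fovea_annulus_prior,
    intensity_cluster_candidates,
    mask_from_vessels,
    matched_filter_vessels,
    VesselTree,
    _footprint_counts,
)
from eigenfundus.matching import GridGeometry, Localization


@pytest.fixture(scope="module")
def scene_with_masks():
    """A default synthetic scene plus its derived vessel tree and geometry."""
    image, truth = ef.make_test_scenes(1, rng_seed=21)[0]
    image = image.astype(float)
    fov = estimate_fov_mask(image)
    tree = matched_filter_vessels(image, fov_mask=fov)
    return image, truth, fov, tree


class TestMatchedFilter:
    def test_detects_straight_dark_line(self):
        sigma = 2.0
        image = np.full((200, 200), 100.0)
        image[96:104, :] = 40.0  # width 4*sigma
        tree = matched_filter_vessels(image, sigma=sigma, threshold_quantile=0.95)
        line = np.zeros_like(image, dtype=bool)
        line[96:104, :] = True
        assert (tree.binary & line).sum() >= 0.9 * line.sum()

    def test_flat_image_gives_empty_tree(self):
        tree = matched_filter_vessels(np.full((80, 80), 50.0))
        assert not tree.binary.any()
        assert not tree.thick.any()

    def test_thick_subset_of_binary(self, scene_with_masks):
        _, _, _, tree = scene_with_masks
        assert not (tree.thick & ~tree.binary).any()

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            matched_filter_vessels(np.zeros((10, 10)), sigma=0.0)


class TestVesselMasking:
    def test_empty_tree_disc_admits_nothing_fovea_everything(self):
        geom = GridGeometry((200, 200), 50, 25)
        empty = VesselTree(
            binary=np.zeros((200, 200), dtype=bool),
            thick=np.zeros((200, 200), dtype=bool),
        )
        disc = mask_from_vessels(empty, geom, "disc")
        fovea = mask_from_vessels(empty, geom, "fovea")
        assert disc.n_admissible == 0
        assert fovea.n_admissible == fovea.admissible.size

    def test_disc_cell_admissible_fovea_cell_not(self, scene_with_masks):
        image, truth, _, tree = scene_with_masks
        geom = GridGeometry(image.shape, 100, 25)
        disc_mask = mask_from_vessels(tree, geom, "disc")
        fovea_mask = mask_from_vessels(tree, geom, "fovea")
        dc = truth.disc_centre
        cell = geom.corner_to_cell((int(dc[0]) - 50, int(dc[1]) - 50))
        assert disc_mask.admissible[cell]  # arcades converge at the disc
        assert not fovea_mask.admissible[cell]

    def test_rules_disjoint_when_thresholds_ordered(self, scene_with_masks):
        image, _, _, tree = scene_with_masks
        geom = GridGeometry(image.shape, 70, 25)
        disc_mask = mask_from_vessels(tree, geom, "disc", min_thick_pixels=50)
        fovea_mask = mask_from_vessels(tree, geom, "fovea", max_thick_pixels=0)
        assert not (disc_mask.admissible & fovea_mask.admissible).any()

    def test_geometry_mismatch_rejected(self, scene_with_masks):
        _, _, _, tree = scene_with_masks
        with pytest.raises(ef.GeometryError):
            mask_from_vessels(tree, GridGeometry((100, 100), 50, 25), "disc")


class TestIntensityClusters:
    def test_single_bright_blob_disc(self):
        image = np.full((200, 200), 80.0)
        yy, xx = np.mgrid[0:200, 0:200]
        image += 100 * np.exp(-((yy - 60) ** 2 + (xx - 140) ** 2) / (2 * 12**2))
        geom = GridGeometry(image.shape, 50, 25)
        mask = intensity_cluster_candidates(
            image, geom, "disc", quantile=0.99,
            fov_mask=np.ones(image.shape, dtype=bool),
        )
        admitted = np.argwhere(mask.admissible)
        assert len(admitted) > 0
        for cell in admitted:
            r, c = geom.cell_to_corner(tuple(cell))
            assert r <= 60 + 40 and r + 50 >= 60 - 40
            assert c <= 140 + 40 and c + 50 >= 140 - 40

    def test_uniform_image_admits_nothing(self):
        geom = GridGeometry((100, 100), 30, 10)
        mask = intensity_cluster_candidates(
            np.full((100, 100), 55.0), geom, "disc",
            fov_mask=np.ones((100, 100), dtype=bool),
        )
        assert mask.n_admissible == 0

    def test_fovea_dark_cluster_admits_true_cell(self, scene_with_masks):
        image, truth, fov, tree = scene_with_masks
        filled = fill_fov_border(image, fov)
        geom = GridGeometry(image.shape, 70, 25)
        mask = intensity_cluster_candidates(
            filled, geom, "fovea", fov_mask=fov, vessel_mask=tree.binary
        )
        fc = truth.fovea_centre
        cell = geom.corner_to_cell((int(fc[0]) - 35, int(fc[1]) - 35))
        assert mask.admissible[cell]

    def test_empty_fov_rejected(self):
        geom = GridGeometry((50, 50), 20, 10)
        with pytest.raises(ValueError):
            intensity_cluster_candidates(
                np.zeros((50, 50)), geom, "disc",
                fov_mask=np.zeros((50, 50), dtype=bool),
            )


class TestFoveaAnnulus:
    def test_scene_geometry_admits_true_fovea_cell(self, scene_with_masks):
        image, truth, _, _ = scene_with_masks
        geom = GridGeometry(image.shape, 70, 25)
        disc_loc = Localization(
            corner=(int(truth.disc_centre[0]) - 50, int(truth.disc_centre[1]) - 50),
            side=100,
            error=0.0,
        )
        mask = fovea_annulus_prior(
            disc_loc, truth.disc_diameter, geom, tolerance_fraction=0.2
        )
        fc = truth.fovea_centre
        cell = geom.corner_to_cell((int(fc[0]) - 35, int(fc[1]) - 35))
        assert mask.admissible[cell]

    def test_zero_tolerance_ring_is_thin(self):
        geom = GridGeometry((500, 500), 70, 25)
        disc_loc = Localization(corner=(200, 60), side=100, error=0.0)
        mask = fovea_annulus_prior(disc_loc, 80.0, geom, tolerance_fraction=0.0)
        assert mask.n_admissible <= 4  # degenerate band on a coarse grid

    def test_disc_at_corner_clips_without_error(self):
        geom = GridGeometry((500, 500), 70, 25)
        disc_loc = Localization(corner=(0, 0), side=100, error=0.0)
        mask = fovea_annulus_prior(disc_loc, 80.0, geom)
        assert mask.admissible.shape == geom.grid_shape

    def test_nonpositive_diameter_rejected(self):
        geom = GridGeometry((500, 500), 70, 25)
        with pytest.raises(ValueError):
            fovea_annulus_prior(
                Localization(corner=(0, 0), side=100, error=0.0), 0.0, geom
            )


class TestFovBorder:
    def test_full_mask_is_identity(self, rng):
        image = rng.uniform(0, 255, size=(40, 40))
        np.testing.assert_array_equal(
            fill_fov_border(image, np.ones((40, 40), dtype=bool)), image
        )

    def test_filled_border_not_darker_than_fov(self):
        yy, xx = np.mgrid[0:100, 0:100]
        fov = (yy - 50) ** 2 + (xx - 50) ** 2 <= 40**2
        image = np.where(fov, 100.0 + 0.2 * xx, 0.0)
        filled = fill_fov_border(image, fov)
        assert filled.min() >= image[fov].min()
        np.testing.assert_array_equal(filled[fov], image[fov])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fill_fov_border(np.zeros((10, 10)), np.zeros((10, 10), dtype=bool))

    def test_estimated_fov_close_to_truth(self, scene_with_masks):
        image, truth, fov, _ = scene_with_masks
        overlap = (fov & truth.fov_mask).sum() / truth.fov_mask.sum()
        assert overlap > 0.95


class TestMaskAlgebra:
    def test_conjunction_commutative_and_subset(self, scene_with_masks):
        image, _, fov, tree = scene_with_masks
        geom = GridGeometry(image.shape, 70, 25)
        a = mask_from_vessels(tree, geom, "fovea")
        b = intensity_cluster_candidates(image, geom, "fovea", fov_mask=fov,
                                         vessel_mask=tree.binary)
        ab, ba = a & b, b & a
        np.testing.assert_array_equal(ab.admissible, ba.admissible)
        assert not (ab.admissible & ~a.admissible).any()
        assert not (ab.admissible & ~b.admissible).any()

    def test_masking_reduces_scored_patches(self, disc_model, scene_with_masks):
        image, _, _, tree = scene_with_masks
        geom = GridGeometry(image.shape, 100, 25)
        mask = mask_from_vessels(tree, geom, "disc")
        full = ef.build_distance_map(disc_model, image, step=25)
        gated = ef.build_distance_map(disc_model, image, step=25, mask=mask)
        assert gated.n_evaluated <= full.n_evaluated
        assert gated.n_evaluated == mask.n_admissible

    def test_footprint_counts_loop_oracle(self, rng):
        pixel_mask = rng.uniform(size=(60, 60)) < 0.1
        geom = GridGeometry((60, 60), 20, 15)
        counts = _footprint_counts(pixel_mask, geom)
        for i in range(geom.grid_shape[0]):
            for j in range(geom.grid_shape[1]):
                r, c = geom.cell_to_corner((i, j))
                assert counts[i, j] == pixel_mask[r : r + 20, c : c + 20].sum()
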