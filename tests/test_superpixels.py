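"""Superpixel partition invariants, boundary recall, annotation snapping."""

import numpy as np
import pytest
from scipy import ndimage

import annoloop as al
from annoloop.errors import ShapeError
from annoloop.superpixels import boundary_recall, compute_superpixels, snap_annotation


def brute_force_boundary_recall(sp_labels, gt, tolerance):
    """Independent oracle: explicit double loop over boundary pixels.

    Ground-truth boundary: foreground pixels with a background 4-neighbour.
    Superpixel boundary: pixels with a differently-labelled 4-neighbour
    (either side). Recall: fraction of gt boundary pixels whose Euclidean
    distance to the nearest superpixel boundary pixel is <= tolerance.
    """
    h, w = gt.shape

    def neighbours(r, c):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield rr, cc

    gt_b = [(r, c) for r in range(h) for c in range(w)
            if gt[r, c] and any(not gt[rr, cc] for rr, cc in neighbours(r, c))]
    sp_b = [(r, c) for r in range(h) for c in range(w)
            if any(sp_labels[rr, cc] != sp_labels[r, c] for rr, cc in neighbours(r, c))]
    if not gt_b:
        return None
    hits = 0
    for r, c in gt_b:
        if any((r - rr) ** 2 + (c - cc) ** 2 <= tolerance ** 2 for rr, cc in sp_b):
            hits += 1
    return hits / len(gt_b)


@pytest.fixture(scope="module")
def scene_image():
    return al.generate_scene("nuclei", 256, 256, density=600, seed=5).image


class TestComputeSuperpixels:
    def test_single_segment(self, scene_image):
        sp = compute_superpixels(scene_image, n_segments=1)
        assert sp.n_segments == 1
        assert (sp.labels == 0).all()

    def test_segment_count_within_factor_two(self, scene_image):
        sp = compute_superpixels(scene_image, n_segments=200)
        assert 100 <= sp.n_segments <= 400

    def test_partition_connectivity_consecutive(self, scene_image):
        """Every pixel labelled; labels consecutive 0..L-1; every label's
        pixel set is one connected component."""
        for feature_map in (None, np.dstack([scene_image / 255.0] * 2)):
            sp = compute_superpixels(scene_image, feature_map=feature_map, n_segments=60)
            labels = sp.labels
            assert labels.min() == 0
            assert np.array_equal(np.unique(labels), np.arange(sp.n_segments))
            for lab in range(sp.n_segments):
                _, n_comp = ndimage.label(labels == lab, structure=np.ones((3, 3)))
                assert n_comp == 1

    def test_constant_image_grid_partition(self):
        img = np.full((128, 128, 3), 127, dtype=np.uint8)
        sp = compute_superpixels(img, n_segments=16)
        assert (np.bincount(sp.labels.ravel()) > 0).all()
        assert 8 <= sp.n_segments <= 32

    def test_feature_mode_flag_and_alignment(self, scene_image):
        feats = np.random.default_rng(0).random((256, 256, 4))
        sp = compute_superpixels(scene_image, feature_map=feats, n_segments=50)
        assert sp.source == "dl_features"
        with pytest.raises(ShapeError):
            compute_superpixels(scene_image, feature_map=feats[:128], n_segments=50)

    def test_too_many_segments(self, scene_image):
        with pytest.raises(ValueError):
            compute_superpixels(scene_image, n_segments=256 * 256 + 1)


class TestBoundaryRecall:
    def _map(self, labels):
        return al.SuperpixelMap(labels=np.asarray(labels, dtype=np.int32),
                                source="intensity", n_segments_requested=0,
                                compactness=1.0)

    def test_superset_boundaries_give_one(self):
        gt = np.zeros((8, 8), dtype=bool)
        gt[2:6, 2:6] = True
        sp = self._map(gt.astype(int))  # sp boundary == gt boundary
        assert boundary_recall(sp, gt, tolerance=0) == 1.0

    def test_distant_boundaries_give_zero(self):
        gt = np.zeros((16, 16), dtype=bool)
        gt[1:4, 1:4] = True
        labels = np.zeros((16, 16), dtype=int)
        labels[:, 12:] = 1  # only boundary at column 11/12, > 2 px away
        assert boundary_recall(self._map(labels), gt, tolerance=2) == 0.0

    def test_empty_gt_boundary_is_undefined(self):
        sp = self._map(np.zeros((8, 8), dtype=int))
        assert boundary_recall(sp, np.zeros((8, 8), dtype=bool)) is None

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_8x8(self, seed):
        rng = np.random.default_rng(seed)
        gt = rng.random((8, 8)) > 0.6
        labels = rng.integers(0, 3, size=(8, 8))
        sp = self._map(labels)
        for tol in (0, 1, 2):
            expected = brute_force_boundary_recall(labels, gt, tol)
            got = boundary_recall(sp, gt, tolerance=tol)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)


class TestSnapAnnotation:
    def test_single_seed_selects_its_superpixel(self, scene_image):
        sp = compute_superpixels(scene_image, n_segments=30)
        lab = sp.labels[40, 40]
        mask = snap_annotation({(40, 40)}, sp)
        assert np.array_equal(mask, sp.labels == lab)

    def test_seeds_on_every_label_select_everything(self, scene_image):
        sp = compute_superpixels(scene_image, n_segments=20)
        seeds = []
        for lab in range(sp.n_segments):
            rr, cc = np.nonzero(sp.labels == lab)
            seeds.append((int(rr[0]), int(cc[0])))
        assert snap_annotation(seeds, sp).all()

    def test_duplicate_seeds_idempotent(self, scene_image):
        sp = compute_superpixels(scene_image, n_segments=30)
        a = snap_annotation([(10, 10)], sp)
        b = snap_annotation([(10, 10), (10, 10)], sp)
        assert np.array_equal(a, b)

    def test_bad_seeds(self, scene_image):
        sp = compute_superpixels(scene_image, n_segments=30)
        with pytest.raises(ValueError):
            snap_annotation([], sp)
        with pytest.raises(ValueError):
            snap_annotation([(999, 0)], sp)


def test_learned_features_adhere_better_under_noise():
    """After fine-tuning, feature-space superpixels adhere to true structure
    boundaries better than colour superpixels when the stain signal is
    noisy — the regime where learned features matter. Sign test over 5
    seeded scenes at equal segment budget: the learned features must win
    on every scene (one-sided p = 1/32 < 0.05)."""
    from conftest import TINY_CFG, scene_patches

    noise = 0.45
    train_scene = al.generate_scene("nuclei", 256, 256, density=600, seed=11,
                                    noise=noise)
    patches = scene_patches(train_scene)
    model = al.build_model(TINY_CFG, seed=3)
    model = al.pretrain_autoencoder(model, patches, epochs=2, seed=3)
    model = al.finetune(model, patches, epochs=30, seed=3)

    wins = 0
    for seed in range(30, 35):
        scene = al.generate_scene("nuclei", 256, 256, density=600, seed=seed,
                                  noise=noise)
        gt = scene.gt_binary()
        sp_int = compute_superpixels(scene.image, n_segments=120)
        feats = al.pixel_features(model, scene.image)
        sp_dl = compute_superpixels(scene.image, feature_map=feats, n_segments=120)
        if boundary_recall(sp_dl, gt, tolerance=2) > boundary_recall(sp_int, gt, tolerance=2):
            wins += 1
    assert wins == 5
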