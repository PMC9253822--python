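from collections import deque

import numpy as np
import pytest

from residuemap.calibration import ClassMap, calibrate_map, label_components


def flood_fill_census(labels, class_id, connectivity=4):
    """Independent BFS flood fill returning sorted component sizes."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(labels, dtype=bool)
    sizes = []
    r, c = labels.shape
    for i in range(r):
        for j in range(c):
            if labels[i, j] != class_id or seen[i, j]:
                continue
            size = 0
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                y, x = queue.popleft()
                size += 1
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if (0 <= ny < r and 0 <= nx < c and not seen[ny, nx]
                            and labels[ny, nx] == class_id):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            sizes.append(size)
    return sorted(sizes)


def _map(labels):
    return ClassMap(np.asarray(labels, dtype=np.int64))


class TestLabelComponents:
    def test_diagonal_touch_depends_on_connectivity(self):
        m = _map([[1, 0], [0, 1]])
        assert label_components(m, 1, connectivity=4).n_components == 2
        assert label_components(m, 1, connectivity=8).n_components == 1

    def test_single_class_map_is_one_component(self):
        m = _map(np.full((6, 9), 2))
        lab = label_components(m, 2)
        assert lab.n_components == 1
        assert lab.sizes[0] == 54

    def test_absent_class_gives_empty_labeling(self):
        assert label_components(_map([[1]]), 3).n_components == 0

    def test_census_matches_flood_fill(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 3, size=(30, 30))
            for cid in (1, 2):
                lab = label_components(ClassMap(labels), cid)
                assert sorted(lab.sizes.tolist()) == flood_fill_census(labels, cid)

    def test_sizes_sum_to_class_pixels(self, rng):
        labels = rng.integers(0, 4, size=(25, 25))
        lab = label_components(ClassMap(labels), 2)
        assert lab.sizes.sum() == (labels == 2).sum()


class TestCalibrateMap:
    def test_noop_when_all_components_large(self):
        labels = np.ones((10, 10), dtype=np.int64)
        labels[:, 5:] = 2
        out = calibrate_map(_map(labels), order=(1, 2), threshold=4)
        assert np.array_equal(out.labels, labels)

    def test_small_blob_absorbed_by_surrounding_class(self):
        labels = np.full((10, 10), 2, dtype=np.int64)
        labels[4, 4:7] = 1  # 3-pixel blob
        out = calibrate_map(_map(labels), order=(1,), threshold=4)
        assert (out.labels == 2).all()
        assert sorted(
            label_components(out, 2).sizes.tolist()
        ) == flood_fill_census(out.labels, 2)

    def test_threshold_boundary_keeps_exact_size(self):
        labels = np.full((10, 10), 2, dtype=np.int64)
        labels[4, 3:7] = 1  # exactly 4 pixels
        out = calibrate_map(_map(labels), order=(1,), threshold=4)
        assert (out.labels == 1).sum() == 4

    def test_idempotent(self, rng):
        for seed in range(5):
            labels = np.random.default_rng(seed).integers(1, 4, size=(40, 40))
            m = _map(labels)
            once = calibrate_map(m, threshold=10)
            twice = calibrate_map(once, threshold=10)
            assert np.array_equal(once.labels, twice.labels)

    def test_pixel_count_conserved_and_no_nodata_created(self, rng):
        labels = rng.integers(0, 4, size=(40, 40))
        m = _map(labels)
        out = calibrate_map(m, threshold=15)
        assert out.labels.shape == labels.shape
        assert (out.labels == 0).sum() == (labels == 0).sum()
        assert np.array_equal(
            (out.labels == 0), (labels == 0)
        )  # nodata never consumed either

    def test_later_classes_see_earlier_reassignments(self):
        # a small class-2 hole absorbed into class 3 first makes the class-3
        # region just large enough (8 -> 9 pixels) to survive its own later
        # cleaning step at threshold 9
        labels = np.full((8, 8), 1, dtype=np.int64)
        labels[2:5, 2:5] = 3
        labels[3, 3] = 2
        out = calibrate_map(_map(labels), order=(2, 3), threshold=9)
        assert (out.labels[2:5, 2:5] == 3).all()

    def test_until_stable_removes_all_small_components(self, rng):
        labels = rng.integers(1, 4, size=(50, 50))
        out = calibrate_map(
            _map(labels), order=(2, 3, 1), threshold=8, until_stable=True
        )
        for cid in (1, 2, 3):
            lab = label_components(out, cid)
            if lab.n_components:
                assert lab.sizes.min() >= 8

    def test_absent_class_warns_and_continues(self):
        with pytest.warns(UserWarning, match="absent"):
            out = calibrate_map(_map(np.ones((5, 5), dtype=np.int64)), order=(9, 1))
        assert (out.labels == 1).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            calibrate_map(_map(np.ones((3, 3), dtype=np.int64)), threshold=0)
        with pytest.raises(ValueError):
            calibrate_map(_map(np.ones((3, 3), dtype=np.int64)), order=())

    def test_provenance_records_parameters(self):
        out = calibrate_map(_map(np.ones((5, 5), dtype=np.int64)), order=(1,), threshold=3)
        assert any("threshold=3" in p for p in out.provenance)
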