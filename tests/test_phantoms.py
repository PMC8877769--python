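"""Phantom generator: determinism, exact ground truth, splits, augmentation."""

import numpy as np
import pytest

from fetalhc.errors import InvalidParameterError
from fetalhc.geometry import exact_perimeter, fit_ellipse
from fetalhc.metrics import dice
from fetalhc.phantoms import (
    PhantomConfig,
    SplitSpec,
    augment_training_set,
    generate_dataset,
    generate_phantom,
    kfold_indices,
    render_filled_mask,
    split_dataset,
)
from fetalhc.postproc import postprocess_to_points


class TestGeneratePhantom:
    def test_same_seed_bit_identical(self):
        cfg = PhantomConfig()
        r1 = generate_phantom(42, cfg)
        r2 = generate_phantom(42, cfg)
        assert np.array_equal(r1.image, r2.image)
        assert np.array_equal(r1.gt_mask, r2.gt_mask)
        assert r1.hc_mm == r2.hc_mm
        assert r1.spacing == r2.spacing

    def test_hc_is_exact_perimeter_of_physical_ellipse(self):
        r = generate_phantom(7, PhantomConfig())
        s = r.spacing.sx
        expected = exact_perimeter(r.ellipse.a * s, r.ellipse.b * s)
        assert r.hc_mm == pytest.approx(expected, rel=1e-9)

    def test_mask_consistent_with_ellipse(self):
        r = generate_phantom(3, PhantomConfig())
        assert np.array_equal(r.gt_mask, render_filled_mask(r.ellipse, r.image.shape[0]))

    def test_ground_truth_independent_of_corruption(self):
        clean = PhantomConfig(noise=False, gap_fraction=0.0)
        noisy = PhantomConfig(noise=True, gap_fraction=0.25)
        rc = generate_phantom(5, clean)
        rn = generate_phantom(5, noisy)
        # identical geometry draws (same leading rng stream), different image
        assert rc.ellipse == rn.ellipse
        assert np.array_equal(rc.gt_mask, rn.gt_mask)
        assert rc.hc_mm == rn.hc_mm
        assert not np.array_equal(rc.image, rn.image)

    def test_clean_phantom_end_to_end_recovery(self, clean_config):
        from fetalhc.geometry import hc_mm as to_mm

        r = generate_phantom(11, clean_config)
        fit = fit_ellipse(postprocess_to_points(r.gt_mask))
        assert abs(to_mm(fit, r.spacing) - r.hc_mm) / r.hc_mm <= 0.01

    def test_oversized_axis_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_phantom(0, PhantomConfig(size=64, a_range=(40.0, 41.0)))

    def test_spacing_within_configured_range(self):
        cfg = PhantomConfig()
        for seed in range(30):
            r = generate_phantom(seed, cfg)
            assert cfg.spacing_range[0] <= r.spacing.sx <= cfg.spacing_range[1]


class TestGenerateDataset:
    def test_counts_and_distinct_seeds(self):
        records, table = generate_dataset(25, 7)
        assert len(records) == len(table) == 25
        assert len({r.id for r in records}) == 25
        # distinct derived seeds -> essentially surely distinct geometry
        assert len({r.hc_mm for r in records}) == 25

    def test_same_seed_identical_tables(self):
        _, t1 = generate_dataset(10, 3)
        _, t2 = generate_dataset(10, 3)
        assert t1.equals(t2)

    def test_annotation_hc_self_consistent(self):
        records, table = generate_dataset(20, 1)
        recomputed = [
            exact_perimeter(r.ellipse.a * r.spacing.sx, r.ellipse.b * r.spacing.sx)
            for r in records
        ]
        dev = np.abs(np.asarray(recomputed) - table["HC(mm)"].to_numpy()) / recomputed
        assert dev.max() <= 1e-6


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        records = list(range(999))
        tr, va, te = split_dataset(records, SplitSpec(600, 199, 200, seed=4))
        assert (len(tr), len(va), len(te)) == (600, 199, 200)
        allidx = sorted(tr + va + te)
        assert allidx == list(range(999))

    def test_all_in_train(self):
        tr, va, te = split_dataset(list(range(10)), SplitSpec(10, 0, 0))
        assert len(tr) == 10 and not va and not te

    def test_reproducible(self):
        s = SplitSpec(6, 2, 2, seed=9)
        assert split_dataset(list(range(10)), s) == split_dataset(list(range(10)), s)

    def test_count_mismatch(self):
        with pytest.raises(InvalidParameterError):
            split_dataset(list(range(10)), SplitSpec(5, 2, 2))


@pytest.fixture(scope="module")
def small_records():
    cfg = PhantomConfig(size=128, a_range=(15.0, 40.0))
    return generate_dataset(6, 13, cfg)[0]


class TestAugmentation:
    def test_triples_count_and_preserves_hc(self, small_records):
        out = augment_training_set(small_records)
        assert len(out) == 3 * len(small_records)
        for i, r in enumerate(small_records):
            assert out[3 * i].hc_mm == out[3 * i + 1].hc_mm == out[3 * i + 2].hc_mm == r.hc_mm

    def test_flip_is_involution(self, small_records):
        from fetalhc.phantoms import _flip_record

        r = small_records[0]
        rr = _flip_record(_flip_record(r))
        assert np.array_equal(rr.image, r.image)
        assert np.array_equal(rr.gt_mask, r.gt_mask)
        assert rr.ellipse.isoclose(r.ellipse, 1e-9)

    def test_flip_transforms_ellipse_consistently(self, small_records):
        from fetalhc.phantoms import _flip_record

        r = small_records[1]
        f = _flip_record(r)
        W = r.image.shape[1]
        assert f.ellipse.cx == pytest.approx(W - 1 - r.ellipse.cx)
        assert np.array_equal(f.gt_mask, render_filled_mask(f.ellipse, W))

    def test_rotation_mask_matches_rotated_ellipse(self, small_records):
        """The re-rendered mask agrees with interpolated rotation of the original."""
        from scipy import ndimage

        from fetalhc.phantoms import _rotate_record

        r = small_records[2]
        rot = _rotate_record(r, 10.0)
        ref = ndimage.rotate(r.gt_mask.astype(float), 10.0, reshape=False, order=0) > 0.5
        assert dice(rot.gt_mask, ref) >= 0.97
        assert rot.ellipse.a == r.ellipse.a and rot.ellipse.b == r.ellipse.b

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            augment_training_set([])


class TestKFold:
    def test_basic_partition(self):
        folds = kfold_indices(10, 5, seed=0)
        assert len(folds) == 5
        test_all = sorted(i for _, te in folds for i in te)
        assert test_all == list(range(10))
        for tr, te in folds:
            assert len(te) == 2
            assert not set(tr) & set(te)

    def test_reproducible(self):
        assert kfold_indices(30, 5, seed=2) == kfold_indices(30, 5, seed=2)

    def test_999_gives_200x4_plus_199_larger_first(self):
        sizes = [len(te) for _, te in kfold_indices(999, 5, seed=1)]
        assert sizes == [200, 200, 200, 200, 199]

    def test_n_smaller_than_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            kfold_indices(3, 5)
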