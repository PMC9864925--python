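"""Synthetic generator, SMOTE, stratified split and client partitioning."""

import numpy as np
import pytest

from dmflsim import (
    SplitSpec,
    generate_synthetic_dataset,
    partition_clients,
    smote_oversample,
    stratified_split,
)
from dmflsim.data import load_archive, load_image_directory, save_archive, save_image_directory


class TestGenerator:
    @pytest.mark.parametrize(
        "counts",
        [[10, 10], [330, 500, 70, 279, 387, 135]],
    )
    def test_count_conservation(self, counts):
        ds = generate_synthetic_dataset(counts, image_size=(8, 8), seed=3)
        assert ds.manifest == {k: c for k, c in enumerate(counts)}
        assert len(ds) == sum(counts)

    def test_determinism_and_seed_sensitivity(self):
        a = generate_synthetic_dataset([5, 5], image_size=(8, 8), seed=1)
        b = generate_synthetic_dataset([5, 5], image_size=(8, 8), seed=1)
        c = generate_synthetic_dataset([5, 5], image_size=(8, 8), seed=2)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
        assert not all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, c))

    def test_intensities_in_unit_interval(self, tiny_dataset):
        px = tiny_dataset.pixels_array()
        assert px.min() >= 0.0 and px.max() <= 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"class_counts": [0, 0]},
            {"class_counts": [5, 5], "separability": -1.0},
            {"class_counts": [5, 5], "image_size": (4, 4)},
            {"class_counts": [5]},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        kwargs.setdefault("image_size", (8, 8))
        with pytest.raises(ValueError):
            generate_synthetic_dataset(**kwargs)

    def test_zero_separability_gives_chance_level_1nn(self, flat_dataset):
        """With identical class templates a 1-NN classifier must score within
        3 sigma of chance, sigma from the binomial null."""
        from sklearn.neighbors import KNeighborsClassifier

        X = flat_dataset.pixels_array().reshape(len(flat_dataset), -1)
        y = flat_dataset.labels_array()
        rng = np.random.default_rng(0)
        order = rng.permutation(len(y))
        half = len(y) // 2
        tr, te = order[:half], order[half:]
        acc = KNeighborsClassifier(n_neighbors=1).fit(X[tr], y[tr]).score(X[te], y[te])
        K = flat_dataset.num_classes
        p = 1.0 / K
        sigma = np.sqrt(p * (1 - p) / len(te))
        assert abs(acc - p) <= 3 * sigma

    def test_high_separability_beats_chance(self, tiny_dataset):
        from sklearn.neighbors import KNeighborsClassifier

        X = tiny_dataset.pixels_array().reshape(len(tiny_dataset), -1)
        y = tiny_dataset.labels_array()
        acc = KNeighborsClassifier(n_neighbors=1).fit(X[::2], y[::2]).score(X[1::2], y[1::2])
        assert acc > 0.9


class TestSmote:
    def test_balances_every_class_and_keeps_originals(self):
        ds = generate_synthetic_dataset([30, 12, 7], image_size=(8, 8), seed=2)
        out = smote_oversample(ds, target_per_class=30, seed=4)
        assert out.manifest == {0: 30, 1: 30, 2: 30}
        originals = {s.id for s in ds}
        kept = {s.id for s in out if s.provenance != "synthetic_smote"}
        assert kept == originals
        by_prov = [s.provenance for s in out]
        assert by_prov.count("synthetic_smote") == (30 - 12) + (30 - 7)

    def test_class_already_at_target_unchanged(self):
        ds = generate_synthetic_dataset([10, 6], image_size=(8, 8), seed=2)
        out = smote_oversample(ds, target_per_class=10, seed=0)
        class0 = [s for s in out if s.label == 0]
        assert len(class0) == 10
        assert all(s.provenance == "generated" for s in class0)

    def test_singleton_class_error_names_the_class(self):
        ds = generate_synthetic_dataset([5, 1], image_size=(8, 8), seed=0)
        with pytest.raises(ValueError, match="class1"):
            smote_oversample(ds, target_per_class=10)

    def test_target_below_max_count_rejected(self):
        ds = generate_synthetic_dataset([10, 4], image_size=(8, 8), seed=0)
        with pytest.raises(ValueError, match="below"):
            smote_oversample(ds, target_per_class=8)

    def test_synthetic_samples_lie_on_original_segments(self):
        """Exhaustive oracle: every synthetic vector is a convex combination of
        two original same-class vectors within 1e-6."""
        ds = generate_synthetic_dataset([12, 15], image_size=(8, 8), seed=9)
        out = smote_oversample(ds, target_per_class=20, k_neighbors=3, seed=1)
        originals = {
            k: [s.pixels.ravel() for s in out if s.label == k and s.provenance != "synthetic_smote"]
            for k in range(2)
        }
        synth = [s for s in out if s.provenance == "synthetic_smote"]
        assert synth
        for s in synth:
            v = s.pixels.ravel()
            assert _on_some_segment(v, originals[s.label], tol=1e-6), s.id

    def test_determinism(self):
        ds = generate_synthetic_dataset([8, 5], image_size=(8, 8), seed=2)
        a = smote_oversample(ds, 12, seed=7)
        b = smote_oversample(ds, 12, seed=7)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))


def _on_some_segment(v, pool, tol):
    for i in range(len(pool)):
        for j in range(len(pool)):
            if i == j:
                continue
            a, b = pool[i], pool[j]
            d = b - a
            denom = float(d @ d)
            if denom == 0:
                continue
            t = float((v - a) @ d) / denom
            if -tol <= t <= 1 + tol and np.linalg.norm(v - (a + t * d)) <= tol:
                return True
    return False


class TestStratifiedSplit:
    def test_floor_rounding_with_remainder_to_train(self):
        ds = generate_synthetic_dataset([700, 705], image_size=(8, 8), seed=1)
        tr, va, te = stratified_split(ds, SplitSpec(0.8, 0.1, 0.1), seed=0)
        assert (tr.manifest[0], va.manifest[0], te.manifest[0]) == (560, 70, 70)
        assert (tr.manifest[1], va.manifest[1], te.manifest[1]) == (565, 70, 70)

    def test_identity_split(self, tiny_dataset):
        tr, va, te = stratified_split(tiny_dataset, SplitSpec(1.0, 0.0, 0.0), seed=0)
        assert sorted(tr.ids()) == sorted(tiny_dataset.ids())
        assert len(va) == 0 and len(te) == 0

    def test_partition_is_exact_by_sample_id(self):
        ds = generate_synthetic_dataset([50] * 10, image_size=(8, 8), seed=6)
        tr, va, te = stratified_split(ds, SplitSpec(0.8, 0.1, 0.1), seed=3)
        recombined = sorted(tr.ids() + va.ids() + te.ids())
        assert recombined == sorted(ds.ids())
        assert len(set(tr.ids()) & set(va.ids())) == 0
        assert len(set(tr.ids()) & set(te.ids())) == 0

    def test_determinism(self, tiny_dataset):
        a = stratified_split(tiny_dataset, seed=5)
        b = stratified_split(tiny_dataset, seed=5)
        assert [x.ids() for x in a] == [x.ids() for x in b]

    def test_class_too_small_for_nonzero_fraction(self):
        ds = generate_synthetic_dataset([3, 20], image_size=(8, 8), seed=0)
        with pytest.raises(ValueError, match="too few"):
            stratified_split(ds, SplitSpec(0.5, 0.25, 0.25), seed=0)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(0.9, 0.2, 0.1)


class TestPartitionClients:
    def test_iid_exact_sizes_disjoint(self):
        ds = generate_synthetic_dataset([600] * 6, image_size=(8, 8), seed=4)
        parts = partition_clients(ds, [500, 1000, 2000], mode="iid", seed=1)
        sizes = [p.size for p in parts]
        assert sizes == [500, 1000, 2000]
        all_ids = [i for p in parts for d in (p.train, p.validation, p.test) for i in d.ids()]
        assert len(all_ids) == len(set(all_ids))

    def test_single_client_full_dataset(self, tiny_dataset):
        (part,) = partition_clients(
            tiny_dataset, [len(tiny_dataset)], mode="iid", seed=0, split=SplitSpec(1.0, 0, 0)
        )
        assert sorted(part.train.ids()) == sorted(tiny_dataset.ids())

    def test_over_allocation_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="available"):
            partition_clients(tiny_dataset, [50, 50], seed=0)

    def test_dirichlet_skew_concentrates_classes(self):
        ds = generate_synthetic_dataset([200, 200], image_size=(8, 8), seed=8)
        parts = partition_clients(
            ds, [100, 100], mode="by_class_skew", seed=3, concentration=1e-3
        )
        for p in parts:
            labels = np.concatenate(
                [d.labels_array() for d in (p.train, p.validation, p.test) if len(d)]
            )
            top = max(np.bincount(labels, minlength=2)) / labels.size
            assert top >= 0.9  # near-pure in one class

    def test_fractional_sizes(self, tiny_dataset):
        parts = partition_clients(tiny_dataset, [0.5, 0.5], mode="iid", seed=0)
        assert sum(p.size for p in parts) == len(tiny_dataset)


class TestIO:
    def test_png_directory_roundtrip(self, tmp_path):
        ds = generate_synthetic_dataset([4, 3], image_size=(8, 8), seed=1)
        save_image_directory(ds, tmp_path / "imgs")
        back = load_image_directory(tmp_path / "imgs")
        assert back.manifest == ds.manifest
        orig = {s.id: s.pixels for s in ds}
        # 8-bit quantization: intensities round-trip to within 1/255
        for s in back:
            assert np.max(np.abs(orig[s.id] - s.pixels)) <= 1.0 / 255 + 1e-12

    def test_archive_roundtrip(self, tmp_path):
        ds = generate_synthetic_dataset([4, 3], image_size=(8, 8), seed=1)
        save_archive(ds, tmp_path / "ds.npz")
        back = load_archive(tmp_path / "ds.npz")
        assert back.ids() == ds.ids()
        assert np.array_equal(back.pixels_array(), ds.pixels_array())
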