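import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvfuse.dataset_io import (AugmentationPolicy, DataError, SpecimenRecord,
                               ViewTriplet, augment_triplet, load_manifest,
                               resize_with_pad, stratified_split, _largest_remainder)


def _write_manifest(path, rows):
    cols = ["specimen_id", "species", "subfamily", "dorsal", "lateral",
            "ventral", "origin"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def _rows(n, species="sp1", subfamily="A", ventral="v.png"):
    return [[f"s{i}", species, subfamily, "d.png", "l.png", ventral, "captured"]
            for i in range(n)]


class TestLoadManifest:
    def test_full_triplets(self, tmp_path):
        records = load_manifest(_write_manifest(tmp_path / "m.csv", _rows(6)))
        assert len(records) == 6
        assert all(r.availability == (True, True, True) for r in records)

    def test_empty_cell_becomes_missing_view(self, tmp_path):
        records = load_manifest(_write_manifest(tmp_path / "m.csv", _rows(1, ventral="")))
        assert records[0].availability == (True, True, False)
        assert "ventral" not in records[0].view_paths

    def test_species_in_two_subfamilies_rejected(self, tmp_path):
        rows = _rows(1) + [["s9", "sp1", "B", "d.png", "", "", "captured"]]
        with pytest.raises(DataError, match="subfamilies"):
            load_manifest(_write_manifest(tmp_path / "m.csv", rows))

    def test_duplicate_id_rejected(self, tmp_path):
        rows = _rows(1) + _rows(1)
        with pytest.raises(DataError, match="duplicate"):
            load_manifest(_write_manifest(tmp_path / "m.csv", rows))

    def test_all_views_empty_rejected(self, tmp_path):
        rows = [["s0", "sp1", "A", "", "", "", "captured"]]
        with pytest.raises(DataError, match="no views"):
            load_manifest(_write_manifest(tmp_path / "m.csv", rows))


def _records(counts: dict) -> list:
    out = []
    for sp, n in counts.items():
        for i in range(n):
            out.append(SpecimenRecord(f"{sp}_{i}", sp, "A", {"dorsal": "d.png"}))
    return out


class TestStratifiedSplit:
    def test_exact_fractions(self):
        split = stratified_split(_records({f"sp{k}": 20 for k in range(10)}), seed=5)
        for sp in range(10):
            ids = [f"sp{sp}_{i}" for i in range(20)]
            counts = pd.Series([split.assignment[i] for i in ids]).value_counts()
            assert counts["train"] == 14 and counts["val"] == 3 and counts["test"] == 3

    def test_largest_remainder_tiebreak_val_before_test(self):
        # 10 * (0.7, 0.15, 0.15) -> floors 7/1/1, equal remainders 0.5/0.5:
        # the leftover seat goes to val
        assert _largest_remainder(10, (0.7, 0.15, 0.15)) == [7, 2, 1]

    def test_deterministic_under_seed(self):
        recs = _records({"a": 13, "b": 9})
        assert stratified_split(recs, seed=11).assignment == \
            stratified_split(recs, seed=11).assignment
        assert stratified_split(recs, seed=11).assignment != \
            stratified_split(recs, seed=12).assignment

    def test_augmented_records_inherit_parent_partition(self):
        recs = _records({"a": 10})
        recs += [SpecimenRecord(f"a_{i}_aug", "a", "A", {"dorsal": "d.png"},
                                origin="augmented", parent_id=f"a_{i}")
                 for i in range(10)]
        split = stratified_split(recs, seed=0)
        for i in range(10):
            assert split.assignment[f"a_{i}_aug"] == split.assignment[f"a_{i}"]

    def test_image_level_mode_allocates_augmented_independently(self):
        recs = _records({"a": 40})
        for r in recs[20:]:
            r.origin, r.parent_id = "augmented", recs[0].specimen_id
        split = stratified_split(recs, seed=0, unit="image")
        counts = pd.Series(list(split.assignment.values())).value_counts()
        assert counts["train"] == 28

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            stratified_split([], seed=0)

    @given(counts=st.lists(st.integers(min_value=1, max_value=37),
                           min_size=1, max_size=6),
           seed=st.integers(0, 2**16))
    @settings(max_examples=40, deadline=None)
    def test_partitions_disjoint_exhaustive_and_sized(self, counts, seed):
        recs = _records({f"sp{k}": n for k, n in enumerate(counts)})
        split = stratified_split(recs, seed=seed)
        assert sorted(split.assignment) == sorted(r.specimen_id for r in recs)
        for k, n in enumerate(counts):
            parts = [split.assignment[f"sp{k}_{i}"] for i in range(n)]
            expected = _largest_remainder(n, (0.7, 0.15, 0.15))
            got = [parts.count(p) for p in ("train", "val", "test")]
            assert got == expected


class TestResizeWithPad:
    def test_portrait_input_centered_with_black_rows(self):
        out = resize_with_pad(np.full((100, 200, 3), 255, np.uint8), 224)
        assert out.shape == (224, 224, 3)
        rows = np.flatnonzero(out.sum(axis=(1, 2)))
        assert len(rows) == 112 and rows[0] == 56  # 56 black rows above
        assert out[:56].sum() == 0 and out[168:].sum() == 0

    def test_square_input_has_no_padding(self):
        out = resize_with_pad(np.full((50, 50, 3), 7, np.uint8), 224)
        assert (out == 0).sum() == 0

    def test_idempotent_at_target_size(self):
        img = (np.random.default_rng(0).integers(0, 255, (224, 224, 3))
               .astype(np.uint8))
        np.testing.assert_array_equal(resize_with_pad(img, 224), img)

    def test_wide_input_content_columns(self):
        out = resize_with_pad(np.full((224, 448, 3), 255, np.uint8), 224)
        cols = np.flatnonzero(out.sum(axis=(0, 2)))
        rows = np.flatnonzero(out.sum(axis=(1, 2)))
        assert len(cols) == 224 and len(rows) == 112

    def test_invalid_dims_rejected(self):
        with pytest.raises(DataError):
            resize_with_pad(np.zeros((0, 5, 3), np.uint8))


def _triplet(rng, n_views=3):
    views = ("dorsal", "lateral", "ventral")[:n_views]
    img = rng.integers(0, 255, (32, 32, 3)).astype(np.uint8)
    return ViewTriplet(images={v: img.copy() for v in views},
                       availability=(True,) * n_views + (False,) * (3 - n_views),
                       label=0, subfamily=0, specimen_id="s0")


IDENTITY = AugmentationPolicy(rotation_deg=(0, 0), translate_frac=(0, 0),
                              brightness=(1, 1), contrast=(1, 1), hflip_prob=0.0)


class TestAugmentTriplet:
    def test_identity_policy_is_pixel_identical(self, rng):
        t = _triplet(rng)
        out = augment_triplet(t, IDENTITY, np.random.default_rng(1))
        for v in t.images:
            np.testing.assert_array_equal(out.images[v], t.images[v])

    def test_same_rng_state_reproduces(self, rng):
        t = _triplet(rng)
        policy = AugmentationPolicy()
        a = augment_triplet(t, policy, np.random.default_rng(5))
        b = augment_triplet(t, policy, np.random.default_rng(5))
        for v in t.images:
            np.testing.assert_array_equal(a.images[v], b.images[v])

    def test_one_parameter_draw_shared_across_views(self, rng):
        # identical input views must stay identical after a synchronized draw
        t = _triplet(rng)
        out = augment_triplet(t, AugmentationPolicy(), np.random.default_rng(2))
        np.testing.assert_array_equal(out.images["dorsal"], out.images["lateral"])
        np.testing.assert_array_equal(out.images["dorsal"], out.images["ventral"])
        assert "augmentation" in out.provenance

    def test_label_and_availability_unchanged(self, rng):
        t = _triplet(rng, n_views=2)
        out = augment_triplet(t, AugmentationPolicy(), np.random.default_rng(3))
        assert out.label == t.label and out.availability == t.availability
        assert set(out.images) == set(t.images)
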